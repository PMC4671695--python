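"""Normal-mixture EM on log2 fold-change distributions.

Used to ask whether a chromosome's response to a perturbation is continuous
(all mixture components shifted together) or carries a discrete "escaper"
subpopulation (a component sitting at zero while others shift).  Components
are fitted by standard expectation-maximization with unequal variances, a
variance floor against collapse, and multiple seeded restarts; model size
(two vs three components) is chosen by BIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

INTERPRET_UP = "all_components_shifted_up"
INTERPRET_UNAFFECTED = "distinct_unaffected_class"
INTERPRET_DOWN = "distinct_down_class"
INTERPRET_SHIFTED_DOWN = "all_components_shifted_down"


@dataclass
class MixtureFit:
    """Result of an EM fit: weights/means/sds sorted by ascending mean."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    bic: float
    converged: bool
    n_iter: int
    loglik_history: list = field(default_factory=list, repr=False)


def _log_pdf(values: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    z = (values[:, None] - means[None, :]) / sds[None, :]
    return -0.5 * z**2 - np.log(sds[None, :]) - 0.5 * np.log(2.0 * np.pi)


def _em_once(values: np.ndarray, means0: np.ndarray, sds0: np.ndarray,
             weights0: np.ndarray, tol: float, max_iter: int,
             sigma_floor: float):
    n = len(values)
    means, sds, weights = means0.copy(), sds0.copy(), weights0.copy()
    history = []
    converged = False
    ll_prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        log_comp = _log_pdf(values, means, sds) + np.log(weights)[None, :]
        log_norm = logsumexp(log_comp, axis=1)
        ll = float(log_norm.sum())
        assert ll >= ll_prev - 1e-7 * (1.0 + abs(ll)), \
            "EM log-likelihood decreased"
        history.append(ll)
        if ll - ll_prev < tol:
            converged = True
            break
        ll_prev = ll
        resp = np.exp(log_comp - log_norm[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp * values[:, None]).sum(axis=0) / nk
        var = (resp * (values[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.maximum(np.sqrt(var), sigma_floor)
    return means, sds, weights, history, converged, it


def fit_gaussian_mixture(values, k: int, seed: int = 0, tol: float = 1e-8,
                         max_iter: int = 1000, sigma_floor: float = 1e-3,
                         n_restarts: int = 10) -> MixtureFit:
    """Fit a k-component normal mixture by EM, best of seeded restarts.

    Restarts initialize means at quantile-spread positions of the sample plus
    seeded jitter; the best restart by final log-likelihood is kept.
    Components are reported sorted by ascending mean.  All-identical input is
    degenerate and rejected; a fit that exhausts ``max_iter`` is returned
    with ``converged=False``.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 10 * k:
        raise ValueError(f"need at least {10 * k} finite values for k={k}")
    if np.ptp(values) == 0:
        raise ValueError("all values identical; mixture fit is degenerate")
    rng = np.random.default_rng(seed)
    sd0 = float(values.std())
    best = None
    for r in range(n_restarts):
        q = (np.arange(k) + 0.5) / k
        means0 = np.quantile(values, q)
        if r > 0:  # first restart is the plain quantile start
            means0 = means0 + rng.normal(0.0, sd0 / 2.0, k)
        sds0 = np.full(k, max(sd0, sigma_floor))
        weights0 = np.full(k, 1.0 / k)
        means, sds, weights, history, converged, n_iter = _em_once(
            values, means0, sds0, weights0, tol, max_iter, sigma_floor)
        if best is None or history[-1] > best[3][-1]:
            best = (means, sds, weights, history, converged, n_iter)
    means, sds, weights, history, converged, n_iter = best
    order = np.argsort(means)
    n_params = 3 * k - 1
    ll = history[-1]
    bic = -2.0 * ll + n_params * np.log(len(values))
    return MixtureFit(k=k, weights=weights[order], means=means[order],
                      sds=sds[order], loglik=ll, bic=float(bic),
                      converged=converged, n_iter=n_iter,
                      loglik_history=history)


def select_and_interpret(fits, zero_band: float = 0.1):
    """Pick the best fit by BIC and interpret the component layout.

    Among converged fits the minimum-BIC model wins.  Interpretation
    precedence (down > unaffected > up): a component below ``-zero_band``
    together with one above ``+zero_band`` is a distinct downregulated class;
    any component inside the band is a distinct unaffected (escaper-like)
    class; all components above the band mean the whole distribution shifted
    up (continuous regulation); all below, shifted down.
    """
    fits = list(fits)
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged mixture fit to select from")
    chosen = min(converged, key=lambda f: f.bic)
    mu = chosen.means
    if (mu < -zero_band).any() and (mu > zero_band).any():
        interpretation = INTERPRET_DOWN
    elif ((mu >= -zero_band) & (mu <= zero_band)).any():
        interpretation = INTERPRET_UNAFFECTED
    elif (mu > zero_band).all():
        interpretation = INTERPRET_UP
    else:
        interpretation = INTERPRET_SHIFTED_DOWN
    return chosen, interpretation
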