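"""Per-gene log2 expression ratios and chromosome-scale statistics.

The central quantity is the per-gene log2 ratio between two conditions
(e.g. hermaphrodite vs mixed-sex), defined as the difference of the mean
per-replicate log2 values, with a Welch-type standard error and confidence
interval.  Chromosome summaries, the X-vs-autosome rank-sum test, Fisher
enrichment of differentially expressed genes, maternal-loading overlap and
the top-regulated-gene summary of a mutant comparison all live here.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import AUTOSOMES, ExpressionTable, ValidationError

RATIO_COLUMNS = ["log2_ratio", "se", "ci_low", "ci_high", "n_a", "n_b"]


def expected_sex_ratio_log2(dcc_repression: float, male_fraction: float = 0.5) -> float:
    """Analytic expected log2(hermaphrodite/mixed-sex) ratio for an X gene.

    Hermaphrodites express two X doses repressed ``dcc_repression``-fold;
    males one unrepressed dose; the mixed pool is the male-fraction-weighted
    mean.  Full two-fold repression gives 0; no repression with an equal
    XX/XO pool gives log2(4/3) ~ 0.415.
    """
    if dcc_repression < 1.0:
        raise ValueError("dcc_repression must be >= 1")
    if not 0.0 < male_fraction <= 1.0:
        raise ValueError("male_fraction must be in (0, 1]")
    herm = 2.0 / dcc_repression
    mixed = (1.0 - male_fraction) * herm + male_fraction * 1.0
    return float(np.log2(herm / mixed))


# ---------------------------------------------------------------------------
# log2 ratios with Welch CI
# ---------------------------------------------------------------------------

def _two_sample_ci(la: np.ndarray, lb: np.ndarray, confidence: float,
                   ci_family: str):
    """SE/CI for the difference of means of log2 values (rows = genes).

    ``pooled`` uses the equal-variance two-sample t (exact nominal coverage
    under the per-gene equal-variance replicate-noise model); ``welch`` uses
    unequal variances with Satterthwaite degrees of freedom (robust to
    variance heterogeneity, mildly conservative at two or three replicates).
    """
    na, nb = la.shape[1], lb.shape[1]
    ma, mb = la.mean(axis=1), lb.mean(axis=1)
    diff = ma - mb
    if na < 2 or nb < 2:
        nan = np.full(diff.shape, np.nan)
        return diff, nan, nan, nan
    va = la.var(axis=1, ddof=1)
    vb = lb.var(axis=1, ddof=1)
    if ci_family == "pooled":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = np.full(diff.shape, float(na + nb - 2))
    elif ci_family == "welch":
        se = np.sqrt(va / na + vb / nb)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        df = np.where(se == 0, 1.0, df)  # placeholder; CI width 0 there
    else:
        raise ValueError(f"unknown ci_family {ci_family!r}")
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df)
    half = tcrit * se
    return diff, se, diff - half, diff + half


def compute_log2_ratios(table_a: ExpressionTable, table_b: ExpressionTable,
                        confidence: float = 0.95,
                        ci_family: str = "pooled") -> pd.DataFrame:
    """Per-gene log2 ratio (A minus B) with two-sample t SE and CI.

    Both tables should already be restricted to expressed genes; a zero value
    reaching this stage is an error (log2 undefined).  Genes absent from
    either side are omitted.  Columns: log2_ratio, se, ci_low, ci_high,
    n_a, n_b; with fewer than two replicates on a side the SE and CI are NaN
    (downstream callers treat such genes as not assessable).  See
    ``ci_family`` (``pooled`` default, ``welch`` alternative).
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    shared = table_a.genes.intersection(table_b.genes)
    if len(shared) == 0:
        raise ValidationError("no shared genes between the two tables")
    va = table_a.values.loc[shared].to_numpy(dtype=float)
    vb = table_b.values.loc[shared].to_numpy(dtype=float)
    if (va == 0).any() or (vb == 0).any():
        raise ValidationError("zero expression value in ratio computation; "
                              "apply the expressed-gene filter upstream")
    diff, se, lo, hi = _two_sample_ci(np.log2(va), np.log2(vb), confidence,
                                      ci_family)
    return pd.DataFrame({"log2_ratio": diff, "se": se, "ci_low": lo,
                         "ci_high": hi, "n_a": va.shape[1], "n_b": vb.shape[1]},
                        index=shared)


def chromosome_summary(ratios: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Median log2 ratio and gene count per chromosome.

    The median is the midpoint of the two central order statistics for even
    counts.  Chromosomes with no genes in ``ratios`` are absent from the
    output.
    """
    unresolved = ratios.index.difference(catalog.index)
    if len(unresolved):
        raise ValidationError(f"genes not in catalog: {list(unresolved[:5])}")
    chrom = catalog.loc[ratios.index, "chromosome"]
    grouped = ratios["log2_ratio"].groupby(chrom)
    out = pd.DataFrame({"median": grouped.median(), "n": grouped.size()})
    out.index.name = "chromosome"
    return out


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (exact with ties for small groups)
# ---------------------------------------------------------------------------

def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray, alternative: str):
    """Exact conditional rank-sum p-value by dynamic programming.

    Works with ties: the distribution of the rank-sum of a random n-subset of
    the pooled midranks is built by convolution over doubled midranks
    (integers).  The observed tail includes the observed value.
    """
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2.0 * stats.rankdata(pooled)).astype(np.int64)
    n, m = len(x), len(y)
    total = math.comb(n + m, n)
    obs = int(ranks2[:n].sum())
    smax = int(ranks2.sum())
    # dp[k, s] = number of k-subsets with doubled-rank sum s
    dp = np.zeros((n + 1, smax + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for w in ranks2:
        for k in range(n, 0, -1):  # descending so each item is used once
            dp[k, w:] += dp[k - 1, : smax + 1 - w]
    dist = dp[n]
    p_greater = dist[obs:].sum() / total
    p_less = dist[: obs + 1].sum() / total
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return float(ranks2[:n].sum() / 2.0), float(p)


def rank_sum_test(x, y, alternative: str = "greater",
                  exact_threshold: int = 10) -> tuple[float, float]:
    """One- or two-sided Wilcoxon rank-sum test of ``x`` against ``y``.

    Uses the exact conditional null distribution (tie-aware, by enumeration-
    equivalent dynamic programming) when ``min(len(x), len(y)) <=
    exact_threshold``, otherwise the normal approximation with tie and
    continuity corrections.  Returns ``(rank_sum_of_x, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("rank_sum_test requires non-empty groups")
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if min(len(x), len(y)) <= exact_threshold:
        return _exact_rank_sum_p(x, y, alternative)
    alt = {"two_sided": "two-sided"}.get(alternative, alternative)
    res = stats.mannwhitneyu(x, y, alternative=alt, method="asymptotic",
                             use_continuity=True)
    w = float(stats.rankdata(np.concatenate([x, y]))[: len(x)].sum())
    return w, float(res.pvalue)


def brute_force_rank_sum_p(x, y, alternative: str = "greater") -> float:
    """Independent oracle: exhaustive enumeration over all group assignments.

    Enumerates every :math:`\\binom{n+m}{n}` assignment of the pooled values
    to the first group and counts rank sums at least (at most) as extreme as
    observed.  Intended for tests and cross-checks at small n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = len(x)
    obs = ranks[:n].sum()
    ge = le = total = 0
    for idx in combinations(range(len(pooled)), n):
        s = ranks[list(idx)].sum()
        total += 1
        if s >= obs - 1e-9:
            ge += 1
        if s <= obs + 1e-9:
            le += 1
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2.0 * min(ge / total, le / total))


def x_vs_autosome_test(ratios: pd.DataFrame, catalog: pd.DataFrame,
                       alternative: str = "greater",
                       bh_correct: bool = False) -> pd.DataFrame:
    """Wilcoxon rank-sum test of X-gene log2 ratios against each autosome.

    One row per autosome present plus a ``pooled`` row testing X against all
    autosomal genes together.  P-values are reported raw; set ``bh_correct``
    for an additional Benjamini-Hochberg column over the per-autosome tests.
    """
    chrom = catalog.loc[ratios.index, "chromosome"]
    xvals = ratios.loc[chrom == "X", "log2_ratio"].to_numpy()
    if len(xvals) == 0:
        raise ValidationError("no X-linked genes among the ratios")
    rows = []
    for a in AUTOSOMES:
        avals = ratios.loc[chrom == a, "log2_ratio"].to_numpy()
        if len(avals) == 0:
            continue
        w, p = rank_sum_test(xvals, avals, alternative)
        rows.append({"comparison": a, "n_x": len(xvals), "n_other": len(avals),
                     "statistic": w, "p": p})
    pooled = ratios.loc[chrom.isin(AUTOSOMES), "log2_ratio"].to_numpy()
    if len(pooled) == 0:
        raise ValidationError("no autosomal genes among the ratios")
    w, p = rank_sum_test(xvals, pooled, alternative)
    out = pd.DataFrame(rows).set_index("comparison")
    if bh_correct and len(out):
        out["p_bh"] = stats.false_discovery_control(out["p"].to_numpy())
    out.loc["pooled"] = {"n_x": len(xvals), "n_other": len(pooled),
                         "statistic": w, "p": p,
                         **({"p_bh": np.nan} if bh_correct else {})}
    return out


# ---------------------------------------------------------------------------
# Fisher enrichment of DE genes
# ---------------------------------------------------------------------------

def hypergeom_enrichment_p(k_on: int, n_on: int, k_total: int, n_total: int) -> float:
    """One-sided hypergeometric upper tail: P(X >= k_on) for drawing ``n_on``
    genes from ``n_total`` of which ``k_total`` carry the label."""
    return float(stats.hypergeom.sf(k_on - 1, n_total, k_total, n_on))


def brute_force_hypergeom_p(k_on: int, n_on: int, k_total: int, n_total: int) -> float:
    """Independent oracle: explicit hypergeometric tail sum with math.comb."""
    denom = math.comb(n_total, n_on)
    num = 0
    for k in range(k_on, min(n_on, k_total) + 1):
        num += math.comb(k_total, k) * math.comb(n_total - k_total, n_on - k)
    return num / denom


def chromosome_enrichment_test(de_flags: pd.Series,
                               catalog: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome Fisher enrichment of up- and downregulated genes.

    ``de_flags`` maps gene_id to ``up``/``down``/``ns``.  For each chromosome
    with at least one analyzed gene, a one-sided hypergeometric tail tests
    whether the chromosome carries more up (resp. down) genes than expected
    from the genome-wide rate.
    """
    bad = set(de_flags.unique()) - {"up", "down", "ns"}
    if bad:
        raise ValidationError(f"unknown DE flags: {sorted(bad)}")
    chrom = catalog.loc[de_flags.index, "chromosome"]
    n_total = len(de_flags)
    rows = []
    for c, idx in de_flags.groupby(chrom).groups.items():
        flags_c = de_flags.loc[idx]
        n_on = len(flags_c)
        row = {"chromosome": c, "n": n_on}
        for direction in ("up", "down"):
            k_total = int((de_flags == direction).sum())
            k_on = int((flags_c == direction).sum())
            row[f"n_{direction}"] = k_on
            row[f"p_{direction}"] = hypergeom_enrichment_p(
                k_on, n_on, k_total, n_total)
        rows.append(row)
    return pd.DataFrame(rows).set_index("chromosome")


# ---------------------------------------------------------------------------
# stage dynamics, maternal loading, sex inference, top-regulated genes
# ---------------------------------------------------------------------------

def change_in_compensation(ratios_older: pd.DataFrame,
                           ratios_younger: pd.DataFrame):
    """Per-gene (older minus younger) log2-ratio difference.

    Returns ``(diff, n_excluded)``: genes present in only one stage are
    excluded and counted, never silently dropped.
    """
    shared = ratios_older.index.intersection(ratios_younger.index)
    if len(shared) == 0:
        raise ValidationError("no shared genes between stages")
    n_excluded = (len(ratios_older.index.difference(shared))
                  + len(ratios_younger.index.difference(shared)))
    diff = (ratios_older.loc[shared, "log2_ratio"]
            - ratios_younger.loc[shared, "log2_ratio"])
    return diff.rename("delta_log2_ratio"), n_excluded


def maternal_overlap(gene_set, oocyte_fpkm: pd.Series, catalog: pd.DataFrame,
                     threshold: float = 1.0) -> pd.DataFrame:
    """Per-chromosome fraction of a gene set that is maternally loaded.

    A gene is loaded iff its oocyte FPKM is strictly above ``threshold``.
    Genes without an oocyte value are counted as not assessable and reported
    separately; the fraction is loaded / assessed (NaN where nothing is
    assessable).
    """
    genes = pd.Index(gene_set)
    chrom = catalog.loc[genes, "chromosome"]
    have = genes.intersection(oocyte_fpkm.index)
    loaded = oocyte_fpkm.loc[have] > threshold
    rows = []
    for c, idx in genes.groupby(chrom).items():
        idx = pd.Index(idx)
        assessed = idx.intersection(have)
        n_loaded = int(loaded.loc[assessed].sum())
        rows.append({"chromosome": c, "n_genes": len(idx),
                     "n_assessed": len(assessed),
                     "n_missing": len(idx) - len(assessed),
                     "n_loaded": n_loaded,
                     "fraction_loaded": (n_loaded / len(assessed)
                                         if len(assessed) else np.nan)})
    return pd.DataFrame(rows).set_index("chromosome")


def estimate_single_sex_expression(herm_level, mixed_level,
                                   male_fraction: float = 0.5):
    """Infer the male expression level from hermaphrodite and mixed-pool levels.

    Solves ``mixed = (1 - f) * herm + f * male`` for ``male``.  Negative
    inferences are clamped to 0 and flagged.  Returns ``(male, clamped)``.
    """
    if male_fraction == 0:
        raise ValueError("male_fraction must be > 0")
    if not 0.0 < male_fraction <= 1.0:
        raise ValueError("male_fraction must be in (0, 1]")
    herm = np.asarray(herm_level, dtype=float)
    mixed = np.asarray(mixed_level, dtype=float)
    male = (mixed - (1.0 - male_fraction) * herm) / male_fraction
    clamped = male < 0
    male = np.where(clamped, 0.0, male)
    if male.ndim == 0:
        return float(male), bool(clamped)
    return male, clamped


def top_fraction_regulated(ratios: pd.DataFrame, catalog: pd.DataFrame,
                           fraction: float = 0.05):
    """Top genes by absolute log2 ratio, with per-chromosome upregulated share.

    Takes ``ceil(fraction * N)`` genes ranked by descending ``|log2_ratio|``;
    ties at the cutoff break lexicographically by gene id, so the selection is
    deterministic.  Returns ``(selected_gene_index, per_chromosome)`` where
    the per-chromosome table reports the share of selected genes with
    ``log2_ratio > 0``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    df = ratios[["log2_ratio"]].copy()
    df["abs_ratio"] = df["log2_ratio"].abs()
    df["gene_id"] = df.index
    df = df.sort_values(["abs_ratio", "gene_id"], ascending=[False, True],
                        kind="mergesort")
    n_take = int(math.ceil(fraction * len(df)))
    top = df.iloc[:n_take]
    chrom = catalog.loc[top.index, "chromosome"]
    grouped = (top["log2_ratio"] > 0).groupby(chrom)
    per_chrom = pd.DataFrame({"n": grouped.size(),
                              "n_up": grouped.sum().astype(int)})
    per_chrom["fraction_up"] = per_chrom["n_up"] / per_chrom["n"]
    per_chrom.index.name = "chromosome"
    return top.index, per_chrom
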