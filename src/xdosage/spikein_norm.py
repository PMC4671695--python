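"""Exogenous-species spike-in corrections for RNA-seq, ChIP-seq and RT-qPCR.

Within-sample normalization (library size, genome-wide median coverage,
reference-gene delta-Ct) is blind to global shifts: if every gene moves
together, renormalization cancels the movement.  Adding a fixed amount of a
second species' material before library or ChIP preparation restores an
absolute anchor — the spike material is identical across conditions, so any
apparent spike change measures the normalization artifact.  Three correction
routes are implemented: a log-scale regression fitted on highly expressed
spike genes (RNA-seq), a ChIP/input ratio-of-ratios factor (ChIP-seq), and a
spike-referenced delta-delta-Ct (RT-qPCR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import CoverageTrack, ExpressionTable, ValidationError


@dataclass
class RegressionCorrection:
    """Log2-scale linear fit of mutant on wild-type spike-gene values."""

    slope: float
    intercept: float
    n_spike_genes: int
    residual_sd: float


@dataclass
class SpikeInFactor:
    """Multiplicative ChIP correction factor, global and per chromosome."""

    comparison: str
    global_factor: float
    per_chromosome: dict

    def __post_init__(self) -> None:
        if self.global_factor <= 0 or any(v <= 0 for v in self.per_chromosome.values()):
            raise ValidationError("spike-in factors must be > 0")


# ---------------------------------------------------------------------------
# RNA-seq regression correction
# ---------------------------------------------------------------------------

def rna_spike_correction(table: ExpressionTable, spike_genes,
                         condition_ref: str = "wt",
                         condition_alt: str = "mutant",
                         high_expr_quantile: float = 0.5):
    """Spike-in regression correction of mutant-vs-wild-type log2 ratios.

    Steps: (1) per-sample total-read normalization, with the library size
    taken as the total read mass of the *target*-species genes (a common
    per-sample scale is required for the spike genes to carry the global
    signal); (2) per-condition median across replicates; (3) OLS of mutant on
    wild-type log2 values over spike genes above the ``high_expr_quantile``
    of wild-type spike expression; (4) target-species mutant values corrected
    by the inverted coefficients, ``value' = (value - intercept)/slope``;
    (5) corrected ratio = corrected mutant - wild type.

    Returns ``(ratios, correction)`` where ``ratios`` has one row per target
    gene with ``log2_uncorrected`` and ``log2_corrected`` columns.  Genes
    with a zero median in either condition are dropped.
    """
    spike_genes = pd.Index(spike_genes).intersection(table.genes)
    target_genes = table.genes.difference(spike_genes, sort=False)
    cond = table.design["condition"]
    samples = {c: list(cond.index[cond == c]) for c in (condition_ref, condition_alt)}
    for c, s in samples.items():
        if not s:
            raise ValidationError(f"no samples for condition {c!r}")

    norm = table.values / table.values.loc[target_genes].sum(axis=0)
    med = pd.DataFrame({c: norm[s].median(axis=1) for c, s in samples.items()})

    spike = med.loc[spike_genes]
    spike = spike[(spike > 0).all(axis=1)]
    cutoff = spike[condition_ref].quantile(high_expr_quantile)
    used = spike[spike[condition_ref] >= cutoff]
    if len(used) < 10:
        raise ValidationError(f"only {len(used)} usable spike genes (need >= 10)")
    xw = np.log2(used[condition_ref].to_numpy())
    xm = np.log2(used[condition_alt].to_numpy())
    slope, intercept = np.polyfit(xw, xm, 1)
    if slope <= 0:
        raise ValidationError(f"pathological spike regression slope {slope:.3g}")
    resid = xm - (slope * xw + intercept)
    correction = RegressionCorrection(float(slope), float(intercept),
                                      len(used), float(resid.std(ddof=1)))

    tgt = med.loc[target_genes]
    tgt = tgt[(tgt > 0).all(axis=1)]
    lw = np.log2(tgt[condition_ref].to_numpy())
    lm = np.log2(tgt[condition_alt].to_numpy())
    corrected_m = (lm - intercept) / slope
    ratios = pd.DataFrame({"log2_uncorrected": lm - lw,
                           "log2_corrected": corrected_m - lw},
                          index=tgt.index)
    return ratios, correction


# ---------------------------------------------------------------------------
# ChIP ratio-of-ratios factor
# ---------------------------------------------------------------------------

MASS_COLUMNS = ["assay", "condition", "species", "chromosome", "reads"]


def track_read_masses(tracks: dict) -> pd.DataFrame:
    """Per-chromosome read masses from ``(condition, assay, species)`` tracks.

    Summing raw bin counts per chromosome gives the read-mass table that
    :func:`chip_spike_factor` consumes.
    """
    rows = []
    for (condition, assay, species), track in tracks.items():
        for chrom, vals in track.values.items():
            rows.append({"assay": assay, "condition": condition,
                         "species": species, "chromosome": chrom,
                         "reads": float(vals.sum())})
    return pd.DataFrame(rows)


def chip_spike_factor(masses: pd.DataFrame, condition_ref: str = "wt",
                      condition_alt: str = "mutant",
                      per_chromosome: bool = True) -> SpikeInFactor:
    """Spike-in ChIP correction factor from total-read-normalized masses.

    Each library (assay x condition) is normalized to its total reads; the
    enrichment ``E = ChIP/input`` is formed per species, and the factor is
    ``[E_target/E_spike]_mutant / [E_target/E_spike]_wt``.  Per-chromosome
    factors restrict the target masses to one chromosome while keeping
    genome-wide spike masses (the spike genome carries no X-dosage
    structure).  Depth drops out: scaling any single library leaves the
    factor unchanged.
    """
    m = masses.copy()
    missing = [c for c in MASS_COLUMNS if c not in m.columns]
    if missing:
        raise ValidationError(f"mass table missing columns: {missing}")
    totals = m.groupby(["assay", "condition"])["reads"].transform("sum")
    m["norm"] = m["reads"] / totals

    def mass(assay, condition, species, chromosome=None):
        sel = ((m["assay"] == assay) & (m["condition"] == condition)
               & (m["species"] == species))
        if chromosome is not None:
            sel &= m["chromosome"] == chromosome
        v = m.loc[sel, "norm"].sum()
        if v <= 0:
            where = f"{assay}/{condition}/{species}" + (
                f"/{chromosome}" if chromosome else "")
            raise ValidationError(f"zero read mass for {where}")
        return v

    def enrich_ratio(chromosome=None):
        out = {}
        for condition in (condition_ref, condition_alt):
            e_t = (mass("chip", condition, "target", chromosome)
                   / mass("input", condition, "target", chromosome))
            e_s = (mass("chip", condition, "spike")
                   / mass("input", condition, "spike"))
            out[condition] = e_t / e_s
        return out[condition_alt] / out[condition_ref]

    global_factor = enrich_ratio()
    per_chrom = {}
    if per_chromosome:
        target_chroms = sorted(m.loc[m["species"] == "target", "chromosome"].unique())
        per_chrom = {c: enrich_ratio(c) for c in target_chroms}
    return SpikeInFactor(f"{condition_alt} vs {condition_ref}",
                         float(global_factor), per_chrom)


def standard_chip_factor(masses: pd.DataFrame, condition_ref: str = "wt",
                         condition_alt: str = "mutant") -> SpikeInFactor:
    """Per-chromosome mutant/wt factor a *non*-spike analysis would report.

    Identical ratio-of-ratios construction, but the reference is the target
    genome itself (each chromosome's enrichment relative to the genome-wide
    target enrichment) instead of the spike species.  A genome-wide
    multiplicative change cancels out entirely — this is the masking that
    spike-in normalization exists to break.
    """
    m = masses[masses["species"] == "target"].copy()
    totals = m.groupby(["assay", "condition"])["reads"].transform("sum")
    m["norm"] = m["reads"] / totals

    def enrich(assay, condition, chromosome):
        sel = (m["assay"] == assay) & (m["condition"] == condition)
        genome = m.loc[sel, "norm"].sum()
        chrom = m.loc[sel & (m["chromosome"] == chromosome), "norm"].sum()
        if chrom <= 0 or genome <= 0:
            raise ValidationError(
                f"zero read mass for {assay}/{condition}/{chromosome}")
        return chrom / genome

    per_chrom = {}
    for c in sorted(m["chromosome"].unique()):
        e = {cond: (enrich("chip", cond, c) / enrich("input", cond, c))
             for cond in (condition_ref, condition_alt)}
        per_chrom[c] = e[condition_alt] / e[condition_ref]
    return SpikeInFactor(f"{condition_alt} vs {condition_ref} (standard)",
                         1.0, per_chrom)


def apply_spike_factor(track: CoverageTrack, factor: SpikeInFactor,
                       per_chromosome: bool = True) -> CoverageTrack:
    """Scale a mutant's normalized coverage by the spike-in factor."""
    values = {}
    for chrom, vals in track.values.items():
        f = (factor.per_chromosome.get(chrom, factor.global_factor)
             if per_chromosome else factor.global_factor)
        values[chrom] = vals * f
    return track.copy_with(values, track.value_kind)


# ---------------------------------------------------------------------------
# delta-delta-Ct
# ---------------------------------------------------------------------------

CT_COLUMNS = ["gene_id", "condition", "replicate", "ct", "is_reference"]


def delta_delta_ct(ct: pd.DataFrame, condition_ref: str = "wt",
                   condition_alt: str = "mutant") -> pd.DataFrame:
    """Raw (delta-Ct) and spike-corrected (delta-delta-Ct) qPCR fold changes.

    ``delta_ct`` is the mean Ct difference (mutant minus wild type) per gene;
    the raw fold change is ``2**(-delta_ct)``.  ``ddct`` subtracts the mean
    ``delta_ct`` of the reference (spike) genes, giving the corrected fold
    ``2**(-ddct)``.  Every reference gene must have Ct values in both
    conditions.
    """
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValidationError(f"Ct table missing columns: {missing}")
    if (ct["ct"] <= 0).any():
        raise ValidationError("Ct values must be > 0")
    mean_ct = (ct.groupby(["gene_id", "condition"])["ct"].mean()
               .unstack("condition"))
    for c in (condition_ref, condition_alt):
        if c not in mean_ct.columns:
            raise ValidationError(f"no Ct values for condition {c!r}")
    refs = ct.loc[ct["is_reference"], "gene_id"].unique()
    if len(refs) == 0:
        raise ValidationError("need at least one reference gene")
    ref_ct = mean_ct.loc[list(refs)]
    if ref_ct.isna().any().any():
        gene = ref_ct.index[ref_ct.isna().any(axis=1)][0]
        raise ValidationError(f"reference gene {gene!r} missing a condition")
    delta = mean_ct[condition_alt] - mean_ct[condition_ref]
    ref_delta = delta.loc[list(refs)].mean()
    out = pd.DataFrame({"delta_ct": delta,
                        "fold_raw": 2.0 ** (-delta),
                        "ddct": delta - ref_delta,
                        "fold_corrected": 2.0 ** (-(delta - ref_delta))})
    out["is_reference"] = out.index.isin(refs)
    return out
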