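"""Synthetic expression, spike-in and ChIP studies with known ground truth.

The generator emulates the statistical structure of a C. elegans
dosage-compensation study: an XX hermaphrodite population compared against a
50/50 XX/XO mixed-sex pool, with a tunable fold-repression applied to X-linked
genes in hermaphrodites by the dosage compensation complex (DCC), maternal
transcript pools shared between sexes in early stages, staged zygotic
activation, sex-biased genes, a second-species spike-in mixed at a fixed
mass fraction, and ChIP/input coverage with gene-body and X-wide enrichment.

Every simulated quantity is recorded in a truth table so that downstream
statistics can be checked against construction rather than against themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import AUTOSOMES, CoverageTrack, ExpressionTable

LN2 = float(np.log(2.0))

#: developmental stage order used for maternal decay / zygotic activation
STAGE_ORDER = ("two_cell", "early_embryo", "comma", "L1", "L3", "young_adult")


@dataclass
class SimulationConfig:
    """Parameters of a simulated two-sex expression study.

    Defaults follow the study design being emulated: ~13% of genes on X
    (roughly 2,700 of 20,000), three biological replicates, a mixed-sex pool
    that is exactly half XO males, and full two-fold DCC repression of
    hermaphrodite X genes (``dcc_repression=2``; 1 means no compensation).
    Replicate noise is lognormal with the given SD in log2 units, so the mean
    of per-replicate log2 values is an unbiased estimate of the log2 of the
    expected expression.
    """

    n_genes: int = 20_000
    x_fraction: float = 0.13
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 2.0
    replicate_sd_log2: float = 0.25
    dcc_repression: float = 2.0
    male_fraction: float = 0.5
    maternal_fraction: float = 0.5
    maternal_decay: float = 0.5
    sex_bias_fraction: float = 0.05
    sex_bias_log2: float = 1.0
    late_activation_fraction: float = 0.3
    stages: tuple[str, ...] = ("early_embryo",)
    chromosome_shifts: dict | None = None
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("x_fraction", "maternal_fraction", "sex_bias_fraction",
                     "maternal_decay", "late_activation_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dcc_repression < 1.0:
            raise ValueError("dcc_repression must be >= 1")
        if not 0.0 < self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in (0, 1]")
        unknown = [s for s in self.stages if s not in STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; known: {STAGE_ORDER}")


def _assign_chromosomes(n_genes: int, x_fraction: float,
                        rng: np.random.Generator) -> np.ndarray:
    n_x = int(round(n_genes * x_fraction))
    n_per_autosome = (n_genes - n_x) // len(AUTOSOMES)
    chroms = []
    for a in AUTOSOMES:
        chroms += [a] * n_per_autosome
    chroms += ["X"] * (n_genes - len(chroms))
    counts = pd.Series(chroms).value_counts()
    if (counts < 10).any():
        raise ValueError("need at least 10 genes per chromosome; "
                         f"smallest has {counts.min()}")
    return np.array(chroms)


def make_gene_catalog(chromosomes: np.ndarray,
                      spacing: int = 5_000, length: int = 2_000) -> pd.DataFrame:
    """Lay simulated genes along their chromosomes at fixed spacing.

    Genes alternate strand; coordinates are 1-based inclusive.  Positions are
    a bookkeeping device for the interval/metagene machinery, not a genome
    model.
    """
    rows = []
    offsets: dict[str, int] = {}
    for i, chrom in enumerate(chromosomes):
        k = offsets.get(chrom, 0)
        start = k * spacing + 1_000 + 1
        rows.append({"gene_id": f"g{i:05d}", "chromosome": chrom,
                     "start": start, "end": start + length - 1,
                     "strand": "+" if k % 2 == 0 else "-"})
        offsets[chrom] = k + 1
    return pd.DataFrame(rows).set_index("gene_id")


def _sex_expectations(cfg: SimulationConfig, rng: np.random.Generator,
                      chromosomes: np.ndarray):
    """Per-gene zygotic expression expectation for each sex.

    The per-allele rate is half the two-dose baseline.  Hermaphrodites carry
    two X doses repressed ``dcc_repression``-fold; males carry one unrepressed
    dose.  Sex-biased genes multiply the hermaphrodite expectation only.
    """
    n = len(chromosomes)
    baseline = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, n)
    on_x = chromosomes == "X"
    herm = np.where(on_x, baseline / cfg.dcc_repression, baseline)
    male = np.where(on_x, baseline / 2.0, baseline)
    n_biased = int(round(cfg.sex_bias_fraction * n))
    biased = rng.choice(n, size=n_biased, replace=False)
    sign = rng.choice([-1.0, 1.0], size=n_biased)
    herm = herm.copy()
    herm[biased] *= 2.0 ** (sign * cfg.sex_bias_log2)
    bias_flag = np.zeros(n)
    bias_flag[biased] = sign
    return baseline, herm, male, bias_flag


def simulate_expression_study(cfg: SimulationConfig):
    """Simulate an FPKM table for hermaphrodite vs mixed-sex samples.

    Returns ``(table, truth, catalog)``.  The mixed-sex expectation per gene
    is the male-fraction-weighted mean of the hermaphrodite and male
    expectations (an equal XX/XO pool by default).  Maternal genes add a
    decaying transcript pool shared between sexes at every stage; zygotic
    transcription switches on at the gene's activation stage.  The truth
    table records, per stage, the exact expected log2(hermaphrodite /
    mixed-sex) ratio.
    """
    rng = np.random.default_rng(cfg.seed)
    chromosomes = _assign_chromosomes(cfg.n_genes, cfg.x_fraction, rng)
    catalog = make_gene_catalog(chromosomes)
    genes = catalog.index
    n = cfg.n_genes

    baseline, herm_z, male_z, bias_flag = _sex_expectations(cfg, rng, chromosomes)
    mixed_z = (1.0 - cfg.male_fraction) * herm_z + cfg.male_fraction * male_z

    maternal = rng.random(n) < cfg.maternal_fraction
    maternal_pool = np.where(maternal, baseline, 0.0)
    # zygotic activation: most genes switch on at the early-embryo burst, a
    # configurable fraction only at the comma stage (the "newly expressed"
    # class downstream analyses look for); maternal genes anywhere earlier
    late = rng.random(n) < cfg.late_activation_fraction
    activation = np.where(late, STAGE_ORDER.index("comma"),
                          STAGE_ORDER.index("early_embryo"))
    activation = np.where(maternal, rng.integers(0, 2, n), activation)

    sd_ln = cfg.replicate_sd_log2 * LN2
    cols, design_rows, truth_cols = {}, [], {}
    for stage in cfg.stages:
        s = STAGE_ORDER.index(stage)
        pool = maternal_pool * cfg.maternal_decay ** s
        active = (activation <= s).astype(float)
        mu_h = pool + active * herm_z
        mu_m = pool + active * mixed_z
        # genes can be entirely silent before activation; keep a tiny floor so
        # FPKM stays positive (the expressed-gene filter removes these anyway)
        mu_h = np.maximum(mu_h, 1e-3)
        mu_m = np.maximum(mu_m, 1e-3)
        truth_cols[f"true_log2_ratio__{stage}"] = np.log2(mu_h / mu_m)
        for sex, mu in (("hermaphrodite", mu_h), ("mixed_sex", mu_m)):
            for r in range(1, cfg.n_replicates + 1):
                sid = f"{sex}__{stage}__rep{r}"
                noise = np.exp(rng.normal(0.0, sd_ln, n))
                cols[sid] = mu * noise
                design_rows.append({
                    "sample_id": sid, "condition": "wild-type",
                    "sex_composition": sex, "stage": stage,
                    "replicate": r, "species": "elegans"})

    table = ExpressionTable(pd.DataFrame(cols, index=genes),
                            pd.DataFrame(design_rows).set_index("sample_id"),
                            unit="FPKM")
    truth = pd.DataFrame({"chromosome": chromosomes,
                          "maternal": maternal,
                          "activation_stage": [STAGE_ORDER[a] for a in activation],
                          "sex_bias": bias_flag,
                          **truth_cols}, index=genes)
    return table, truth, catalog


# ---------------------------------------------------------------------------
# spike-in RNA study
# ---------------------------------------------------------------------------

def simulate_spikein_rna_study(cfg: SimulationConfig,
                               spike_fraction: float = 1.0 / 11.0,
                               n_spike_genes: int = 2_000,
                               depth: int = 5_000_000):
    """Simulate a two-species spike-in RNA-seq count study (wt vs mutant).

    The default ``spike_fraction`` (1/11) corresponds to mixing 10,000 target
    organisms with 1,000 spike organisms of comparable RNA content.  Target
    genes in the mutant are multiplied by ``cfg.chromosome_shifts`` (per
    chromosome; default no change); spike-gene expectations are identical
    across conditions.  Each library is sequenced to a fixed depth, so a
    uniform true repression of target genes inflates the apparent abundance of
    everything else — the library-size artifact the spike-in correction
    removes.

    Returns ``(table, truth, catalog)``; spike genes carry chromosome ``"I"``
    bookkeeping but species ``briggsae`` in the truth table, and gene ids
    prefixed ``cb_``.
    """
    if not 0.0 < spike_fraction < 1.0:
        raise ValueError(f"spike_fraction must be in (0, 1), got {spike_fraction}")
    rng = np.random.default_rng(cfg.seed)
    chromosomes = _assign_chromosomes(cfg.n_genes, cfg.x_fraction, rng)
    catalog = make_gene_catalog(chromosomes)
    target_ids = list(catalog.index)
    spike_ids = [f"cb_{i:05d}" for i in range(n_spike_genes)]

    target_mass = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd,
                                    cfg.n_genes)
    # hermaphrodite (XX) target population: X genes carry two doses repressed
    # dcc_repression-fold, i.e. 1/dcc_repression of the two-dose baseline
    target_mass = np.where(chromosomes == "X",
                           target_mass / cfg.dcc_repression, target_mass)
    spike_mass = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd,
                                   n_spike_genes)
    # scale spike mass so it is spike_fraction of the wild-type library
    spike_mass *= (spike_fraction / (1.0 - spike_fraction)
                   * target_mass.sum() / spike_mass.sum())

    shifts = cfg.chromosome_shifts or {}
    shift_vec = np.array([shifts.get(c, 1.0) for c in chromosomes])

    sd_ln = cfg.replicate_sd_log2 * LN2
    cols, design_rows = {}, []
    for condition, tshift in (("wt", np.ones(cfg.n_genes)), ("mutant", shift_vec)):
        for r in range(1, cfg.n_replicates + 1):
            mass = np.concatenate([
                target_mass * tshift * np.exp(rng.normal(0, sd_ln, cfg.n_genes)),
                spike_mass * np.exp(rng.normal(0, sd_ln, n_spike_genes))])
            p = mass / mass.sum()
            counts = rng.poisson(depth * p)
            sid = f"{condition}__rep{r}"
            cols[sid] = counts
            design_rows.append({
                "sample_id": sid, "condition": condition,
                "sex_composition": "hermaphrodite", "stage": "L1",
                "replicate": r, "species": "elegans"})

    genes = pd.Index(target_ids + spike_ids, name="gene_id")
    table = ExpressionTable(pd.DataFrame(cols, index=genes),
                            pd.DataFrame(design_rows).set_index("sample_id"),
                            unit="counts")
    truth = pd.DataFrame({
        "chromosome": np.concatenate([chromosomes, ["spike"] * n_spike_genes]),
        "species": ["elegans"] * cfg.n_genes + ["briggsae"] * n_spike_genes,
        "true_log2_fold": np.concatenate([np.log2(shift_vec),
                                          np.zeros(n_spike_genes)]),
    }, index=genes)
    return table, truth, catalog


# ---------------------------------------------------------------------------
# spike-in ChIP study
# ---------------------------------------------------------------------------

@dataclass
class ChipSimConfig:
    """Parameters of a simulated spike-in ChIP study (wt vs mutant).

    ``me1_gain`` multiplies the mutant's expected ChIP signal per chromosome
    group (``autosomes`` / ``X``); the input and the spike-species extract are
    unaffected.  Poisson sampling of bin counts is applied last.
    """

    chrom_lengths: dict = field(default_factory=lambda: {
        "I": 1_000_000, "II": 1_000_000, "III": 1_000_000,
        "IV": 1_000_000, "V": 1_000_000, "X": 700_000})
    spike_chrom_lengths: dict = field(default_factory=lambda: {
        "cbI": 600_000, "cbII": 600_000})
    bin_size: int = 200
    gene_body_enrichment: float = 3.0
    x_wide_enrichment: float = 2.0
    chip_depth: float = 30.0
    input_depth: float = 30.0
    me1_gain: dict = field(default_factory=lambda: {"autosomes": 1.0, "X": 1.0})
    spike_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if any(g < 0 for g in self.me1_gain.values()):
            raise ValueError("me1_gain values must be >= 0")


def tile_genes(chrom_lengths: dict, spacing: int = 10_000,
               length: int = 3_000, prefix: str = "g") -> pd.DataFrame:
    """Regularly spaced genes (alternating strand) for ChIP simulations."""
    rows, i = [], 0
    for chrom, clen in chrom_lengths.items():
        pos = 2_000
        k = 0
        while pos + length < clen - 2_000:
            rows.append({"gene_id": f"{prefix}{i:05d}", "chromosome": chrom,
                         "start": pos + 1, "end": pos + length,
                         "strand": "+" if k % 2 == 0 else "-"})
            pos += spacing
            i += 1
            k += 1
    return pd.DataFrame(rows).set_index("gene_id")


def _gene_body_mask(chrom_lengths: dict, bin_size: int,
                    annotation: pd.DataFrame) -> dict[str, np.ndarray]:
    masks = {c: np.zeros(int(np.ceil(n / bin_size)), dtype=bool)
             for c, n in chrom_lengths.items()}
    for _, g in annotation.iterrows():
        if g["chromosome"] in masks:
            b0 = (int(g["start"]) - 1) // bin_size
            b1 = int(np.ceil(int(g["end"]) / bin_size))
            masks[g["chromosome"]][b0:b1] = True
    return masks


def _gain_for(chrom: str, me1_gain: dict) -> float:
    if chrom in me1_gain:
        return me1_gain[chrom]
    return me1_gain["X"] if chrom == "X" else me1_gain["autosomes"]


def simulate_chip_study(cfg: ChipSimConfig, annotation: pd.DataFrame | None = None,
                        spike_annotation: pd.DataFrame | None = None):
    """Simulate ChIP+input coverage for wt and mutant, target and spike species.

    Returns ``(tracks, truth, annotation, spike_annotation)`` where ``tracks``
    maps ``(condition, assay, species)`` to a raw :class:`CoverageTrack`
    (conditions ``wt``/``mutant``, assays ``chip``/``input``, species
    ``target``/``spike``) and ``truth`` records the per-chromosome true gain.
    """
    rng = np.random.default_rng(cfg.seed)
    if annotation is None:
        annotation = tile_genes(cfg.chrom_lengths, prefix="g")
    if spike_annotation is None:
        spike_annotation = tile_genes(cfg.spike_chrom_lengths, prefix="cb")
    bad = set(annotation["chromosome"]) - set(cfg.chrom_lengths)
    if bad:
        raise ValueError(f"annotation chromosomes {sorted(bad)} not in config lengths")

    def expected(chrom_lengths, ann, x_wide: float, depth: float):
        masks = _gene_body_mask(chrom_lengths, cfg.bin_size, ann)
        lam = {}
        for chrom, mask in masks.items():
            base = np.full(mask.shape, 1.0)
            base[mask] += cfg.gene_body_enrichment
            if chrom == "X":
                base += x_wide
            lam[chrom] = base * depth
        return lam

    def flat(chrom_lengths, depth: float):
        return {c: np.full(int(np.ceil(n / cfg.bin_size)), depth)
                for c, n in chrom_lengths.items()}

    chip_t = expected(cfg.chrom_lengths, annotation, cfg.x_wide_enrichment,
                      cfg.chip_depth)
    input_t = flat(cfg.chrom_lengths, cfg.input_depth)
    sf = cfg.spike_fraction / (1.0 - cfg.spike_fraction)
    chip_s = expected(cfg.spike_chrom_lengths, spike_annotation, 0.0,
                      cfg.chip_depth * sf)
    input_s = flat(cfg.spike_chrom_lengths, cfg.input_depth * sf)

    tracks = {}
    for condition in ("wt", "mutant"):
        gains = ({c: _gain_for(c, cfg.me1_gain) for c in cfg.chrom_lengths}
                 if condition == "mutant" else
                 {c: 1.0 for c in cfg.chrom_lengths})
        lam_chip_t = {c: chip_t[c] * gains[c] for c in chip_t}
        for assay, lam_t, lam_s in (("chip", lam_chip_t, chip_s),
                                    ("input", input_t, input_s)):
            tracks[(condition, assay, "target")] = CoverageTrack(
                cfg.bin_size, {c: rng.poisson(v).astype(float)
                               for c, v in lam_t.items()}, "raw")
            tracks[(condition, assay, "spike")] = CoverageTrack(
                cfg.bin_size, {c: rng.poisson(v).astype(float)
                               for c, v in lam_s.items()}, "raw")

    truth = pd.DataFrame({
        "chromosome": list(cfg.chrom_lengths),
        "true_gain": [_gain_for(c, cfg.me1_gain) for c in cfg.chrom_lengths],
    }).set_index("chromosome")
    return tracks, truth, annotation, spike_annotation
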