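"""Configuration-driven orchestration of the full analysis on synthetic data.

A single seeded configuration drives simulate -> dosage statistics ->
equivalence calls -> stage clustering -> mixture model -> spike-in RNA and
ChIP corrections -> metagene profiles, writing TSV/BED/report files, a plain
run log with retained/excluded counts at every filter, and a machine-readable
manifest.  Outputs are deterministic given the configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (chip_profiles, dosage_stats, equivalence, io_core,
               mixture_model, spikein_norm, stage_clusters, synthetic_data)


@dataclass
class PipelineConfig:
    """All thresholds, sizes and seeds of an end-to-end run."""

    seed: int = 0
    n_genes: int = 6_000
    x_fraction: float = 0.13
    dcc_repression: float = 1.0
    maternal_fraction: float = 0.0
    n_replicates: int = 3
    expressed_fpkm: float = 1.0
    confidence: float = 0.95
    max_change: float = 0.30
    cluster_k: int = 5
    mixture_k: tuple = (2, 3)
    spike_fraction: float = 1.0 / 11.0
    autosome_shift: float = 0.8
    me1_gain_autosomes: float = 10.0
    me1_gain_x: float = 6.0
    chip_bin_size: int = 200
    flank: int = 2_000
    stages: tuple = ("simulate", "dosage", "equivalence", "clusters",
                     "mixture", "spike_rna", "spike_chip", "chip_profile")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise io_core.ValidationError(f"unknown config keys: {unknown}")
        d = dict(d)
        for key in ("mixture_k", "stages"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the configured stages; returns the manifest dict.

    Every stage logs record counts at each filter; any stage error aborts
    with the stage name in the message and an ``INCOMPLETE`` marker in the
    log.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    manifest: dict = {"config": dataclasses.asdict(config), "outputs": {},
                      "metrics": {}}

    def log(msg: str) -> None:
        log_lines.append(msg)

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", **kw)
        manifest["outputs"][name] = str(path)

    state: dict = {}
    try:
        for stage in config.stages:
            log(f"stage {stage}: start")
            _STAGES[stage](config, state, outdir, manifest, log, save)
            log(f"stage {stage}: done")
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        log(f"INCOMPLETE: stage failed: {exc}")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        raise io_core.ValidationError(f"pipeline stage failed: {exc}") from exc

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_simulate(cfg, state, outdir, manifest, log, save):
    sim_cfg = synthetic_data.SimulationConfig(
        n_genes=cfg.n_genes, x_fraction=cfg.x_fraction,
        dcc_repression=cfg.dcc_repression,
        maternal_fraction=cfg.maternal_fraction,
        n_replicates=cfg.n_replicates,
        stages=("two_cell", "early_embryo", "comma"), seed=cfg.seed)
    table, truth, catalog = synthetic_data.simulate_expression_study(sim_cfg)
    state.update(table=table, truth=truth, catalog=catalog)
    io_core.write_expression_table(table, outdir / "expression.tsv",
                                   outdir / "design.tsv")
    manifest["outputs"]["expression.tsv"] = str(outdir / "expression.tsv")
    save(truth, "truth.tsv")
    io_core.write_gene_annotation(catalog, outdir / "catalog.tsv")
    manifest["outputs"]["catalog.tsv"] = str(outdir / "catalog.tsv")
    log(f"simulated {cfg.n_genes} genes, "
        f"{table.values.shape[1]} samples, dcc_repression={cfg.dcc_repression}")


def _split_sexes(cfg, state, stage="early_embryo"):
    table = state["table"]
    design = table.design
    herm = table.subset_samples(design.index[
        (design["sex_composition"] == "hermaphrodite") & (design["stage"] == stage)])
    mixed = table.subset_samples(design.index[
        (design["sex_composition"] == "mixed_sex") & (design["stage"] == stage)])
    herm_f = io_core.filter_expressed(herm, cfg.expressed_fpkm)
    mixed_f = io_core.filter_expressed(mixed, cfg.expressed_fpkm)
    return herm, mixed, herm_f, mixed_f


def _stage_dosage(cfg, state, outdir, manifest, log, save):
    herm, mixed, herm_f, mixed_f = _split_sexes(cfg, state)
    log(f"expressed filter (> {cfg.expressed_fpkm} FPKM): hermaphrodite "
        f"{len(herm_f.genes)}/{len(herm.genes)} retained, "
        f"mixed_sex {len(mixed_f.genes)}/{len(mixed.genes)} retained")
    ratios = dosage_stats.compute_log2_ratios(herm_f, mixed_f, cfg.confidence)
    state["ratios"] = ratios
    save(ratios, "ratios.tsv", index_label="gene_id")
    summary = dosage_stats.chromosome_summary(ratios, state["catalog"])
    save(summary, "chromosome_summary.tsv")
    tests = dosage_stats.x_vs_autosome_test(ratios, state["catalog"], "greater")
    save(tests, "x_vs_autosome.tsv")
    truth = state["truth"]
    truth_med = (truth["true_log2_ratio__early_embryo"]
                 .groupby(truth["chromosome"]).median())
    manifest["metrics"]["chromosome_median_log2"] = summary["median"].to_dict()
    manifest["metrics"]["chromosome_true_median_log2"] = truth_med.to_dict()
    for c in summary.index:
        log(f"chromosome {c}: median log2 {summary.loc[c, 'median']:.4f} "
            f"(truth {truth_med.get(c, float('nan')):.4f}, "
            f"n={summary.loc[c, 'n']})")


def _stage_equivalence(cfg, state, outdir, manifest, log, save):
    _, _, herm_f, mixed_f = _split_sexes(cfg, state)
    calls = equivalence.call_similar_expression(
        herm_f, mixed_f, cfg.confidence, cfg.max_change)
    save(calls, "equivalence_calls.tsv", index_label="gene_id")
    summary = equivalence.similarity_summary(calls, state["catalog"])
    save(summary, "equivalence_summary.tsv")
    n_sim = int(summary.loc["genome", "n_similar"])
    log(f"similarly expressed: {n_sim} of "
        f"{int(summary.loc['genome', 'n_assessed'])} assessed "
        f"({summary.loc['genome', 'percent']:.1f}%)")
    manifest["metrics"]["n_similar"] = n_sim


def _stage_clusters(cfg, state, outdir, manifest, log, save):
    table = state["table"]
    avg = io_core.average_replicates(table)
    herm_cols = [s for s in avg.samples if "hermaphrodite" in s]
    matrix = avg.values[herm_cols]
    stage_names = [avg.design.loc[c, "stage"] for c in herm_cols]
    order = np.argsort([synthetic_data.STAGE_ORDER.index(s) for s in stage_names])
    matrix = matrix.iloc[:, order]
    labels, centers, sse = stage_clusters.kmeans_cluster(
        matrix, cfg.cluster_k, seed=cfg.seed)
    rising = stage_clusters.identify_rising_cluster(
        centers, earlier_cols=[0], later_cols=[len(matrix.columns) - 1])
    classes, flagged = stage_clusters.classify_new_expression(
        matrix.iloc[:, 0], matrix.iloc[:, -1], labels,
        rising if rising is not None else -1,
        low=cfg.expressed_fpkm)
    out = pd.DataFrame({"cluster": labels, "class": classes})
    save(out, "clusters.tsv", index_label="gene_id")
    n_new = int((classes != stage_clusters.CLASS_OTHER).sum())
    log(f"k-means k={cfg.cluster_k} SSE={sse:.1f}; rising cluster {rising}; "
        f"newly expressed {n_new}; missing-stage flagged {len(flagged)}")
    manifest["metrics"]["n_newly_expressed"] = n_new


def _stage_mixture(cfg, state, outdir, manifest, log, save):
    ratios = state["ratios"]
    chrom = state["catalog"].loc[ratios.index, "chromosome"]
    xvals = ratios.loc[chrom == "X", "log2_ratio"].to_numpy()
    fits = [mixture_model.fit_gaussian_mixture(xvals, k, seed=cfg.seed)
            for k in cfg.mixture_k]
    fit, interp = mixture_model.select_and_interpret(fits)
    report = {"k": fit.k, "weights": fit.weights.tolist(),
              "means": fit.means.tolist(), "sds": fit.sds.tolist(),
              "loglik": fit.loglik, "bic": fit.bic,
              "interpretation": interp}
    with open(outdir / "mixture_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    manifest["outputs"]["mixture_report.json"] = str(outdir / "mixture_report.json")
    manifest["metrics"]["mixture"] = report
    log(f"mixture on X log2 ratios: K={fit.k}, means "
        f"{np.round(fit.means, 3).tolist()}, interpretation {interp}")


def _stage_spike_rna(cfg, state, outdir, manifest, log, save):
    shifts = {c: cfg.autosome_shift for c in io_core.AUTOSOMES}
    sim_cfg = synthetic_data.SimulationConfig(
        n_genes=cfg.n_genes, x_fraction=cfg.x_fraction,
        n_replicates=cfg.n_replicates, chromosome_shifts=shifts,
        seed=cfg.seed + 1)
    table, truth, _ = synthetic_data.simulate_spikein_rna_study(
        sim_cfg, spike_fraction=cfg.spike_fraction)
    spike_genes = truth.index[truth["species"] == "briggsae"]
    ratios, corr = spikein_norm.rna_spike_correction(table, spike_genes)
    save(ratios, "spike_rna_ratios.tsv", index_label="gene_id")
    chrom = truth.loc[ratios.index, "chromosome"]
    med = ratios.groupby(chrom).median()
    save(med, "spike_rna_medians.tsv")
    manifest["metrics"]["spike_rna"] = {
        "slope": corr.slope, "intercept": corr.intercept,
        "autosome_uncorrected_median":
            float(med.loc[list(io_core.AUTOSOMES), "log2_uncorrected"].median()),
        "autosome_corrected_median":
            float(med.loc[list(io_core.AUTOSOMES), "log2_corrected"].median()),
        "x_corrected_median": float(med.loc["X", "log2_corrected"]),
    }
    log(f"spike RNA regression: slope {corr.slope:.3f}, intercept "
        f"{corr.intercept:.3f} on {corr.n_spike_genes} spike genes; injected "
        f"autosomal shift {cfg.autosome_shift} (log2 {np.log2(cfg.autosome_shift):.3f})")


def _stage_spike_chip(cfg, state, outdir, manifest, log, save):
    chip_cfg = synthetic_data.ChipSimConfig(
        bin_size=cfg.chip_bin_size,
        me1_gain={"autosomes": cfg.me1_gain_autosomes, "X": cfg.me1_gain_x},
        seed=cfg.seed + 2)
    tracks, truth, annotation, _ = synthetic_data.simulate_chip_study(chip_cfg)
    state.update(chip_tracks=tracks, chip_annotation=annotation,
                 chip_cfg=chip_cfg)
    masses = spikein_norm.track_read_masses(tracks)
    save(masses, "chip_read_masses.tsv", index=False)
    factor = spikein_norm.chip_spike_factor(masses)
    report = {"global": factor.global_factor, **factor.per_chromosome}
    with open(outdir / "chip_spike_factor.json", "w") as fh:
        json.dump(report, fh, indent=2)
    manifest["outputs"]["chip_spike_factor.json"] = str(outdir / "chip_spike_factor.json")
    manifest["metrics"]["chip_spike_factor"] = report
    manifest["metrics"]["chip_true_gain"] = truth["true_gain"].to_dict()
    log("chip spike factors: " +
        ", ".join(f"{c}={v:.2f}" for c, v in factor.per_chromosome.items()) +
        f" (truth autosomes {cfg.me1_gain_autosomes}, X {cfg.me1_gain_x})")


def _stage_chip_profile(cfg, state, outdir, manifest, log, save):
    tracks = state["chip_tracks"]
    annotation = state["chip_annotation"]
    norm = chip_profiles.normalize_enrichment(
        tracks[("wt", "chip", "target")], tracks[("wt", "input", "target")])
    io_core.write_bedgraph(norm, outdir / "wt_enrichment.bedgraph")
    manifest["outputs"]["wt_enrichment.bedgraph"] = str(outdir / "wt_enrichment.bedgraph")
    profile = chip_profiles.metagene_profile(
        norm, annotation, anchor="TSS", flank=cfg.flank,
        groups="by_chromosome")
    save(profile, "metagene_tss.tsv", index=False)
    x_mean = profile.loc[profile["group"] == "X", "mean"].mean()
    a_mean = profile.loc[profile["group"] != "X", "mean"].mean()
    log(f"metagene TSS: mean X enrichment {x_mean:.3f}, "
        f"mean autosome enrichment {a_mean:.3f}")
    manifest["metrics"]["metagene_x_mean"] = float(x_mean)
    manifest["metrics"]["metagene_autosome_mean"] = float(a_mean)


_STAGES = {
    "simulate": _stage_simulate,
    "dosage": _stage_dosage,
    "equivalence": _stage_equivalence,
    "clusters": _stage_clusters,
    "mixture": _stage_mixture,
    "spike_rna": _stage_spike_rna,
    "spike_chip": _stage_spike_chip,
    "chip_profile": _stage_chip_profile,
}
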