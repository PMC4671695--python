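"""ChIP coverage normalization, consensus peaks and metagene profiles.

Coverage tracks are fixed-bin approximations of per-base signal (bin_size=1
recovers per-base exactly).  Normalization divides each track by its own
genome-wide median over non-mitochondrial bins and subtracts input from
ChIP; z-standardization uses the presumed background, i.e. all bins outside
the supplied peak intervals.  Metagene profiles average strand-oriented
windows anchored at the TSS, TES or intergenic midpoints.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_core import CoverageTrack, ValidationError


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _genome_median(track: CoverageTrack) -> float:
    vals = np.concatenate([v for c, v in track.values.items() if c != "MtDNA"])
    if len(vals) == 0:
        raise ValidationError("no non-mitochondrial bins")
    return float(np.median(vals))


def normalize_enrichment(chip: CoverageTrack, input_: CoverageTrack) -> CoverageTrack:
    """Median-normalize ChIP and input, then subtract input from ChIP.

    Each track is divided by its own genome-wide median over non-MtDNA bins
    (MtDNA bins are carried through but never influence the median).  The
    result is invariant to rescaling either library by any positive constant.
    """
    if not chip.same_bins(input_):
        raise ValidationError("ChIP and input tracks have different bin structure")
    med_c, med_i = _genome_median(chip), _genome_median(input_)
    if med_c == 0 or med_i == 0:
        raise ValidationError("genome-wide median coverage is zero")
    values = {c: chip.values[c] / med_c - input_.values[c] / med_i
              for c in chip.values}
    return chip.copy_with(values, "normalized")


def merge_replicates(tracks) -> CoverageTrack:
    """Per-bin arithmetic mean across replicate tracks."""
    tracks = list(tracks)
    if not tracks:
        raise ValidationError("no tracks to merge")
    first = tracks[0]
    for t in tracks[1:]:
        if not first.same_bins(t):
            raise ValidationError("replicate tracks have mismatched bins")
    values = {c: np.mean([t.values[c] for t in tracks], axis=0)
              for c in first.values}
    return first.copy_with(values, first.value_kind)


def _peak_bin_mask(track: CoverageTrack, peaks: pd.DataFrame | None) -> dict:
    """Boolean mask of bins overlapping any peak (BED, 0-based half-open)."""
    masks = {c: np.zeros(len(v), dtype=bool) for c, v in track.values.items()}
    if peaks is None or len(peaks) == 0:
        return masks
    bs = track.bin_size
    for chrom, start, end in peaks[["chrom", "start", "end"]].itertuples(index=False):
        if chrom not in masks or end <= start:
            continue
        b0 = int(start) // bs
        b1 = int(np.ceil(end / bs))
        masks[chrom][b0:min(b1, len(masks[chrom]))] = True
    return masks


def standardize_zscore(track: CoverageTrack, peaks: pd.DataFrame | None = None,
                       per_chromosome: bool = False) -> CoverageTrack:
    """Z-score transformation against the peak-excluded background.

    The background is every bin not overlapping a peak; its mean and SD
    standardize *all* bins.  With no peaks the background is the whole
    genome.  ``per_chromosome`` standardizes each chromosome against its own
    background instead of the genome-wide one.
    """
    masks = _peak_bin_mask(track, peaks)

    def stats_of(vals: np.ndarray):
        mu = float(vals.mean())
        sd = float(vals.std())
        if sd == 0:
            raise ValidationError("background standard deviation is zero")
        return mu, sd

    values = {}
    if per_chromosome:
        for c, v in track.values.items():
            mu, sd = stats_of(v[~masks[c]])
            values[c] = (v - mu) / sd
    else:
        background = np.concatenate([v[~masks[c]] for c, v in track.values.items()])
        mu, sd = stats_of(background)
        values = {c: (v - mu) / sd for c, v in track.values.items()}
    return track.copy_with(values, "zscore")


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def consensus_peaks(combined_peaks: pd.DataFrame, replicate_peaks) -> pd.DataFrame:
    """Combined peaks supported by a strict majority of replicate peak sets.

    A combined peak is retained iff it overlaps (by >= 1 bp) a peak in more
    than half of the replicate sets — for two replicates that means both.
    The output is always a subset of the combined peaks.
    """
    replicate_peaks = list(replicate_peaks)
    if not replicate_peaks:
        raise ValidationError("need at least one replicate peak set")
    trees = []
    for peaks in replicate_peaks:
        byc: dict[str, IntervalTree] = {}
        for chrom, start, end in peaks[["chrom", "start", "end"]].itertuples(index=False):
            if end > start:
                byc.setdefault(chrom, IntervalTree()).addi(int(start), int(end))
        trees.append(byc)
    need = len(replicate_peaks) / 2.0
    keep = []
    for i, (chrom, start, end) in enumerate(
            combined_peaks[["chrom", "start", "end"]].itertuples(index=False)):
        support = sum(1 for byc in trees
                      if chrom in byc and byc[chrom].overlap(int(start), int(end)))
        if support > need:
            keep.append(i)
    return combined_peaks.iloc[keep].reset_index(drop=True)


def call_peaks_simple(track: CoverageTrack, quantile: float = 0.99,
                      min_bins: int = 2) -> pd.DataFrame:
    """Naive threshold peak caller (not MACS): runs of bins above a quantile.

    Exists only to make the pipeline self-contained on synthetic data; real
    studies should supply externally called peaks as BED.
    """
    all_vals = np.concatenate(list(track.values.values()))
    cutoff = np.quantile(all_vals, quantile)
    rows = []
    bs = track.bin_size
    for chrom, vals in track.values.items():
        above = vals > cutoff
        edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
        for b0, b1 in zip(edges[::2], edges[1::2]):
            if b1 - b0 >= min_bins:
                rows.append({"chrom": chrom, "start": int(b0 * bs),
                             "end": int(b1 * bs)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------

def intergenic_midpoints(catalog: pd.DataFrame, chrom_lengths: dict,
                         min_distance: int = 5_000) -> pd.DataFrame:
    """Midpoints of intergenic gaps whose every base is > min_distance from
    any gene (gap length must exceed 2*min_distance)."""
    rows = []
    for chrom, clen in chrom_lengths.items():
        genes = catalog[catalog["chromosome"] == chrom].sort_values("start")
        # merged occupied intervals, 0-based half-open
        occupied = []
        for s, e in zip(genes["start"] - 1, genes["end"]):
            if occupied and s <= occupied[-1][1]:
                occupied[-1] = (occupied[-1][0], max(occupied[-1][1], e))
            else:
                occupied.append((int(s), int(e)))
        bounds = [0] + [b for iv in occupied for b in iv] + [clen]
        for gs, ge in zip(bounds[::2], bounds[1::2]):
            if ge - gs > 2 * min_distance:
                rows.append({"chrom": chrom, "position": (gs + ge) // 2})
    return pd.DataFrame(rows, columns=["chrom", "position"])


def _anchor_positions(catalog: pd.DataFrame, anchor: str) -> pd.DataFrame:
    """0-based anchor coordinate per gene: TSS = start for +, end for -."""
    plus = catalog["strand"] == "+"
    if anchor == "TSS":
        pos = np.where(plus, catalog["start"] - 1, catalog["end"] - 1)
    elif anchor == "TES":
        pos = np.where(plus, catalog["end"] - 1, catalog["start"] - 1)
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    return pd.DataFrame({"chrom": catalog["chromosome"], "position": pos,
                         "strand": catalog["strand"]}, index=catalog.index)


def expression_quintiles(expression: pd.Series) -> pd.Series:
    """Quintile label (Q1 lowest .. Q5 highest) per gene; exact fifths."""
    ranks = expression.rank(method="first")
    return pd.qcut(ranks, 5, labels=["Q1", "Q2", "Q3", "Q4", "Q5"]).astype(str)


def metagene_profile(track: CoverageTrack, catalog: pd.DataFrame,
                     anchor: str = "TSS", flank: int = 2_000,
                     groups: str | dict = "by_chromosome",
                     expression: pd.Series | None = None,
                     chrom_lengths: dict | None = None,
                     min_intergenic_distance: int = 5_000) -> pd.DataFrame:
    """Average signal over strand-oriented windows around gene anchors.

    ``anchor`` is ``TSS``, ``TES`` or ``intergenic_midpoint``; windows span
    ``-flank..+flank`` at bin resolution and are reversed for minus-strand
    genes so +x is always downstream in gene orientation.  ``groups`` is
    ``"by_chromosome"``, ``"expression_quintiles"`` (requires
    ``expression``), or a mapping of group name to gene ids.  Positions
    falling off a chromosome contribute nothing (position-wise n accounting).
    Output columns: group, position, mean, n.
    """
    bs = track.bin_size
    w = flank // bs
    positions = np.arange(-w, w + 1) * bs

    if anchor == "intergenic_midpoint":
        if chrom_lengths is None:
            chrom_lengths = {c: track.chromosome_length(c) for c in track.values}
        mids = intergenic_midpoints(catalog, chrom_lengths,
                                    min_intergenic_distance)
        anchors = pd.DataFrame({"chrom": mids["chrom"],
                                "position": mids["position"],
                                "strand": "+"},
                               index=pd.Index(range(len(mids)), name="anchor"))
        membership = {"intergenic": anchors.index}
    else:
        anchors = _anchor_positions(catalog, anchor)
        if groups == "by_chromosome":
            membership = {c: idx for c, idx in
                          anchors.groupby("chrom").groups.items()}
        elif groups == "expression_quintiles":
            if expression is None:
                raise ValueError("expression_quintiles grouping needs an "
                                 "expression Series")
            q = expression_quintiles(expression.loc[anchors.index.intersection(
                expression.index)])
            membership = {lab: idx for lab, idx in q.groupby(q).groups.items()}
        elif isinstance(groups, dict):
            membership = {name: pd.Index(g) for name, g in groups.items()}
        else:
            raise ValueError(f"unknown groups spec {groups!r}")

    rows = []
    for name, members in membership.items():
        members = pd.Index(members).intersection(anchors.index)
        if len(members) == 0:
            continue  # empty groups reported absent
        total = np.zeros(len(positions))
        count = np.zeros(len(positions), dtype=int)
        sub = anchors.loc[members]
        for chrom, pos, strand in sub[["chrom", "position", "strand"]].itertuples(index=False):
            if chrom not in track.values:
                continue
            vals = track.values[chrom]
            center = int(pos) // bs
            idx = center + np.arange(-w, w + 1)
            ok = (idx >= 0) & (idx < len(vals))
            window = np.full(len(positions), np.nan)
            window[ok] = vals[idx[ok]]
            if strand == "-":
                window = window[::-1]
            good = ~np.isnan(window)
            total[good] += window[good]
            count[good] += 1
        with np.errstate(invalid="ignore"):
            mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        rows.append(pd.DataFrame({"group": name, "position": positions,
                                  "mean": mean, "n": count}))
    if not rows:
        return pd.DataFrame(columns=["group", "position", "mean", "n"])
    return pd.concat(rows, ignore_index=True)
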