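"""Domain types, readers/writers and basic table hygiene.

All coordinate-convention conversions live here: gene catalogs are 1-based
inclusive (GFF convention), coverage tracks and BED intervals are 0-based
half-open.  The allowed chromosome names are the six C. elegans nuclear
chromosomes plus the mitochondrial genome.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

CHROMOSOMES = ("I", "II", "III", "IV", "V", "X", "MtDNA")
AUTOSOMES = ("I", "II", "III", "IV", "V")

DESIGN_COLUMNS = ("condition", "sex_composition", "stage", "replicate", "species")
#: replicate grouping key: everything except the replicate index
REPLICATE_GROUP_KEY = ["condition", "sex_composition", "stage", "species"]

SEX_COMPOSITIONS = ("hermaphrodite", "mixed_sex")
STAGES = ("two_cell", "early_embryo", "comma", "mixed_embryo", "L1", "L3",
          "young_adult", "oocyte")
SPECIES = ("elegans", "briggsae")

CATALOG_COLUMNS = ["chromosome", "start", "end", "strand"]


class ValidationError(ValueError):
    """Raised when an input file or table violates a domain invariant."""


# ---------------------------------------------------------------------------
# gene catalogs
# ---------------------------------------------------------------------------

def validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene catalog (index gene_id; chromosome/start/end/strand).

    Coordinates are 1-based inclusive.  Raises :class:`ValidationError`
    naming the first offending record.
    """
    missing = [c for c in CATALOG_COLUMNS if c not in catalog.columns]
    if missing:
        raise ValidationError(f"catalog missing columns: {missing}")
    if catalog.index.has_duplicates:
        dup = catalog.index[catalog.index.duplicated()][0]
        raise ValidationError(f"duplicate gene_id: {dup!r}")
    bad_chrom = ~catalog["chromosome"].isin(CHROMOSOMES)
    if bad_chrom.any():
        gene = catalog.index[bad_chrom][0]
        name = catalog.loc[gene, "chromosome"]
        raise ValidationError(
            f"unknown chromosome {name!r} for gene {gene!r}; "
            f"allowed: {CHROMOSOMES}")
    bad_coord = (catalog["start"] > catalog["end"]) | (catalog["start"] < 1)
    if bad_coord.any():
        gene = catalog.index[bad_coord][0]
        raise ValidationError(f"invalid coordinates for gene {gene!r}: "
                              f"start must satisfy 1 <= start <= end")
    bad_strand = ~catalog["strand"].isin(["+", "-"])
    if bad_strand.any():
        gene = catalog.index[bad_strand][0]
        raise ValidationError(f"invalid strand for gene {gene!r}")
    out = catalog[CATALOG_COLUMNS].copy()
    out.index.name = "gene_id"
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    return out


_GFF_ID_RE = re.compile(r"(?:^|;)\s*(?:ID|gene_id|Name)=([^;]+)")


def read_gene_annotation(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read a gene catalog from GFF3, BED6 or TSV.

    GFF3 and TSV coordinates are kept 1-based inclusive; BED is converted
    from 0-based half-open (``start+1``, ``end`` unchanged).  The format is
    inferred from the file suffix unless ``fmt`` is given.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {"gff": "gff3", "gff3": "gff3", "bed": "bed", "tsv": "tsv",
               "txt": "tsv"}.get(suffix.lstrip("."), None)
        if fmt is None:
            raise ValidationError(f"cannot infer annotation format from {path.name!r}")
    if fmt == "gff3":
        raw = pd.read_csv(path, sep="\t", comment="#", header=None,
                          names=["seqid", "source", "type", "start", "end",
                                 "score", "strand", "frame", "attributes"],
                          dtype={"seqid": str})
        raw = raw[raw["type"] == "gene"]
        ids = []
        for attr in raw["attributes"]:
            m = _GFF_ID_RE.search(str(attr))
            if not m:
                raise ValidationError(f"GFF3 gene line without ID attribute: {attr!r}")
            ids.append(m.group(1).removeprefix("gene:"))
        catalog = pd.DataFrame({
            "chromosome": raw["seqid"].values, "start": raw["start"].values,
            "end": raw["end"].values, "strand": raw["strand"].values,
        }, index=pd.Index(ids, name="gene_id"))
    elif fmt == "bed":
        raw = pd.read_csv(path, sep=r"\s+", header=None,
                          names=["chrom", "start", "end", "name", "score", "strand"],
                          dtype={"chrom": str, "name": str})
        catalog = pd.DataFrame({
            "chromosome": raw["chrom"].values,
            "start": raw["start"].values + 1,      # 0-based half-open -> 1-based
            "end": raw["end"].values,
            "strand": raw["strand"].values,
        }, index=pd.Index(raw["name"], name="gene_id"))
    elif fmt == "tsv":
        raw = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
        need = {"gene_id", "chromosome", "start", "end", "strand"}
        if not need.issubset(raw.columns):
            raise ValidationError(f"TSV catalog missing columns: {sorted(need - set(raw.columns))}")
        catalog = raw.set_index("gene_id")
    else:
        raise ValidationError(f"unknown annotation format {fmt!r}")
    return validate_catalog(catalog)


def write_gene_annotation(catalog: pd.DataFrame, path: str | Path) -> None:
    """Write a catalog as TSV (1-based inclusive coordinates)."""
    validate_catalog(catalog).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTable:
    """Genes x samples nonnegative expression matrix with a sample design.

    Parameters
    ----------
    values
        DataFrame, index gene_id, columns sample_id, nonnegative.
    design
        DataFrame indexed by sample_id with columns
        condition / sex_composition / stage / replicate / species.
    unit
        ``"FPKM"`` or ``"counts"``.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    unit: str = "FPKM"

    def __post_init__(self) -> None:
        if self.unit not in ("FPKM", "counts"):
            raise ValidationError(f"unknown unit {self.unit!r}")
        missing = [c for c in DESIGN_COLUMNS if c not in self.design.columns]
        if missing:
            raise ValidationError(f"design missing columns: {missing}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene_id: {dup!r}")
        vcols, dcols = set(self.values.columns), set(self.design.index)
        if vcols != dcols:
            only_v = sorted(vcols - dcols)
            only_d = sorted(dcols - vcols)
            raise ValidationError(
                f"design/sample mismatch: samples without design {only_v}, "
                f"design rows without samples {only_d}")
        arr = self.values.to_numpy()
        if (arr < 0).any():
            gi, si = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value at gene {self.values.index[gi]!r}, "
                f"sample {self.values.columns[si]!r}")
        key = self.design.reset_index()[list(DESIGN_COLUMNS)]
        if key.duplicated().any():
            raise ValidationError("duplicate (condition, sex_composition, stage, "
                                  "replicate, species) design row")
        # align design row order to column order; normalize axis names
        self.design = self.design.loc[self.values.columns]
        self.values.index.name = "gene_id"
        self.values.columns.name = None
        self.design.index.name = "sample_id"

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def replicate_groups(self):
        """Group sample ids by (condition, sex_composition, stage, species)."""
        return self.design.groupby(REPLICATE_GROUP_KEY, sort=False, observed=True).groups

    def subset_genes(self, genes) -> "ExpressionTable":
        return replace(self, values=self.values.loc[genes])

    def subset_samples(self, samples) -> "ExpressionTable":
        return ExpressionTable(self.values[list(samples)],
                               self.design.loc[list(samples)], self.unit)

    def equals(self, other: "ExpressionTable") -> bool:
        return (self.unit == other.unit
                and self.values.equals(other.values)
                and self.design.equals(other.design))


def read_expression_table(path: str | Path, design_path: str | Path,
                          unit: str = "FPKM") -> ExpressionTable:
    """Read a genes-x-samples TSV plus its sample-design TSV."""
    values = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
    values.index = values.index.astype(str)
    values.index.name = "gene_id"
    design = pd.read_csv(design_path, sep="\t", index_col="sample_id")
    design.index = design.index.astype(str)
    return ExpressionTable(values, design, unit=unit)


def write_expression_table(table: ExpressionTable, path: str | Path,
                           design_path: str | Path) -> None:
    """Write the matrix and design TSVs; full float precision (repr), so the
    paired reader round-trips exactly."""
    table.values.to_csv(path, sep="\t")
    table.design.to_csv(design_path, sep="\t", index_label="sample_id")


def filter_expressed(table: ExpressionTable, threshold: float = 1.0) -> ExpressionTable:
    """Keep genes whose mean FPKM across all samples is strictly above threshold.

    The strict inequality is deliberate: a gene sitting exactly at the cutoff
    is not called expressed.  Gene order is preserved; counts-unit tables are
    rejected (convert to FPKM first).
    """
    if table.unit != "FPKM":
        raise ValidationError("filter_expressed requires FPKM units; got counts")
    keep = table.values.mean(axis=1) > threshold
    return replace(table, values=table.values.loc[keep])


def average_replicates(table: ExpressionTable) -> ExpressionTable:
    """Arithmetic mean per replicate group; one output column per group."""
    groups = table.replicate_groups()
    if not groups:
        raise ValidationError("no replicate groups in design")
    cols, rows = {}, []
    for key, sample_ids in groups.items():
        if len(sample_ids) == 0:
            raise ValidationError(f"replicate group {key} has zero columns")
        condition, sex, stage, species = key
        name = f"{condition}__{sex}__{stage}__{species}"
        cols[name] = table.values[list(sample_ids)].mean(axis=1)
        rows.append({"sample_id": name, "condition": condition,
                     "sex_composition": sex, "stage": stage,
                     "replicate": 1, "species": species})
    design = pd.DataFrame(rows).set_index("sample_id")
    return ExpressionTable(pd.DataFrame(cols, index=table.genes), design, table.unit)


def replicate_correlation(table: ExpressionTable):
    """Pairwise Spearman correlation between samples plus a clustering leaf order.

    Returns ``(rho, leaf_order, undefined_samples)``.  ``rho`` is symmetric
    with unit diagonal; correlations involving a constant column are NaN and
    the offending samples are listed in ``undefined_samples`` (never silently
    imputed).  The leaf order comes from average-linkage clustering of 1-rho
    distances, with NaN distances replaced by the neutral value 1 for ordering
    purposes only.
    """
    if table.values.shape[1] < 2:
        raise ValidationError("need >= 2 samples")
    if table.values.shape[0] < 3:
        raise ValidationError("need >= 3 genes")
    arr = table.values.to_numpy(dtype=float)
    constant = arr.std(axis=0) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns handled below
        res = spearmanr(arr)
    if arr.shape[1] == 2:  # scipy returns a scalar for two columns
        r = float(res.statistic)
        rho_arr = np.array([[1.0, r], [r, 1.0]])
    else:
        rho_arr = np.array(res.statistic, dtype=float)
    rho_arr[constant, :] = np.nan
    rho_arr[:, constant] = np.nan
    np.fill_diagonal(rho_arr, 1.0)
    rho = pd.DataFrame(rho_arr, index=table.samples, columns=table.samples)
    dist = 1.0 - np.nan_to_num(rho_arr, nan=0.0)
    np.fill_diagonal(dist, 0.0)
    order = leaves_list(average(squareform(dist, checks=False)))
    leaf_order = [table.samples[i] for i in order]
    undefined = list(table.samples[constant])
    return rho, leaf_order, undefined


# ---------------------------------------------------------------------------
# coverage tracks
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    """Fixed-bin per-chromosome signal.

    Bins are 0-based half-open ``[i*bin_size, (i+1)*bin_size)``.
    ``value_kind`` is one of ``raw`` (nonnegative counts), ``normalized``
    (median-scaled enrichment) or ``zscore``.
    """

    bin_size: int
    values: dict[str, np.ndarray]
    value_kind: str = "raw"

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValidationError("bin_size must be positive")
        if self.value_kind not in ("raw", "normalized", "zscore"):
            raise ValidationError(f"unknown value_kind {self.value_kind!r}")
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}
        if self.value_kind == "raw":
            for c, v in self.values.items():
                if (v < 0).any():
                    raise ValidationError(f"negative raw coverage on {c}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.values)

    def chromosome_length(self, chrom: str) -> int:
        return len(self.values[chrom]) * self.bin_size

    def same_bins(self, other: "CoverageTrack") -> bool:
        return (self.bin_size == other.bin_size
                and set(self.values) == set(other.values)
                and all(len(self.values[c]) == len(other.values[c])
                        for c in self.values))

    def copy_with(self, values: dict[str, np.ndarray], value_kind: str) -> "CoverageTrack":
        return CoverageTrack(self.bin_size, values, value_kind)


def read_bedgraph(path: str | Path, bin_size: int,
                  chrom_lengths: dict[str, int],
                  value_kind: str = "raw") -> CoverageTrack:
    """Read a bedGraph into fixed-size bins.

    Each record's value is assigned to every bin it covers; records must be
    bin-aligned or at least not straddle bins with conflicting values (last
    write wins within a bin).
    """
    values = {c: np.zeros(int(np.ceil(n / bin_size))) for c, n in chrom_lengths.items()}
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str}, float_precision="round_trip")
    for chrom, start, end, value in df.itertuples(index=False):
        if chrom not in values:
            raise ValidationError(f"bedGraph chromosome {chrom!r} not in chrom_lengths")
        b0, b1 = int(start) // bin_size, int(np.ceil(end / bin_size))
        values[chrom][b0:b1] = value
    return CoverageTrack(bin_size, values, value_kind)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write one bedGraph record per bin (runs are not merged, so the paired
    reader round-trips exactly)."""
    with open(path, "w") as fh:
        for chrom, vals in track.values.items():
            starts = np.arange(len(vals)) * track.bin_size
            for s, v in zip(starts, vals):
                fh.write(f"{chrom}\t{s}\t{s + track.bin_size}\t{float(v)!r}\n")


# ---------------------------------------------------------------------------
# BED intervals (peaks)
# ---------------------------------------------------------------------------

def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Read BED3+ intervals (0-based half-open) into chrom/start/end."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str})
    if (df["start"] > df["end"]).any():
        raise ValidationError("BED interval with start > end")
    return df


def write_bed_intervals(intervals: pd.DataFrame, path: str | Path) -> None:
    intervals[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False,
                                                index=False)
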