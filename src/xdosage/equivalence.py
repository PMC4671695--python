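"""Statistically-similar-expression calling via confidence-interval bounds.

A gene is called similarly expressed between two conditions when the entire
two-sided confidence interval around its log2 expression ratio stays within a
maximum allowed change (default: 95% CI inside a 30% change, i.e.
+/- log2(1.30) ~ 0.3785 log2 units).  This is deliberately stricter than "not
differentially expressed": replicate variability alone can make a gene fail a
differential test without being demonstrably similar.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dosage_stats import compute_log2_ratios
from .io_core import ExpressionTable

CALL_SIMILAR = "similar"
CALL_NOT_SIMILAR = "not_similar"
CALL_NOT_ASSESSABLE = "not_assessable"


def equivalence_threshold_log2(max_change: float) -> float:
    """Symmetric log2 bound for a maximum relative change (0.30 -> 0.3785)."""
    if max_change <= 0:
        raise ValueError("max_change must be > 0")
    return float(np.log2(1.0 + max_change))


def call_similar_expression(table_a: ExpressionTable, table_b: ExpressionTable,
                            confidence: float = 0.95,
                            max_change: float = 0.30,
                            ci_family: str = "pooled") -> pd.DataFrame:
    """Equivalence calls from two-sample t confidence intervals on log2 ratios.

    A gene is ``similar`` iff ``ci_low >= -log2(1+max_change)`` and
    ``ci_high <= +log2(1+max_change)``.  Genes with fewer than two replicates
    on either side (no CI) are ``not_assessable`` — reported, never called
    similar.  Apply the expressed-gene filter upstream.  ``ci_family`` is
    ``pooled`` (equal-variance t, nominal coverage under the replicate-noise
    model) or ``welch``.
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    threshold = equivalence_threshold_log2(max_change)
    ratios = compute_log2_ratios(table_a, table_b, confidence=confidence,
                                 ci_family=ci_family)
    assessable = ratios["ci_low"].notna() & ratios["ci_high"].notna()
    inside = (ratios["ci_low"] >= -threshold) & (ratios["ci_high"] <= threshold)
    call = np.where(~assessable, CALL_NOT_ASSESSABLE,
                    np.where(inside, CALL_SIMILAR, CALL_NOT_SIMILAR))
    out = ratios.copy()
    out["threshold_log2"] = threshold
    out["call"] = call
    return out


def similarity_summary(calls: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome similar/assessed counts and percentages, plus a genome row.

    ``percent`` is 100 * n_similar / n_assessed (NaN where nothing was
    assessable); per-chromosome counts sum exactly to the genome row.
    """
    chrom = catalog.loc[calls.index, "chromosome"]
    rows = []
    for c, idx in calls.groupby(chrom).groups.items():
        sub = calls.loc[idx, "call"]
        n_sim = int((sub == CALL_SIMILAR).sum())
        n_ass = int((sub != CALL_NOT_ASSESSABLE).sum())
        rows.append({"chromosome": c, "n_similar": n_sim, "n_assessed": n_ass,
                     "n_not_assessable": len(sub) - n_ass,
                     "percent": 100.0 * n_sim / n_ass if n_ass else np.nan})
    out = pd.DataFrame(rows).set_index("chromosome")
    genome = {"n_similar": out["n_similar"].sum(),
              "n_assessed": out["n_assessed"].sum(),
              "n_not_assessable": out["n_not_assessable"].sum()}
    genome["percent"] = (100.0 * genome["n_similar"] / genome["n_assessed"]
                         if genome["n_assessed"] else np.nan)
    out.loc["genome"] = genome
    for col in ("n_similar", "n_assessed", "n_not_assessable"):
        out[col] = out[col].astype(int)
    return out
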