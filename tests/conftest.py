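import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from xdosage.io_core import ExpressionTable

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


def build_table(values, genes=None, samples=None, *, condition="wild-type",
                sex="hermaphrodite", stage="early_embryo", species="elegans",
                unit="FPKM", design_rows=None):
    """Small-table builder: values is 2-D (genes x samples)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_genes, n_samples = values.shape
    genes = list(genes) if genes is not None else [f"g{i}" for i in range(n_genes)]
    samples = (list(samples) if samples is not None
               else [f"s{i}" for i in range(n_samples)])
    if design_rows is None:
        design_rows = [{"sample_id": s, "condition": condition,
                        "sex_composition": sex, "stage": stage,
                        "replicate": i + 1, "species": species}
                       for i, s in enumerate(samples)]
    design = pd.DataFrame(design_rows).set_index("sample_id")
    return ExpressionTable(pd.DataFrame(values, index=genes, columns=samples),
                           design, unit=unit)


@pytest.fixture
def toy_catalog():
    """Six genes: four autosomal (I, II), two on X."""
    return pd.DataFrame(
        {"chromosome": ["I", "I", "II", "II", "X", "X"],
         "start": [100, 500, 100, 500, 100, 500],
         "end": [200, 600, 200, 600, 200, 600],
         "strand": ["+", "-", "+", "-", "+", "-"]},
        index=pd.Index(["g0", "g1", "g2", "g3", "g4", "g5"], name="gene_id"))
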