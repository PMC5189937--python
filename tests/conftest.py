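import numpy as np
import pandas as pd
import pytest

from icindex.io import ExpressionMatrix


def make_matrix(values, cell_ids=None, gene_ids=None, roles=None,
                time_points=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from a raw array with minimal metadata."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    cell_ids = cell_ids or [f"c{i}" for i in range(n)]
    gene_ids = gene_ids or [f"g{j}" for j in range(m)]
    df = pd.DataFrame(values, index=cell_ids, columns=gene_ids)
    meta = pd.DataFrame({
        "time_point": time_points if time_points is not None else "t0",
        "treatment": "none", "fraction": "M"}, index=cell_ids)
    role_series = pd.Series(roles if roles is not None else "target",
                            index=gene_ids)
    return ExpressionMatrix(values=df, cell_meta=meta, gene_roles=role_series)


@pytest.fixture
def toy_matrix():
    """6 cells x 4 genes integer matrix with a shared profile plus variation."""
    rng = np.random.default_rng(42)
    base = np.array([1.0, 3.0, 5.0, 2.0])
    values = base + rng.integers(-2, 3, size=(6, 4)).astype(float)
    return make_matrix(values)


@pytest.fixture
def cq_files(tmp_path):
    """A tiny Cq table + LOD map on disk (2 cells, 3 genes, triplicates)."""
    cq = tmp_path / "cq.csv"
    cq.write_text(
        "Cell,Gene,Replicate,Cq\n"
        # cellA: gata1 detected triplicate, pu1 one passing replicate, gapdh ref
        "cellA,gata1,1,25.0\ncellA,gata1,2,25.2\ncellA,gata1,3,26.0\n"
        "cellA,pu1,1,25.0\ncellA,pu1,2,31.0\ncellA,pu1,3,\n"
        "cellA,gapdh,1,20.0\ncellA,gapdh,2,20.0\ncellA,gapdh,3,20.0\n"
        # cellB: gata1 all beyond LOD, pu1 detected, gapdh ref
        "cellB,gata1,1,31.0\ncellB,gata1,2,32.0\ncellB,gata1,3,\n"
        "cellB,pu1,1,22.0\ncellB,pu1,2,22.4\ncellB,pu1,3,22.2\n"
        "cellB,gapdh,1,19.0\ncellB,gapdh,2,21.0\ncellB,gapdh,3,20.0\n")
    lod = tmp_path / "lod.csv"
    lod.write_text("gene,lod,control\ngata1,30,0\npu1,30,0\ngapdh,32,1\n")
    return cq, lod
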