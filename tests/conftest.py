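from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from setscope.io import CountMatrix
from setscope.de import NormalizedExpression


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 genes x 4 cells with hand-checkable totals."""
    values = np.array(
        [
            [2, 0, 1, 4],
            [0, 0, 0, 0],
            [3, 5, 1, 1],
        ]
    )
    return CountMatrix(
        values=sparse.csr_matrix(values),
        gene_ids=["gA", "gB", "gC"],
        cell_ids=["c1", "c2", "c3", "c4"],
    )


def make_expression(values, identities) -> tuple[NormalizedExpression, pd.DataFrame]:
    """Wrap a dense genes x cells array plus per-cell identity labels."""
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    gene_ids = [f"g{i}" for i in range(n_genes)]
    cell_ids = [f"c{j}" for j in range(n_cells)]
    expr = NormalizedExpression(
        values=sparse.csr_matrix(values), gene_ids=gene_ids, cell_ids=cell_ids
    )
    ann = pd.DataFrame({"cell_id": cell_ids, "identity": list(identities)})
    return expr, ann


@pytest.fixture
def mtx_bundle(tmp_path: Path) -> dict[str, Path]:
    """A 3-gene x 2-cell MatrixMarket triplet with one nonzero (g1, c2) = 5."""
    matrix = tmp_path / "matrix.mtx"
    matrix.write_text(
        "%%MatrixMarket matrix coordinate integer general\n3 2 1\n1 2 5\n"
    )
    genes = tmp_path / "genes.tsv"
    genes.write_text("g1\ng2\ng3\n")
    barcodes = tmp_path / "barcodes.tsv"
    barcodes.write_text("c1\nc2\n")
    return {"matrix": matrix, "genes": genes, "barcodes": barcodes}
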