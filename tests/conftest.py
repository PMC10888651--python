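import numpy as np
import pandas as pd
import pytest

from connexsig.connectivity import ReferenceCompendium
from connexsig.formats_io import DenseMatrixFile


def make_compendium(
    values: np.ndarray,
    genes=None,
    pert_ids=None,
    cell_ids=None,
    n_landmark=None,
    touchstone=None,
) -> ReferenceCompendium:
    """Hand-built reference compendium around an explicit z-score matrix.

    ``pert_ids``/``cell_ids`` are per-column labels (defaults: one compound,
    one cell line).
    """
    values = np.asarray(values, dtype=float)
    n_genes, n_cols = values.shape
    genes = list(genes) if genes is not None else [f"G{i + 1:05d}" for i in range(n_genes)]
    pert_ids = list(pert_ids) if pert_ids is not None else ["BRD-X0001"] * n_cols
    cell_ids = list(cell_ids) if cell_ids is not None else ["A375"] * n_cols
    sig_ids = [f"{p}:{c}:{j + 1}" for j, (p, c) in enumerate(zip(pert_ids, cell_ids))]
    sig_info = pd.DataFrame(
        {
            "sig_id": sig_ids,
            "pert_id": pert_ids,
            "pert_iname": [p.lower() for p in pert_ids],
            "pert_type": ["trt_cp"] * n_cols,
            "cell_id": cell_ids,
        }
    )
    if n_landmark is None:
        n_landmark = n_genes
    gene_info = pd.DataFrame(
        {
            "pr_gene_id": genes,
            "pr_gene_symbol": genes,
            "pr_is_lm": [i < n_landmark for i in range(n_genes)],
            "pr_is_bing": [True] * n_genes,
        }
    )
    return ReferenceCompendium(
        DenseMatrixFile(genes, sig_ids, values), sig_info, gene_info, touchstone=touchstone
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix():
    return DenseMatrixFile(
        row_ids=["g1", "g2", "g3"],
        col_ids=["s1", "s2"],
        values=np.array([[1.0, 2.0], [3.5, -1.25], [0.0, 7.0]]),
    )
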