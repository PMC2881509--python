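import numpy as np
import pandas as pd
import pytest

from overlapkit import ExpressionMatrix, GeneList


def make_matrix(case: np.ndarray, ctrl: np.ndarray, genes=None) -> ExpressionMatrix:
    """Assemble an ExpressionMatrix from case/control value blocks."""
    case = np.atleast_2d(np.asarray(case, dtype=float))
    ctrl = np.atleast_2d(np.asarray(ctrl, dtype=float))
    n_genes = case.shape[0]
    genes = genes or [f"G{i + 1:05d}" for i in range(n_genes)]
    case_ids = [f"case_{j + 1:03d}" for j in range(case.shape[1])]
    ctrl_ids = [f"ctrl_{j + 1:03d}" for j in range(ctrl.shape[1])]
    frame = pd.DataFrame(
        np.hstack([case, ctrl]), index=genes, columns=case_ids + ctrl_ids
    )
    groups = {s: "case" for s in case_ids} | {s: "control" for s in ctrl_ids}
    return ExpressionMatrix(values=frame, groups=groups)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_universe():
    return GeneList(name="universe", genes=[f"U{i:02d}" for i in range(10)])
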