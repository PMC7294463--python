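import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nervenet import CellTypeAnnotation, ExpressionMatrix, GeneSet, make_db


@pytest.fixture
def toy_matrix():
    """3 genes x 4 cells with hand-readable counts."""
    counts = np.array([
        [1, 0, 2, 0],   # GA: detected in cells 0, 2
        [0, 0, 0, 0],   # GB: never detected
        [5, 5, 1, 3],   # GC: detected everywhere
    ])
    return ExpressionMatrix(["Ga", "Gb", "Gc"],
                            ["c0", "c1", "c2", "c3"],
                            sp.csr_matrix(counts))


@pytest.fixture
def toy_annotation():
    return CellTypeAnnotation(pd.DataFrame({
        "cell_id": ["c0", "c1", "c2", "c3"],
        "cell_type": ["alpha", "alpha", "beta", "beta"],
        "dataset": ["d1", "d1", "d1", "d2"],
    }))


@pytest.fixture
def toy_db():
    return make_db([("L1", "R1"), ("L1", "R2"), ("L2", "R2"), ("L3", "R3")])


@pytest.fixture
def toy_genes():
    return GeneSet.from_iterable("toy", ["Ga", "Gb", "Gc"])
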