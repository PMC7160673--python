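import numpy as np
import pandas as pd
import pytest

from kmeopl import FLANK_OFFSETS, RESIDUES, ReaderProfile


def make_profile(matrix, reader_id="reader", methyl_order=3, columns=None):
    """Build a ReaderProfile from a 6-row matrix (rows = P-3..P+3)."""
    cols = list(columns) if columns is not None else list(RESIDUES)
    raw = pd.DataFrame(
        np.asarray(matrix, dtype=float), index=list(FLANK_OFFSETS), columns=cols
    )
    return ReaderProfile(reader_id, methyl_order, raw)


@pytest.fixture
def uniform_profile():
    return make_profile(np.full((6, 19), 250.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
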