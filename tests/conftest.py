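import numpy as np
import pandas as pd
import pytest

from oppti import ExpressionMatrix


def _make_matrix(arr, markers=None, samples=None, source_level="protein"):
    arr = np.asarray(arr, dtype=float)
    markers = markers or [f"M{i + 1}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j + 1}" for j in range(arr.shape[1])]
    values = pd.DataFrame(arr, index=pd.Index(markers, name="marker_id"), columns=samples)
    return ExpressionMatrix(values=values, source_level=source_level)


@pytest.fixture
def make_matrix():
    """Factory building an ExpressionMatrix from a 2-D array."""
    return _make_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
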