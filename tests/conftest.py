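import numpy as np
import pytest

from dsenorm import GroupDesign, IntensityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def design_2x2():
    return GroupDesign({"T1": "treatment", "T2": "treatment",
                        "R1": "reference", "R2": "reference"})


@pytest.fixture
def small_matrix(rng, design_2x2):
    """12 variables x 4 samples, log2 scale, no signal."""
    values = rng.normal(9.0, 1.0, size=(12, 4))
    return IntensityMatrix(values=values,
                           variable_ids=[f"v{i}" for i in range(12)],
                           sample_ids=["T1", "T2", "R1", "R2"],
                           scale="log2")


def make_matrix(values, scale="log2", sample_ids=None, blocks=None):
    values = np.asarray(values, dtype=float)
    n, s = values.shape
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(s)]
    return IntensityMatrix(values=values,
                           variable_ids=[f"v{i}" for i in range(n)],
                           sample_ids=sample_ids, scale=scale, blocks=blocks)
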