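from pathlib import Path

import numpy as np
import pytest

from micelle_qspr.data_io import DescriptorTable
from micelle_qspr.synthetic import SyntheticSpec, generate

#: location a hand-transcribed copy of the study's supplementary data tables
#: (descriptor values + LC per formulation) would live if available
STUDY_FIXTURE = Path(__file__).parent / "data" / "study_table.csv"


def make_table(values, response=None, ids=None, names=None, scale="raw"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return DescriptorTable(
        sample_ids=tuple(ids or [f"S{i}" for i in range(1, n + 1)]),
        descriptor_names=tuple(names or [f"x{j}" for j in range(1, p + 1)]),
        values=values,
        response=None if response is None else np.asarray(response, float),
        response_scale=scale,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_table(rng):
    """10 samples x 4 descriptors with a known linear response."""
    X = rng.standard_normal((10, 4))
    y = 1.5 + 2.0 * X[:, 0] - 0.5 * X[:, 2]
    return make_table(X, response=y, scale="ln")


@pytest.fixture(scope="session")
def default_synthetic():
    """One draw of the default simulated formulation study."""
    return generate(SyntheticSpec(seed=7))
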