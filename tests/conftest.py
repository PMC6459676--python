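import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from renomics import MetaboliteMatrix

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(values, groups, rundays=None, compounds=None):
    """Small MetaboliteMatrix from a 2-D list (compounds x samples)."""
    arr = np.asarray(values, dtype=float)
    samples = [f"s{i + 1}" for i in range(arr.shape[1])]
    compounds = compounds or [f"c{i + 1}" for i in range(arr.shape[0])]
    rundays = rundays or [1] * len(samples)
    return MetaboliteMatrix(
        pd.DataFrame(arr, index=compounds, columns=samples),
        pd.Series(list(groups), index=samples),
        pd.Series(list(rundays), index=samples),
    )


@pytest.fixture
def toy_matrix():
    """Two compounds, six samples, two run-day blocks, one missing value."""
    return make_matrix(
        [[2, 4, 6, 8, 16, 24], [1, 1, 1, np.nan, 2, 2]],
        groups=["A", "A", "A", "B", "B", "B"],
        rundays=[1, 1, 1, 2, 2, 2],
    )
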