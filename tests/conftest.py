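import numpy as np
import pandas as pd
import pytest

from peptidiff import AnalysisMatrix, SimulationConfig


def make_matrix(columns: dict[str, list[float]], groups: dict[str, str],
                mzs=None) -> AnalysisMatrix:
    """Build a small analysis matrix from explicit per-sample columns.

    Use ``np.nan`` for absent cells.
    """
    n = len(next(iter(columns.values())))
    if mzs is None:
        mzs = 1000.0 + 10.0 * np.arange(n)
    table = pd.DataFrame(columns, index=pd.Index(np.asarray(mzs, float), name="m/z"))
    return AnalysisMatrix(table, groups)


@pytest.fixture
def two_group_null_config():
    """Continuous (fully detected) null config at the study's group sizes."""
    return SimulationConfig(
        n_samples_per_group={"PP": 10, "RR": 11},
        n_peaks=1000,
        detection_prob=1.0,
        seed=42,
    )
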