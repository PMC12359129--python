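from pathlib import Path

import numpy as np
import pytest

from hespat import DecisionMatrix

REPO_ROOT = Path(__file__).resolve().parents[1]
SUPPLEMENTARY_DIR = REPO_ROOT / "data" / "supplementary"

# (region, period) -> expected converted-CSV filename, see README data section
SUPPLEMENTARY_FILES = {
    ("European Union", "2019"): "eu_2019.csv",
    ("European Union", "2021"): "eu_2021.csv",
    ("European Union", "2017-2021"): "eu_2017_2021.csv",
    ("African Region", "2019"): "africa_2019.csv",
    ("African Region", "2021"): "africa_2021.csv",
    ("African Region", "2017-2021"): "africa_2017_2021.csv",
    ("Eastern Mediterranean", "2019"): "emr_2019.csv",
    ("Eastern Mediterranean", "2021"): "emr_2021.csv",
    ("Eastern Mediterranean", "2017-2021"): "emr_2017_2021.csv",
}


def supplementary_matrix(region: str, period: str) -> DecisionMatrix:
    """Load one converted supplementary-workbook matrix, or fail.

    The source workbook is an external download (see README, "Obtaining
    the study data"); its sheets must be exported as CSV under
    data/supplementary/ before the full-reproduction checks can run.
    A missing file is a genuine failure of those checks, not a skip:
    they assert reproduction of results this repository cannot carry.
    """
    from hespat import read_decision_matrix

    path = SUPPLEMENTARY_DIR / SUPPLEMENTARY_FILES[(region, period)]
    if not path.exists():
        pytest.fail(
            f"supplementary data not available: {path} "
            "(export the study workbook sheets as CSV — see README, "
            "'Obtaining the study data')"
        )
    return read_decision_matrix(path, period_label=period)


@pytest.fixture
def toy_matrix() -> DecisionMatrix:
    """4 countries x 3 indicators, all benefit, no ties."""
    return DecisionMatrix(
        countries=("A", "B", "C", "D"),
        indicators=("x", "y", "z"),
        scores=np.array(
            [
                [80.0, 60.0, 70.0],
                [50.0, 55.0, 90.0],
                [30.0, 40.0, 65.0],
                [65.0, 70.0, 60.0],
            ]
        ),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_matrix(rng, m=None, n=None, low=1.0, high=99.0) -> np.ndarray:
    m = m or int(rng.integers(3, 10))
    n = n or int(rng.integers(2, 7))
    return rng.uniform(low, high, size=(m, n))
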