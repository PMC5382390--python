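import numpy as np
import pytest

from actifit.config import RunConfig
from actifit.synthetic import CohortConfig, sample_participant


@pytest.fixture(scope="session")
def run_cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def cohort_cfg() -> CohortConfig:
    return CohortConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def male_participant(cohort_cfg):
    return sample_participant(cohort_cfg, "M", np.random.default_rng(7), pid="P0001")


def make_day_cpm(fill: int = 50, blocks: list[tuple[int, int, int]] = ()) -> np.ndarray:
    """A 1440-min cpm day: sleep-window zeros, waking `fill`, plus
    (start_minute, length, cpm) blocks."""
    cpm = np.full(1440, fill, dtype=float)
    cpm[:360] = 0.0
    for start, length, value in blocks:
        cpm[start:start + length] = value
    return cpm
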