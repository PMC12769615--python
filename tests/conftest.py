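import numpy as np
import pytest

import formantmod as fm


@pytest.fixture(scope="session")
def small_cfg() -> fm.SynthConfig:
    """A compact experiment: 12 sampled days, 2 vocalizations/day/type."""
    return fm.SynthConfig(seed=7, vocs_per_day_per_type=2)


@pytest.fixture(scope="session")
def small_days() -> list[int]:
    return sorted(set(int(round(d)) for d in np.linspace(1, 54, 12)))


@pytest.fixture(scope="session")
def small_dataset(small_cfg, small_days) -> list[fm.FormantContour]:
    return fm.simulate_dataset(small_cfg, days=small_days)


@pytest.fixture(scope="session")
def cleaned_dataset(small_dataset):
    cleaned, report = fm.apply_qc(small_dataset)
    return cleaned, report
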