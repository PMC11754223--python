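import numpy as np
import pytest

from meridian.cohort import CohortSpec, ObserverProfile, make_cohort
from meridian.pipeline import StudyConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_cohort():
    return make_cohort(CohortSpec(seed=0))


@pytest.fixture
def observer():
    """A single observer with a lapse-free Weibull and known CSF."""
    return ObserverProfile(
        participant_id="NAS01",
        group="NAS",
        age=22.0,
        sphere=-1.0,
        cylinder=-0.25,
        axis=90.0,
        true_csf={"H": (-1.3, 1.17, 1.7), "V": (-1.3, 1.17, 1.7)},
        psycho_slope=3.0,
        lapse=0.0,
    )


@pytest.fixture(scope="session")
def small_study_config():
    """A scaled-down study used by the pipeline tests."""
    return StudyConfig(
        cohort=CohortSpec(
            n_per_group=4, seed=0, fs=256.0, segment_duration=4.0
        ),
        seed=0,
    )
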