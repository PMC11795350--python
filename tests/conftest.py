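import math

import numpy as np
import pytest

import eegwmnet as ew


@pytest.fixture(scope="session")
def small_cohort():
    return ew.simulate_cohort(n_subjects=8, age_min=20, age_max=81, seed=11)


@pytest.fixture(scope="session")
def subject(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def single_pair_profile():
    """One alpha-coupled pair (O1, O2), quarter-cycle lag, full strength."""
    return ew.CouplingProfile(
        bands={
            "alpha": ew.BandCoupling(
                pairs=(("O1", "O2"),),
                phase_lag=math.pi / 2,
                strength=ew.AgeResponse("constant", {"g": 1.0}),
            )
        }
    )


@pytest.fixture(scope="session")
def coupled_epochs(subject, single_pair_profile):
    return ew.simulate_epochs(subject, "shape", single_pair_profile, 60, seed=21)


@pytest.fixture(scope="session")
def null_epochs(subject):
    return ew.simulate_epochs(subject, "shape", ew.NULL_PROFILE, 60, seed=22)


@pytest.fixture
def sinusoid_epochs():
    """Clean 10-Hz, 20-uV peak sinusoid epochs on all channels."""
    t = np.arange(256) / 256.0
    rng = np.random.default_rng(5)
    phase = rng.uniform(0, 2 * np.pi, size=(12, 30, 1))
    data = 20.0 * np.sin(2 * np.pi * 10.0 * t[None, None, :] + phase)
    return ew.EpochArray(subject_id="SYN", condition="shape", data=data)
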