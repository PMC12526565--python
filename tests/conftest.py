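import numpy as np
import pytest

from nightfall.synth import ActivityScript, NoiseConfig, generate_cohort, generate_trial


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 subjects x 4 trials x 12 s: enough structure for protocol tests."""
    return generate_cohort(n_subjects=2, trials_per_subject=4, seed=42,
                           duration=12.0)


@pytest.fixture(scope="session")
def small_cohort():
    """4 subjects x 6 trials x 20 s: used for the branch-separation tests."""
    return generate_cohort(n_subjects=4, trials_per_subject=6, seed=11,
                           duration=20.0)


@pytest.fixture()
def fall_script():
    return ActivityScript(activity_kind="fall_forward", duration=20.0,
                          event_interval=(8.0, 9.5))


@pytest.fixture()
def quiet_noise():
    return NoiseConfig.zero()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
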