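import dataclasses

import numpy as np
import pytest

from mindseye.preprocess import preprocess_cohort
from mindseye.spectral import compute_psd_tensor
from mindseye.synth import SyntheticConfig, generate_cohort

# Small-but-complete simulation settings used throughout the suite: the
# session *design* (three interleaved conditions, rated imagery trials) is
# kept; sensor count, sampling rate and trial length are reduced so a cohort
# generates in well under a second.
SMALL = dict(n_sensors=8, sfreq=256.0, trial_duration=4.0)


def small_config(**overrides) -> SyntheticConfig:
    kw = dict(SMALL, n_participants=6, n_trials_per_condition=4, seed=11)
    kw.update(overrides)
    return SyntheticConfig(**kw)


def null_config(**overrides) -> SyntheticConfig:
    """Conditions share one generative distribution: no condition effects,
    no vividness couplings."""
    kw = dict(condition_effects=[], vividness_couplings=[])
    kw.update(overrides)
    return small_config(**kw)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def small_psd(small_cohort):
    cohort, _ = small_cohort
    epochs = preprocess_cohort(cohort)
    return compute_psd_tensor(epochs, ratings=cohort.metadata)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def replace_cfg(cfg: SyntheticConfig, **kw) -> SyntheticConfig:
    return dataclasses.replace(cfg, **kw)
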