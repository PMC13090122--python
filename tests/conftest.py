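import numpy as np
import pytest

from ppgage.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-calibration cohort, n=300, canonical seed."""
    cfg = CohortConfig(n=300, seed=0)
    subjects, waveforms = generate_cohort(cfg)
    return cfg, subjects, waveforms


@pytest.fixture(scope="session")
def det_cohort():
    """Fully deterministic (noise-free) cohort for parameter-recovery tests."""
    cfg = CohortConfig.deterministic(n=1200, seed=3)
    subjects, waveforms = generate_cohort(cfg)
    return cfg, subjects, waveforms


@pytest.fixture(scope="session")
def det_arrays(det_cohort):
    cfg, subjects, waveforms = det_cohort
    ages = np.array([s.age for s in subjects])
    wav = np.stack([w.samples for w in waveforms])
    return ages, wav


@pytest.fixture(scope="session")
def trained_smolk(det_arrays):
    """SMoLK fitted on the first 1000 deterministic subjects (shared)."""
    from ppgage.models import SmolkAgeModel, TrainConfig

    ages, wav = det_arrays
    return SmolkAgeModel(ages[:1000], wav[:1000]).fit(TrainConfig(seed=11))


@pytest.fixture(scope="session")
def trained_resnet(det_arrays):
    from ppgage.models import ResnetAgeModel, TrainConfig

    ages, wav = det_arrays
    return ResnetAgeModel(ages[:1000], wav[:1000]).fit(TrainConfig(seed=11))
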