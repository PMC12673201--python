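import numpy as np
import pytest

from stenosisnet import PhantomConfig, generate_patient_volume


@pytest.fixture(scope="session")
def clean_config() -> PhantomConfig:
    """Noise-free, blur-free, straight-tube phantom for exact-value checks."""
    return PhantomConfig(
        n_patients=1,
        segments_per_patient=2,
        stenosis_prevalence=0.0,
        vessel_radius=3.0,
        lumen_intensity=300.0,
        background_intensity=60.0,
        blur_sigma=0.0,
        noise_sigma=0.0,
        curvature_max=0.0,
        patient_scale_sigma=0.0,
        volume_shape=(48, 48, 48),
        seed=0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-patient noisy cohort with guaranteed positives, shared across tests."""
    cfg = PhantomConfig(
        n_patients=6,
        segments_per_patient=6,
        stenosis_prevalence=0.35,
        volume_shape=(64, 64, 64),
        seed=42,
    )
    cohort = []
    for p in range(cfg.n_patients):
        vol, truths = generate_patient_volume(cfg, p)
        cohort.append((truths[0].patient_id, vol, truths))
    return cfg, cohort


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
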