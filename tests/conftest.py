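import numpy as np
import pytest

from melscape.synthetic import CallerNoise, CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest noisy cohort shared by read-only tests."""
    cfg = CohortConfig(n_subtype_a=14, n_subtype_b=10, seed=11)
    bundle, truth = generate_cohort(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free channels, generous depths: filter should recover truth exactly."""
    cfg = CohortConfig(
        n_subtype_a=6,
        n_subtype_b=4,
        seed=5,
        purity_range=(0.5, 0.9),
        depth_mean=150.0,
        caller_noise=CallerNoise(
            fn1=0.0, fn2=0.0, fp1=0.0, fp2=0.0, artifact_rate=0.0, clustered_indel_rate=0.0
        ),
        snp_leak_rate=0.0,
        segment_log2_noise_sd=0.0,
    )
    bundle, truth = generate_cohort(cfg)
    return cfg, bundle, truth


@pytest.fixture
def rng():
    return np.random.default_rng(123)
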