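import numpy as np
import pytest

import connectocam as cc


@pytest.fixture(scope="session")
def atlas():
    return cc.default_atlas()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_connectome(rng, subject_id="s1", metric="NOS", density=0.5):
    """Random sparse symmetric non-negative 84x84 matrix."""
    upper = np.triu(rng.random((84, 84)) * (rng.random((84, 84)) < density), k=1)
    vals = upper + upper.T
    return cc.ConnectomeMatrix(subject_id, metric, vals * 100)


@pytest.fixture
def small_cohort():
    """Tiny deterministic cohort with a strong planted effect."""
    cfg = cc.CohortConfig(n_per_group=6, seed=7, subject_noise_sd=0.1,
                          effects=(cc.EffectSpec(effect_size=3.0),))
    return cc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_arch():
    """A very small architecture for fast optimization tests."""
    return cc.ArchitectureSpec(conv_channels=(2, 3), fc_units=(8, 2))
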