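import numpy as np
import pytest

from beatbp.model import ModelConfig, ResUTransRPE
from beatbp.sim import SimConfig, generate_record


@pytest.fixture(scope="session")
def clean_record():
    """Two-minute low-noise simulated record with ground truth."""
    cfg = SimConfig(duration_s=120.0, seed=42, noise_sigma=0.01,
                    baseline_wander_amp=0.05)
    return generate_record(cfg, subject_id="fixture")


@pytest.fixture(scope="session")
def eight_min_record():
    """Record of at least 8 min (passes the length screen)."""
    return generate_record(SimConfig(duration_s=480.0, seed=7),
                           subject_id="eightmin")


def tiny_config(**over) -> ModelConfig:
    base = dict(n=6, l0=16, l=16, d=2, r=1, heads=4, layers=2,
                base_channels=2, mlp_expansion=2, dropout=0.0)
    base.update(over)
    return ModelConfig(**base)


@pytest.fixture()
def tiny_model():
    return ResUTransRPE(tiny_config(), seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
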