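import numpy as np
import pytest
from hypothesis import settings

from ctperf import GammaVariateParams, StudyConfig, TimeEnhancementCurve, evaluate_curve

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture
def pancreas_params() -> GammaVariateParams:
    """Tissue-like curve: peak 100 delta-HU at 35 s, bolus shape 9."""
    return GammaVariateParams(y_max=100.0, t_max=35.0, alpha=9.0)


@pytest.fixture
def aorta_params() -> GammaVariateParams:
    """Aorta-like curve: peak 350 delta-HU at 14 s, bolus shape 9."""
    return GammaVariateParams(y_max=350.0, t_max=14.0, alpha=9.0)


def sampled_curve(
    params: GammaVariateParams,
    baseline: float = 0.0,
    n_frames: int = 40,
    interval: float = 1.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TimeEnhancementCurve:
    """Sample a gamma-variate curve on the standard 40-frame/1.5 s grid."""
    t = np.arange(n_frames) * interval
    v = baseline + evaluate_curve(params, t)
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.size)
    return TimeEnhancementCurve(t, v)


@pytest.fixture
def noiseless_study_config() -> StudyConfig:
    return StudyConfig(noise_sd=0.0, seed=7)
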