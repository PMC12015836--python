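import numpy as np
import pytest

from alphatse.containers import EpochSet
from alphatse.simulate import SimulationParams


def quiet_params(seed: int = 0, n_trials: int = 30, **kwargs) -> SimulationParams:
    """Params with every stochastic/artifact component switched off; turn
    individual components back on via attribute edits in the test."""
    p = SimulationParams(seed=seed, n_subjects=1, n_trials_per_condition=n_trials)
    p.p3.amplitude_uv = {"ST": 0.0, "DT": 0.0}
    p.p3.amplitude_sd_uv = 0.0
    p.evoked_alpha.amplitude_uv = 0.0
    p.induced_alpha.ongoing_amplitude_uv = 0.0
    p.induced_alpha.depth = 0.0
    p.noise.rms_uv = 0.0
    p.artifacts.blink_rate_per_trial = 0.0
    p.artifacts.heog_fraction = 0.0
    p.artifacts.ocular_noise_rms_uv = 0.0
    for key, value in kwargs.items():
        setattr(p, key, value)
    return p


def make_epochs(data: np.ndarray, fs: float = 500.0, t0_ms: float = -200.0,
                labels=None, **kwargs) -> EpochSet:
    n_tr, n_ch, n_sp = data.shape
    labels = labels if labels is not None else [f"ch{i}" for i in range(n_ch)]
    times = t0_ms + (1000.0 / fs) * np.arange(n_sp)
    return EpochSet(np.asarray(data, float), times, list(labels), **kwargs)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
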