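import pytest

from hbci.config import PipelineConfig
from hbci.pipeline import preprocess_eeg, preprocess_nirs
from hbci.simulate import (
    SimulationConfig,
    simulate_session,
    strong_effect_config,
)


@pytest.fixture(scope="session")
def strong_epochs():
    """Preprocessed epochs of the strong-effect synthetic subject (90 trials)."""
    cfg = PipelineConfig()
    eeg_rec, nirs_rec = simulate_session(strong_effect_config(seed=123))
    return preprocess_eeg(eeg_rec, cfg), preprocess_nirs(nirs_rec, cfg)


@pytest.fixture(scope="session")
def small_session():
    """A short default-preset session (6 trials/class) for plumbing tests."""
    sim = SimulationConfig(n_trials_per_class=6, seed=42)
    return simulate_session(sim)
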