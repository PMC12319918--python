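import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import fusnpx
from fusnpx.config import TrialTimeline

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def timeline() -> TrialTimeline:
    return TrialTimeline()


@pytest.fixture(scope="session")
def small_session():
    """A small noisy SC-like session (two contrasts, few trials)."""
    cfg = fusnpx.sc_config(n_trials=4, contrasts=(0.0, 100.0))
    return fusnpx.gen_session(cfg, seed=11)


@pytest.fixture(scope="session")
def noiseless_session():
    """Deterministic rates, zero Doppler noise: the forward model exactly."""
    cfg = fusnpx.sc_config(
        n_trials=2, contrasts=(0.0, 100.0), deterministic_rates=True
    )
    gt = dataclasses.replace(cfg.ground_truth, noise_sd=0.0)
    return fusnpx.gen_session(cfg.replace(ground_truth=gt), seed=5)


@pytest.fixture(scope="session")
def sc_batch():
    """20 seeded SC-config sessions analyzed end to end (shared across
    recovery assertions to keep the suite within budget)."""
    return fusnpx.summarize_batch(
        fusnpx.recovery_batch(
            "SC", n_sessions=20, base_seed=1, n_trials=20, n_candidates=2000
        )
    )


@pytest.fixture(scope="session")
def lgn_batch():
    return fusnpx.summarize_batch(
        fusnpx.recovery_batch(
            "LGN", n_sessions=20, base_seed=2, n_trials=20, n_candidates=2000
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
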