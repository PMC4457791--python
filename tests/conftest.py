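"""Shared fixtures: small synthetic cohorts and spectra built at test time."""

import numpy as np
import pytest

from serumpep.simulate import SimulationConfig, simulate_cohort
from serumpep.pipeline import preprocess_cohort


def small_config(**overrides) -> SimulationConfig:
    """A reduced-mass-window, low-background config for fast functional tests.

    The informative peaks (1365-5867 Da) all stay inside the window.
    """
    defaults = dict(
        n_mutant=12, n_wild=12, mz_min=800.0, mz_max=6500.0, grid_step=0.5,
        n_background_peaks=25, seed=7,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """One small simulated cohort preprocessed end to end (session-cached)."""
    cfg = small_config()
    spectra, meta = simulate_cohort(cfg)
    fm = preprocess_cohort(spectra, cfg)
    return cfg, spectra, meta, fm


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
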