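"""Shared fixtures: small, fast synthetic configurations.

``fast_config`` trades realism for speed (narrow m/z window, small grid) and
is used by unit tests; the acceptance tests build the default full-range
study themselves.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from ovimsi.io import StudyDesign
from ovimsi.synth import SyntheticConfig

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


def make_config(**overrides) -> SyntheticConfig:
    """Small single-batch config: 12x12 grid, m/z 700-800, 12 peaks."""
    kw = dict(
        grid=(12, 12),
        mz_range=(700.0, 800.0),
        n_peaks=12,
        n_highmass=0,
        n_up=1,
        n_down=1,
        design=StudyDesign(timepoints=("16w",), modes=("positive",)),
    )
    kw.update(overrides)
    return SyntheticConfig(**kw)


def make_quiet_config(**overrides) -> SyntheticConfig:
    """Deterministic config: no noise, no TIC variation, no jitter, no
    baseline — spectra are exact sums of planted Gaussians."""
    kw = dict(
        noise_sigma=0.0,
        tic_sigma=0.0,
        sample_jitter=0.0,
        baseline_amplitude=0.0,
    )
    kw.update(overrides)
    return make_config(**kw)


@pytest.fixture
def fast_config() -> SyntheticConfig:
    return make_config()


@pytest.fixture
def quiet_config() -> SyntheticConfig:
    return make_quiet_config()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
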