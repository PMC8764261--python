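"""Shared fixtures: small seeded synthetic datasets and montages."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import emodyn as e

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

FS = 128.0


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def montage16():
    return e.default_montage()


@pytest.fixture(scope="session")
def short_cfg(montage16):
    """A fast single-subject configuration for per-trial tests."""
    return e.SimConfig(montage=montage16, n_subjects=1, trials_per_subject=1,
                       trial_duration=16.0)


@pytest.fixture(scope="session")
def clean_quiet_cfg(montage16):
    """Blink-free, low-noise configuration for signal-level checks."""
    return e.SimConfig(montage=montage16, n_subjects=1, trials_per_subject=1,
                       trial_duration=16.0, blink_rate=0.0)


def make_sine(freq: float, duration: float = 8.0, fs: float = FS,
              amplitude: float = 1.0, phase: float = 0.0) -> np.ndarray:
    t = np.arange(int(duration * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t + phase)


@pytest.fixture(scope="session")
def small_dataset():
    """2 subjects x 8 trials, short duration — for table-level plumbing."""
    cfg = e.SimConfig(n_subjects=2, trials_per_subject=8, trial_duration=8.0)
    return e.generate_dataset(cfg, seed=7)
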