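"""Shared fixtures: synthetic signals and small cohorts, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from cardioformant.pcg_io import PcgRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tone(freq: float, duration: float, rate: float, amplitude: float = 0.8,
              noise: float = 0.0, seed: int = 0) -> PcgRecording:
    t = np.arange(int(round(duration * rate))) / rate
    x = amplitude * np.sin(2 * np.pi * freq * t)
    if noise:
        x = x + noise * np.random.default_rng(seed).standard_normal(t.size)
    return PcgRecording(x, rate)


@pytest.fixture
def tone_440():
    """20 s pure 440 Hz tone at the 8 kHz analysis rate."""
    return make_tone(440.0, 20.0, 8000.0)


def fft_peak_hz(x: np.ndarray, rate: float) -> float:
    """Independent oracle: frequency of the largest DFT magnitude bin."""
    spectrum = np.abs(np.fft.rfft(x))
    return float(np.fft.rfftfreq(x.size, 1.0 / rate)[np.argmax(spectrum)])


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort (8 normal / 6 PAH, 8 s) shared across tests."""
    from cardioformant.simulate import SyntheticCohortConfig, synth_cohort

    cfg = SyntheticCohortConfig(n_normal=8, n_pah=6, duration=8.0, seed=42)
    return synth_cohort(cfg)
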