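"""Synthetic multi-site heart-sound cohorts for end-to-end testing.

The generative model is deliberately simple plumbing: periodic S1/S2 bursts
(Gaussian-enveloped low-frequency oscillations at a per-subject heart rate)
plus white noise.  At one designated site both groups additionally carry an
equal-power tonal component built from a small harmonic stack near
``signature_f0``; in the hypertensive group it is a frequency-stable
harmonic stack (ordered, entropy-lowering) while in the normal group the
same stack wobbles rapidly in frequency (disordered, spectrum-spreading).
With ``signature_strength = 0`` the two groups are statistically identical.

All randomness flows from one seed via per-subject spawned generators, so a
cohort is reproducible subject-by-subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .pcg_io import SITES, PcgRecording, write_wav

NORMAL_MPAP_RANGE = (5.0, 24.0)
PAH_MPAP_RANGE = (25.0, 93.0)
PAWP_RANGE = (3.0, 14.0)


@dataclass
class SyntheticCohortConfig:
    n_normal: int = 35
    n_pah: int = 25
    duration: float = 20.0
    rate: float = 4000.0
    heart_rate: tuple[float, float] = (60.0, 140.0)
    signature_site: str = "2LICS"
    signature_f0: float = 300.0
    signature_strength: float = 0.3  # tone RMS relative to unit S1 peak
    signature_stability: float = 0.01  # relative frequency jitter, PAH tone
    signature_harmonics: tuple = (1.0, 0.15)  # harmonic-stack weights
    normal_jitter: float = 0.15  # relative frequency wobble of the normal-group component
    noise_level: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal <= 0 or self.n_pah <= 0:
            raise ParameterError("group counts must be positive")
        if not 0 < self.signature_f0 < self.rate / 2:
            raise ParameterError("signature_f0 must lie below the Nyquist frequency")
        if self.signature_strength < 0 or self.noise_level < 0:
            raise ParameterError("amplitudes must be >= 0")
        if self.signature_site not in SITES:
            raise ParameterError(f"signature_site must be one of {SITES}")
        if self.duration <= 0 or self.rate <= 0:
            raise ParameterError("duration and rate must be positive")


def _smooth_noise(rng: np.random.Generator, n: int, rate: float, step_s: float) -> np.ndarray:
    """Standard-normal control points every ``step_s`` s, linearly interpolated."""
    n_ctrl = max(int(np.ceil(n / rate / step_s)) + 2, 2)
    ctrl = rng.standard_normal(n_ctrl)
    t = np.arange(n) / rate
    return np.interp(t, np.arange(n_ctrl) * step_s, ctrl)


def _add_burst(
    signal: np.ndarray, rate: float, center: float, sigma: float, freq: float,
    phase: float, amplitude: float,
) -> None:
    """Add a Gaussian-enveloped oscillation in place (support limited to 5 sigma)."""
    lo = max(int((center - 5 * sigma) * rate), 0)
    hi = min(int((center + 5 * sigma) * rate) + 1, signal.size)
    if hi <= lo:
        return
    t = np.arange(lo, hi) / rate - center
    signal[lo:hi] += amplitude * np.exp(-0.5 * (t / sigma) ** 2) * np.sin(
        2.0 * np.pi * freq * t + phase
    )


def _base_heart_sound(
    cfg: SyntheticCohortConfig, rng: np.random.Generator, heart_rate: float
) -> np.ndarray:
    n = int(round(cfg.duration * cfg.rate))
    signal = np.zeros(n)
    period = 60.0 / heart_rate
    beat = rng.uniform(0.0, period)
    while beat < cfg.duration + period:
        # S1: lower pitch, wider envelope; S2: higher pitch, narrower
        s1_f = rng.uniform(35.0, 55.0)
        s2_f = rng.uniform(60.0, 90.0)
        _add_burst(signal, cfg.rate, beat, 0.020, s1_f,
                   rng.uniform(0, 2 * np.pi), rng.uniform(0.9, 1.1))
        _add_burst(signal, cfg.rate, beat + 0.33 * period, 0.012, s2_f,
                   rng.uniform(0, 2 * np.pi), rng.uniform(0.6, 0.8))
        beat += period * rng.uniform(0.97, 1.03)
    signal += cfg.noise_level * rng.standard_normal(n)
    return signal


def _tonal_component(
    cfg: SyntheticCohortConfig, rng: np.random.Generator, group: str
) -> np.ndarray:
    """Equal-power spectral component near ``signature_f0``.

    PAH: an ordered, frequency-stable harmonic stack (a vowel-like tone).
    Normal: a disordered, band-limited noise covering the same spectral
    region, so the two groups differ in spectral order, not in power.
    """
    n = int(round(cfg.duration * cfg.rate))
    if group == "PAH":
        # ordered: slow, tiny frequency drift and mild amplitude variation
        jitter, ctrl_step, am_depth = cfg.signature_stability, 0.25, 0.1
    else:
        # disordered: fast, large frequency wobble (chirps within analysis frames)
        jitter, ctrl_step, am_depth = cfg.normal_jitter, 0.03, 0.3
    freq = cfg.signature_f0 * (1.0 + jitter * _smooth_noise(rng, n, cfg.rate, ctrl_step))
    freq = np.clip(freq, 10.0, 0.45 * cfg.rate)
    amp = np.clip(1.0 + am_depth * _smooth_noise(rng, n, cfg.rate, ctrl_step), 0.2, 2.0)
    phase = 2.0 * np.pi * np.cumsum(freq) / cfg.rate
    component = np.zeros(n)
    for h, weight in enumerate(cfg.signature_harmonics, start=1):
        if h * cfg.signature_f0 < 0.45 * cfg.rate:
            component += weight * np.sin(h * phase + rng.uniform(0, 2 * np.pi))
    component *= amp
    rms = np.sqrt(np.mean(component**2))
    if rms > 0:
        component *= cfg.signature_strength / rms
    return component


def synth_heart_sound(
    cfg: SyntheticCohortConfig, group: str, site: str, rng: np.random.Generator,
    heart_rate: float | None = None, subject_id: str = "",
) -> PcgRecording:
    """One synthetic recording for a (group, site) cell."""
    if group not in ("PAH", "normal"):
        raise ParameterError(f"group must be 'PAH' or 'normal', got {group!r}")
    hr = heart_rate if heart_rate is not None else rng.uniform(*cfg.heart_rate)
    signal = _base_heart_sound(cfg, rng, hr)
    if site == cfg.signature_site and cfg.signature_strength > 0:
        signal = signal + _tonal_component(cfg, rng, group)
    peak = np.max(np.abs(signal))
    if peak > 0:
        signal = signal / peak
    return PcgRecording(signal, cfg.rate, site=site, subject_id=subject_id)


@dataclass
class SyntheticCohort:
    """A generated cohort: metadata table plus in-memory recordings."""

    metadata: pd.DataFrame
    recordings: dict = field(repr=False, default_factory=dict)  # (subject_id, site) -> PcgRecording
    config: SyntheticCohortConfig | None = None


def synth_cohort(cfg: SyntheticCohortConfig, outdir=None) -> SyntheticCohort:
    """Generate the full cohort (4 site recordings per subject).

    Normal subjects draw mPAp uniformly in [5, 24] mmHg, hypertensive
    subjects in [25, 93]; wedge pressure is below 15 for everyone.  With
    ``outdir`` set, WAV files and a ``metadata.tsv`` are written in the same
    formats the real pipeline consumes.
    """
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_normal + cfg.n_pah)
    subjects = [(f"N{i + 1:03d}", "normal") for i in range(cfg.n_normal)]
    subjects += [(f"P{i + 1:03d}", "PAH") for i in range(cfg.n_pah)]
    rows = []
    recordings = {}
    for (subject_id, group), seed in zip(subjects, seeds):
        rng = np.random.default_rng(seed)
        lo, hi = NORMAL_MPAP_RANGE if group == "normal" else PAH_MPAP_RANGE
        mpap = rng.uniform(lo, hi)
        pawp = rng.uniform(*PAWP_RANGE)
        hr = rng.uniform(*cfg.heart_rate)
        for site in SITES:
            rec = synth_heart_sound(cfg, group, site, rng, heart_rate=hr, subject_id=subject_id)
            recordings[(subject_id, site)] = rec
            rows.append(
                {
                    "subject_id": subject_id,
                    "site": site,
                    "mPAp_mmHg": round(mpap, 2),
                    "PAWp_mmHg": round(pawp, 2),
                    "wav_path": f"wavs/{subject_id}_{site}.wav",
                    "seed": cfg.seed,
                }
            )
    metadata = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "wavs").mkdir(parents=True, exist_ok=True)
        for (subject_id, site), rec in recordings.items():
            write_wav(outdir / "wavs" / f"{subject_id}_{site}.wav", rec)
        metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    return SyntheticCohort(metadata=metadata, recordings=recordings, config=cfg)
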