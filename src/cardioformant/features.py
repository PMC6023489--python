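"""Spectrogram computation and the three speech-spectral features.

Features are computed on the magnitude short-time Fourier transform ``S`` of
a sinusoid-formant waveform:

* ``entropy``  — sum over time frames and frequency bins of ``log(S^2 + eps)``;
  a small floor ``eps`` (relative to the spectrogram's maximum squared
  magnitude) keeps the log finite on silent frames.  Lower values indicate a
  concentrated, ordered spectrum.
* ``energy``   — sum of ``S^2`` over the same grid.
* relative band power — fraction of total signal power inside a narrow
  frequency band (the 21-22 Hz comparator feature).

Windowed variants split the recording into ``floor(duration / L)`` disjoint
segments of length ``L`` seconds and average the per-segment feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window, periodogram

from .errors import EmptyInputError, ParameterError
from .pcg_io import PcgRecording, resample

FEATURE_KINDS = ("entropy", "energy")


@dataclass(frozen=True)
class SpectrogramParams:
    """STFT analysis parameters (echoed into output metadata)."""

    window_s: float = 0.032
    hop_fraction: float = 0.5
    window: str = "hann"
    nfft: int | None = None  # default: next power of two above the window
    eps_rel: float = 1e-12  # log floor, relative to max(S^2)


@dataclass
class Spectrogram:
    """Magnitude STFT on an explicit time-frequency grid."""

    magnitudes: np.ndarray  # (n_bins, n_frames), all >= 0
    bin_freqs: np.ndarray
    frame_times: np.ndarray  # frame centers, seconds
    rate: float
    params: SpectrogramParams
    log_floor: float = field(init=False)

    def __post_init__(self) -> None:
        peak = float(np.max(self.magnitudes) ** 2) if self.magnitudes.size else 0.0
        self.log_floor = self.params.eps_rel * peak if peak > 0 else self.params.eps_rel

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[1]


def compute_spectrogram(
    signal: np.ndarray, rate: float, params: SpectrogramParams | None = None
) -> Spectrogram:
    """Magnitude STFT with non-centered frames (no edge padding).

    Frame ``i`` covers samples ``[i*hop, i*hop + nperseg)``; its time stamp is
    the frame center.  Magnitudes are the raw ``|rfft|`` of the tapered frame.
    """
    params = params or SpectrogramParams()
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1 or signal.size == 0:
        raise EmptyInputError("signal must be a non-empty 1-D array")
    nperseg = int(round(params.window_s * rate))
    if nperseg < 2:
        raise ParameterError(f"window of {params.window_s} s is too short at {rate} Hz")
    if nperseg > signal.size:
        raise ParameterError(
            f"analysis window ({nperseg} samples) exceeds signal length ({signal.size})"
        )
    if not 0 < params.hop_fraction <= 1:
        raise ParameterError("hop_fraction must be in (0, 1]")
    hop = max(int(round(nperseg * params.hop_fraction)), 1)
    nfft = params.nfft or int(2 ** np.ceil(np.log2(nperseg)))
    if nfft < nperseg:
        raise ParameterError("nfft must be >= the analysis window length")
    n_frames = 1 + (signal.size - nperseg) // hop
    starts = np.arange(n_frames) * hop
    frames = np.lib.stride_tricks.sliding_window_view(signal, nperseg)[starts]
    win = get_window(params.window, nperseg)
    mags = np.abs(np.fft.rfft(frames * win, nfft, axis=1)).T
    return Spectrogram(
        magnitudes=mags,
        bin_freqs=np.fft.rfftfreq(nfft, 1.0 / rate),
        frame_times=(starts + nperseg / 2.0) / rate,
        rate=rate,
        params=params,
    )


def _segment_columns(spec: Spectrogram, segment: tuple[float, float] | None) -> np.ndarray:
    if segment is None:
        return np.arange(spec.n_frames)
    t0, t1 = segment
    if not t1 > t0:
        raise ParameterError(f"segment ({t0}, {t1}) must have positive length")
    cols = np.nonzero((spec.frame_times >= t0) & (spec.frame_times < t1))[0]
    if cols.size == 0:
        raise EmptyInputError(f"segment ({t0}, {t1}) contains no spectrogram frames")
    return cols


def entropy_feature(spec: Spectrogram, segment: tuple[float, float] | None = None) -> float:
    """Sum of ``log(S^2 + eps)`` over the segment's time-frequency bins."""
    cols = _segment_columns(spec, segment)
    s2 = spec.magnitudes[:, cols] ** 2
    return float(np.sum(np.log(s2 + spec.log_floor)))


def energy_feature(spec: Spectrogram, segment: tuple[float, float] | None = None) -> float:
    """Sum of ``S^2`` over the segment's time-frequency bins."""
    cols = _segment_columns(spec, segment)
    return float(np.sum(spec.magnitudes[:, cols] ** 2))


def frame_feature_profile(spec: Spectrogram, kind: str) -> np.ndarray:
    """Per-frame feature contributions (the feature is additive over frames).

    Summing entries over a frame range reproduces the segment feature; this
    is what makes window-length sweeps cheap.
    """
    if kind == "entropy":
        return np.sum(np.log(spec.magnitudes**2 + spec.log_floor), axis=0)
    if kind == "energy":
        return np.sum(spec.magnitudes**2, axis=0)
    raise ParameterError(f"unknown feature kind {kind!r}; expected one of {FEATURE_KINDS}")


def profile_segment_mean(
    profile: np.ndarray, frame_times: np.ndarray, window_length: float, total_duration: float
) -> tuple[float, int]:
    """Average per-frame feature contributions over disjoint segments.

    Returns ``(mean value, number of segments used)``.  The tail shorter than
    one segment is discarded.
    """
    if not window_length > 0:
        raise ParameterError("window_length must be > 0")
    n_segments = int(np.floor(total_duration / window_length + 1e-9))
    if n_segments == 0:
        raise ParameterError(
            f"window_length {window_length} s exceeds recording duration {total_duration} s"
        )
    seg_of_frame = np.floor(frame_times / window_length).astype(np.intp)
    values = []
    for s in range(n_segments):
        mask = seg_of_frame == s
        if not mask.any():
            raise EmptyInputError(f"segment {s} contains no spectrogram frames")
        values.append(profile[mask].sum())
    return float(np.mean(values)), n_segments


def segment_mean_feature(
    spec: Spectrogram, kind: str, window_length: float, total_duration: float
) -> tuple[float, int]:
    """Average the feature over disjoint ``window_length``-second segments."""
    profile = frame_feature_profile(spec, kind)
    return profile_segment_mean(profile, spec.frame_times, window_length, total_duration)


def relative_band_power(
    signal: np.ndarray, rate: float, band: tuple[float, float] = (21.0, 22.0)
) -> float:
    """Fraction of total spectral power inside ``band`` (inclusive), in [0, 1]."""
    lo, hi = band
    if not (0.0 < lo < hi < rate / 2.0):
        raise ParameterError(f"band {band} must satisfy 0 < lo < hi < rate/2 ({rate / 2})")
    freqs, psd = periodogram(np.asarray(signal, dtype=np.float64), fs=rate)
    total = psd.sum()
    if total <= 0:
        raise EmptyInputError("signal has zero power")
    in_band = (freqs >= lo) & (freqs <= hi)
    return float(psd[in_band].sum() / total)


@dataclass
class FeatureValue:
    """One speech-spectral feature value for a (subject, site, formant, L) cell."""

    value: float
    kind: str
    formant: int
    site: str
    window_length: float
    subject_id: str
    n_segments: int = 1


def windowed_feature(
    rec: PcgRecording,
    formant: int,
    kind: str = "entropy",
    window_length: float = 10.0,
    analysis_rate: float = 8000.0,
    params: SpectrogramParams | None = None,
) -> FeatureValue:
    """Full per-recording feature pipeline for one formant.

    resample -> formant tracking -> sinusoid replica -> spectrogram ->
    per-segment feature averaged over all disjoint ``window_length``-second
    segments.
    """
    from .formants import track_formants
    from .replica import synthesize_replica

    if not 1 <= formant <= 4:
        raise ParameterError(f"formant must be 1..4, got {formant}")
    if window_length > rec.duration:
        raise ParameterError(
            f"window_length {window_length} s exceeds recording duration {rec.duration:.3f} s"
        )
    work = resample(rec.normalized(), analysis_rate)
    track = track_formants(work)
    rep = synthesize_replica(track)
    spec = compute_spectrogram(rep.waveforms[formant - 1], rep.rate, params)
    duration = rep.n_samples / rep.rate
    value, n_segments = segment_mean_feature(spec, kind, window_length, duration)
    return FeatureValue(
        value=value,
        kind=kind,
        formant=formant,
        site=rec.site,
        window_length=window_length,
        subject_id=rec.subject_id,
        n_segments=n_segments,
    )
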