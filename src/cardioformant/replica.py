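"""Sine-wave replica synthesis from formant tracks.

Each of the four formant trajectories drives an interpolating oscillator:
frequency and amplitude are linearly interpolated between frame centers and
the phase is the running integral of the instantaneous frequency, so the
synthesized tone is phase-continuous.  Frames where a formant is absent
synthesize silence for that formant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError
from .formants import MAX_FORMANTS, FormantTrack
from .pcg_io import PcgRecording, write_wav


@dataclass
class SinusoidReplica:
    """Four time-varying sinusoids, one per formant trajectory."""

    waveforms: np.ndarray  # (4, n_samples)
    rate: float

    @property
    def n_samples(self) -> int:
        return self.waveforms.shape[1]

    def export_wavs(self, directory, stem: str = "replica") -> list:
        """Write each formant waveform to ``<directory>/<stem>_f<i>.wav``."""
        paths = []
        for i in range(self.waveforms.shape[0]):
            rec = PcgRecording(self.waveforms[i], self.rate, subject_id=f"{stem}_f{i + 1}")
            path = f"{directory}/{stem}_f{i + 1}.wav"
            write_wav(path, rec.normalized() if np.any(rec.samples) else rec)
            paths.append(path)
        return paths


def _fill_nan(values: np.ndarray) -> np.ndarray:
    """Interpolate over NaN runs; edge NaNs are held at the nearest value."""
    out = values.copy()
    valid = np.isfinite(out)
    if not valid.any():
        return out
    idx = np.arange(out.size)
    out[~valid] = np.interp(idx[~valid], idx[valid], out[valid])
    return out


def synthesize_replica(track: FormantTrack, rate: float | None = None) -> SinusoidReplica:
    """Synthesize the four-sinusoid replica of a formant track.

    The synthesis rate defaults to the analysis rate so spectrogram grids of
    the original and the replica stay comparable.  A track with every formant
    absent produces four all-zero waveforms and a warning.
    """
    if track.n_frames == 0:
        raise EmptyInputError("formant track is empty")
    rate = float(rate if rate is not None else track.rate)
    frame_len = int(round(track.frame_duration * rate))
    n_samples = frame_len * track.n_frames
    t = np.arange(n_samples) / rate
    frame_index = np.minimum((t / track.frame_duration).astype(np.intp), track.n_frames - 1)
    waveforms = np.zeros((MAX_FORMANTS, n_samples))
    any_present = False
    for f in range(MAX_FORMANTS):
        freq_frames = track.freqs[:, f]
        amp_frames = track.amps[:, f]
        absent = ~np.isfinite(freq_frames)
        if absent.all():
            continue
        any_present = True
        freq = np.interp(t, track.frame_times, _fill_nan(freq_frames))
        amp = np.interp(t, track.frame_times, np.where(absent, 0.0, amp_frames))
        amp[absent[frame_index]] = 0.0  # silence over absent frames, exactly
        phase = 2.0 * np.pi * np.cumsum(freq) / rate
        waveforms[f] = amp * np.cos(phase)
    if not any_present:
        warnings.warn("all formants absent; replica is silent", stacklevel=2)
    return SinusoidReplica(waveforms=waveforms, rate=rate)
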