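"""Reading, writing, resampling and framing of mono heart-sound recordings.

All downstream analysis consumes :class:`PcgRecording` objects.  Recordings
are plain float arrays normalized to the [-1, 1] range together with their
sampling rate, auscultation site and subject id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import EmptyInputError, FormatError, ParameterError

#: Recognized auscultation sites (2nd left/right and 4th left intercostal
#: spaces plus the cardiac apical impulse).
SITES = ("apex", "2LICS", "2RICS", "4LICS")

_INT_SCALE = {
    np.dtype(np.int16): 2.0**15,
    np.dtype(np.int32): 2.0**31,
}


@dataclass
class PcgRecording:
    """A mono, sampled heart-sound signal.

    Parameters
    ----------
    samples
        1-D float array of amplitudes, nominally within [-1, 1].
    sampling_rate
        Sampling rate in Hz; must be positive.
    site
        Auscultation site, one of :data:`SITES` or ``"unknown"``.
    subject_id
        Opaque subject identifier.
    """

    samples: np.ndarray
    sampling_rate: float
    site: str = "unknown"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise FormatError(
                f"expected exactly one channel, got array with shape {self.samples.shape}"
            )
        if self.samples.size == 0:
            raise EmptyInputError("recording has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("recording contains non-finite samples")
        if not self.sampling_rate > 0:
            raise ParameterError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.site not in SITES and self.site != "unknown":
            raise ParameterError(f"unknown site {self.site!r}; expected one of {SITES}")

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.sampling_rate

    def normalized(self) -> "PcgRecording":
        """Return a copy scaled to unit peak amplitude.

        Recordings with zero peak are returned unchanged; stethoscope gain is
        arbitrary, so analysis should not depend on it.
        """
        peak = np.max(np.abs(self.samples))
        samples = self.samples / peak if peak > 0 else self.samples.copy()
        return PcgRecording(samples, self.sampling_rate, self.site, self.subject_id)


@dataclass
class FrameSequence:
    """Consecutive, non-overlapping fixed-length frames of a recording.

    The trailing partial frame (if any) is discarded, never zero-padded.
    """

    frames: np.ndarray  # (n_frames, frame_length)
    frame_duration: float
    frame_length: int
    source_rate: float
    frame_times: np.ndarray = field(init=False)  # frame centers, seconds

    def __post_init__(self) -> None:
        starts = np.arange(self.frames.shape[0]) * self.frame_length
        self.frame_times = (starts + self.frame_length / 2.0) / self.source_rate

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def read_wav(path, site: str = "unknown", subject_id: str = "") -> PcgRecording:
    """Read a mono PCM/float WAV file into a :class:`PcgRecording`.

    Integer sample formats are rescaled to [-1, 1]; float formats are taken
    as-is.  Multi-channel files are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise FormatError(f"cannot read {path} as PCM WAV: {exc}") from exc
    if data.ndim != 1:
        raise FormatError(
            f"{path} has {data.shape[1]} channels; only mono recordings are supported"
        )
    dtype = data.dtype
    if dtype in _INT_SCALE:
        samples = data.astype(np.float64) / _INT_SCALE[dtype]
    elif dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise FormatError(f"unsupported WAV sample format {dtype} in {path}")
    return PcgRecording(samples, float(rate), site=site, subject_id=subject_id or path.stem)


def write_wav(path, rec: PcgRecording, dtype: str = "int16") -> None:
    """Write a recording to disk as 16-bit PCM (default) or float32 WAV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dtype == "int16":
        clipped = np.clip(rec.samples, -1.0, 1.0 - 1.0 / 2**15)
        data = np.round(clipped * 2**15).astype(np.int16)
    elif dtype == "float32":
        data = rec.samples.astype(np.float32)
    else:
        raise ParameterError(f"unsupported output dtype {dtype!r}")
    wavfile.write(str(path), int(round(rec.sampling_rate)), data)


def resample(rec: PcgRecording, target_rate: float) -> PcgRecording:
    """Band-limited (polyphase) resampling to ``target_rate`` Hz.

    Identity when the rate already matches.  Duration is preserved to within
    one sample period.
    """
    if not target_rate > 0:
        raise ParameterError(f"target_rate must be > 0, got {target_rate}")
    if target_rate == rec.sampling_rate:
        return PcgRecording(rec.samples.copy(), rec.sampling_rate, rec.site, rec.subject_id)
    ratio = Fraction(target_rate / rec.sampling_rate).limit_denominator(10_000)
    samples = resample_poly(rec.samples, ratio.numerator, ratio.denominator)
    return PcgRecording(samples, float(target_rate), rec.site, rec.subject_id)


def frame_signal(rec: PcgRecording, frame_duration: float = 0.032) -> FrameSequence:
    """Split a recording into consecutive non-overlapping frames.

    ``frame_length = round(frame_duration * sampling_rate)``; the trailing
    partial frame is discarded.
    """
    if not frame_duration > 0:
        raise ParameterError(f"frame_duration must be > 0, got {frame_duration}")
    frame_length = int(round(frame_duration * rec.sampling_rate))
    n_frames = rec.samples.size // frame_length
    if n_frames == 0:
        raise EmptyInputError(
            f"recording of {rec.duration:.4f} s is shorter than one "
            f"{frame_duration:.3f} s frame"
        )
    frames = rec.samples[: n_frames * frame_length].reshape(n_frames, frame_length)
    return FrameSequence(
        frames=frames,
        frame_duration=frame_duration,
        frame_length=frame_length,
        source_rate=rec.sampling_rate,
    )


def load_cohort_metadata(path) -> "pd.DataFrame":
    """Load a cohort metadata table (TSV/CSV with a header).

    Required columns: subject_id, site, mPAp_mmHg, PAWp_mmHg, wav_path.
    """
    import pandas as pd

    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep, dtype={"subject_id": str})
    required = {"subject_id", "site", "mPAp_mmHg", "PAWp_mmHg", "wav_path"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"metadata {path} is missing columns: {sorted(missing)}")
    return table
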