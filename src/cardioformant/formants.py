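"""Formant-track estimation via per-frame 8th-order LPC analysis.

Each 32-ms frame is tapered, autocorrelated and fit with an all-pole linear
predictor.  The complex-conjugate pole pairs of the prediction polynomial
locate spectral resonances; the four with the largest spectral-envelope
amplitude are reported as the frame's formants, sorted by ascending
frequency.  Frames with fewer than four usable resonances carry NaN in the
remaining slots — missing formants are explicit, never silent zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import solve_toeplitz
from scipy.signal import get_window

from .errors import DegenerateFrameError, ParameterError
from .pcg_io import PcgRecording, frame_signal

logger = logging.getLogger(__name__)

#: Diagonal loading applied to the zero-lag autocorrelation.  Keeps the
#: normal equations well-conditioned on nearly-deterministic frames (pure
#: tones) without measurably biasing the fit.
AUTOCORR_RIDGE = 1e-9

DEFAULT_ORDER = 8
DEFAULT_TAPER = "hamming"
DEFAULT_MIN_POLE_RADIUS = 0.7
MAX_FORMANTS = 4


@dataclass
class LpcFit:
    """An all-pole linear-predictive fit of one frame.

    ``coefficients`` are the predictor weights ``a_1..a_p`` such that
    ``x[t] ~= sum_k a_k x[t-k]``; the prediction-error polynomial is
    ``A(z) = 1 - a_1 z^-1 - ... - a_p z^-p`` (leading coefficient 1).
    """

    order: int
    coefficients: np.ndarray
    gain: float

    @property
    def error_polynomial(self) -> np.ndarray:
        """Coefficients of A(z), highest power first: [1, -a_1, ..., -a_p]."""
        return np.concatenate(([1.0], -self.coefficients))

    @property
    def is_stable(self) -> bool:
        """True when all characteristic roots lie strictly inside the unit circle."""
        roots = np.roots(self.error_polynomial)
        return bool(np.all(np.abs(roots) < 1.0))


@dataclass
class FormantPoint:
    """One resonance: frequency in Hz and spectral-envelope amplitude."""

    frequency: float
    amplitude: float


@dataclass
class FormantTrack:
    """Per-frame formant frequencies and amplitudes for one recording.

    ``freqs`` and ``amps`` are ``(n_frames, 4)`` arrays; absent formants are
    NaN.  Rows are sorted ascending by frequency.
    """

    frame_times: np.ndarray
    freqs: np.ndarray
    amps: np.ndarray
    rate: float
    frame_duration: float
    n_degenerate: int = 0

    @property
    def n_frames(self) -> int:
        return self.freqs.shape[0]

    def save(self, path) -> None:
        """Serialize to a TSV with columns time_s, f1_hz..f4_hz, a1..a4.

        Absent formants are written as the literal string ``NaN``.
        """
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        header = "time_s\t" + "\t".join(
            [f"f{i}_hz" for i in range(1, 5)] + [f"a{i}" for i in range(1, 5)]
        )
        data = np.column_stack([self.frame_times, self.freqs, self.amps])
        np.savetxt(path, data, fmt="%.6f", delimiter="\t", header=header, comments="")

    @classmethod
    def load(cls, path, rate: float = 8000.0, frame_duration: float = 0.032) -> "FormantTrack":
        data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
        return cls(
            frame_times=data[:, 0],
            freqs=data[:, 1:5],
            amps=data[:, 5:9],
            rate=rate,
            frame_duration=frame_duration,
        )


def _autocorrelate(tapered: np.ndarray, order: int) -> np.ndarray:
    """Biased autocorrelation at lags 0..order via FFT (batched over rows)."""
    n = tapered.shape[-1]
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spectrum = np.abs(np.fft.rfft(tapered, nfft, axis=-1)) ** 2
    acf = np.fft.irfft(spectrum, nfft, axis=-1)[..., : order + 1]
    return acf / n


def _levinson_fit(r: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Solve the autocorrelation normal equations for predictor weights.

    Returns (coefficients a_1..a_p, prediction-error power).
    """
    r = r.copy()
    r[0] *= 1.0 + AUTOCORR_RIDGE
    a = solve_toeplitz(r[:order], r[1 : order + 1])
    err = float(r[0] - a @ r[1 : order + 1])
    return a, max(err, 0.0)


def lpc_fit(
    frame: np.ndarray, order: int = DEFAULT_ORDER, taper: str | None = DEFAULT_TAPER
) -> LpcFit:
    """Fit an all-pole predictor to one frame (autocorrelation method).

    The frame is tapered before autocorrelation (``taper=None`` disables).
    Raises :class:`DegenerateFrameError` on all-zero or constant frames.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 1:
        raise ParameterError("frame must be 1-D")
    if frame.size <= order:
        raise ParameterError(f"frame length {frame.size} must exceed order {order}")
    if np.ptp(frame) == 0.0:
        raise DegenerateFrameError("frame is constant or all zero")
    tapered = frame * get_window(taper, frame.size) if taper else frame
    r = _autocorrelate(tapered, order)
    if r[0] <= 0.0:
        raise DegenerateFrameError("frame has zero power after tapering")
    a, err = _levinson_fit(r, order)
    return LpcFit(order=order, coefficients=a, gain=float(np.sqrt(err)))


def formants_from_fit(
    fit: LpcFit,
    rate: float,
    min_pole_radius: float = DEFAULT_MIN_POLE_RADIUS,
    max_formants: int = MAX_FORMANTS,
) -> list[FormantPoint]:
    """Convert an LPC fit into at most four formant points.

    Complex roots of the prediction polynomial with positive imaginary part
    and radius >= ``min_pole_radius`` are candidate resonances.  Frequency is
    the root angle mapped to Hz; amplitude is the all-pole spectral envelope
    ``|gain / A(e^{j w})|`` at that frequency.  The ``max_formants`` strongest
    candidates are kept and reported sorted ascending by frequency.  Fewer
    candidates simply yield a shorter list; nothing is fabricated.
    """
    roots = np.roots(fit.error_polynomial)
    # conjugate pairs: keep the upper half plane, away from the real axis
    upper = roots[roots.imag > 1e-9]
    if upper.size == 0:
        return []
    radii = np.abs(upper)
    keep = radii >= min_pole_radius
    upper = upper[keep]
    if upper.size == 0:
        return []
    angles = np.angle(upper)
    freqs = angles * rate / (2.0 * np.pi)
    in_band = (freqs > 0.0) & (freqs < rate / 2.0)
    upper, freqs = upper[in_band], freqs[in_band]
    if upper.size == 0:
        return []
    # evaluate the envelope at each candidate frequency
    z = np.exp(1j * freqs * 2.0 * np.pi / rate)
    denom = np.polyval(fit.error_polynomial, z) / z ** fit.order
    gain = fit.gain if fit.gain > 0 else 1.0
    amps = gain / np.abs(denom)
    order_by_amp = np.argsort(amps)[::-1][:max_formants]
    freqs, amps = freqs[order_by_amp], amps[order_by_amp]
    order_by_freq = np.argsort(freqs)
    return [FormantPoint(float(f), float(a)) for f, a in zip(freqs[order_by_freq], amps[order_by_freq])]


def _batch_levinson(acf: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Levinson-Durbin recursion vectorized over frames.

    ``acf`` is (n_frames, order+1).  Returns (coefficients (n_frames, order),
    error power (n_frames,), valid mask).  Equivalent to solving the
    autocorrelation normal equations frame by frame (see :func:`_levinson_fit`).
    """
    acf = acf.copy()
    acf[:, 0] *= 1.0 + AUTOCORR_RIDGE
    n = acf.shape[0]
    a = np.zeros((n, order))
    err = acf[:, 0].copy()
    valid = err > 0.0
    for m in range(1, order + 1):
        acc = acf[:, m].copy()
        if m > 1:
            acc -= np.einsum("ij,ij->i", a[:, : m - 1], acf[:, m - 1 : 0 : -1])
        with np.errstate(divide="ignore", invalid="ignore"):
            k = np.where(valid & (err > 0), acc / np.where(err == 0, 1.0, err), 0.0)
        prev = a[:, : m - 1].copy()
        a[:, : m - 1] = prev - k[:, None] * prev[:, ::-1]
        a[:, m - 1] = k
        err = err * (1.0 - k**2)
        valid &= np.isfinite(err) & (err >= 0.0)
    return a, np.maximum(err, 0.0), valid


def _batch_formants(
    a: np.ndarray, gain: np.ndarray, rate: float, min_pole_radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pole -> formant conversion over frames.

    Mirrors :func:`formants_from_fit` exactly (the per-frame reference
    implementation) but runs on stacked companion matrices.
    """
    n, order = a.shape
    companion = np.zeros((n, order, order))
    companion[:, 0, :] = a
    idx = np.arange(order - 1)
    companion[:, idx + 1, idx] = 1.0
    roots = np.linalg.eigvals(companion)
    freqs = np.angle(roots) * rate / (2.0 * np.pi)
    candidate = (
        (roots.imag > 1e-9)
        & (np.abs(roots) >= min_pole_radius)
        & (freqs > 0.0)
        & (freqs < rate / 2.0)
    )
    omega = freqs * (2.0 * np.pi / rate)
    harmonics = np.arange(1, order + 1)
    phases = np.exp(-1j * omega[:, :, None] * harmonics[None, None, :])
    denom = 1.0 - np.einsum("fk,fck->fc", a + 0j, phases)
    with np.errstate(divide="ignore"):
        amps = np.where(gain[:, None] > 0, gain[:, None], 1.0) / np.abs(denom)
    amps = np.where(candidate, amps, -np.inf)
    top = np.argsort(-amps, axis=1, kind="stable")[:, :MAX_FORMANTS]
    rows = np.arange(n)[:, None]
    sel_freqs = np.where(np.take_along_axis(candidate, top, 1), np.take_along_axis(freqs, top, 1), np.nan)
    sel_amps = np.where(np.isfinite(sel_freqs), np.take_along_axis(amps, top, 1), np.nan)
    by_freq = np.argsort(sel_freqs, axis=1, kind="stable")  # NaN sorts last
    return sel_freqs[rows, by_freq], sel_amps[rows, by_freq]


def track_formants(
    rec: PcgRecording,
    frame_duration: float = 0.032,
    order: int = DEFAULT_ORDER,
    taper: str | None = DEFAULT_TAPER,
    min_pole_radius: float = DEFAULT_MIN_POLE_RADIUS,
) -> FormantTrack:
    """Estimate four formant tracks over consecutive 32-ms frames.

    Degenerate (constant/zero) frames yield all-NaN rows and are counted in
    ``n_degenerate``; the row count always equals ``floor(duration / frame_duration)``.
    Uses a batched implementation equivalent to calling :func:`lpc_fit` and
    :func:`formants_from_fit` on every frame.
    """
    seq = frame_signal(rec, frame_duration)
    tapered = seq.frames * (get_window(taper, seq.frame_length) if taper else 1.0)
    acf = _autocorrelate(tapered, order)
    nonconstant = np.ptp(seq.frames, axis=1) > 0.0
    a, err, valid = _batch_levinson(acf, order)
    valid &= nonconstant & (acf[:, 0] > 0.0)
    freqs, amps = _batch_formants(a, np.sqrt(err), rec.sampling_rate, min_pole_radius)
    freqs[~valid] = np.nan
    amps[~valid] = np.nan
    n_degenerate = int(np.sum(~valid))
    if n_degenerate:
        logger.info("track_formants: %d degenerate frame(s) skipped", n_degenerate)
    return FormantTrack(
        frame_times=seq.frame_times,
        freqs=freqs,
        amps=amps,
        rate=rec.sampling_rate,
        frame_duration=frame_duration,
        n_degenerate=n_degenerate,
    )
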