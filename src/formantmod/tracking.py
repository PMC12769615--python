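"""Burg-LPC formant contour extraction.

A Praat-style tracker: band-limit the recording below the formant ceiling,
resample to twice the ceiling, pre-emphasize, then per Gaussian-windowed
frame estimate an autoregressive model with the Burg method and convert the
poles of the prediction polynomial to formant (frequency, bandwidth)
candidates. The lowest ``n_formants`` candidates per frame become F1..F3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synth import FormantContour

__all__ = [
    "TrackerConfig",
    "burg_coefficients",
    "hann_stopband_filter",
    "lpc_to_formants",
    "track_formants",
]


@dataclass(frozen=True)
class TrackerConfig:
    """Formant tracker settings.

    ``n_formants`` is the number of output tracks (F1..F3);
    ``n_candidate_formants`` sets the pole budget of the Burg fit at two
    poles per candidate (the Praat-default 5-candidate search gives order
    10, which absorbs spectral tilt and resampling zeros into
    wide-bandwidth poles). Set ``n_candidate_formants=3`` for a strict
    six-pole fit. Candidates broader than ``max_bandwidth_hz`` are rejected
    before assignment.
    """

    max_formant_hz: float = 3000.0
    window_s: float = 0.05
    time_step_s: float = 0.0125  # quarter of the window
    n_formants: int = 3
    n_candidate_formants: int = 5
    extra_poles: int = 0
    preemph_from_hz: float = 50.0
    stopband_smooth_hz: float = 50.0
    min_formant_hz: float = 50.0
    max_bandwidth_hz: float = 400.0
    merge_within_hz: float = 50.0

    @property
    def lpc_order(self) -> int:
        return 2 * self.n_candidate_formants + self.extra_poles

    def __post_init__(self) -> None:
        if self.time_step_s > self.window_s:
            raise ValueError("time_step_s must not exceed window_s")
        if self.n_candidate_formants < self.n_formants:
            raise ValueError("n_candidate_formants must be >= n_formants")
        if self.lpc_order < 2 * self.n_formants or self.lpc_order % 2:
            raise ValueError("lpc_order must be even and >= 2*n_formants")


def hann_stopband_filter(
    x: np.ndarray, fs: float, upper_hz: float = 3000.0, smooth_hz: float = 50.0
) -> np.ndarray:
    """Zero out spectral content above ``upper_hz`` with a raised-cosine edge.

    Frequency-domain implementation of Praat's "Filter (stop Hann band)"
    from ``upper_hz`` to Nyquist: unit gain below ``upper_hz - smooth_hz``,
    zero above ``upper_hz + smooth_hz``, half-cosine transition in between.
    """
    if fs <= 2 * upper_hz:
        raise ValueError("sampling rate must exceed twice the stopband edge")
    x = np.asarray(x, dtype=float)
    n = x.size
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.ones_like(f)
    lo, hi = upper_hz - smooth_hz, upper_hz + smooth_hz
    trans = (f > lo) & (f < hi)
    gain[trans] = 0.5 * (1.0 + np.cos(np.pi * (f[trans] - lo) / (hi - lo)))
    gain[f >= hi] = 0.0
    return np.fft.irfft(X * gain, n=n)


def burg_coefficients(frame: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Burg AR coefficient estimation.

    Minimizes the sum of forward and backward prediction errors with a
    Levinson-style lattice recursion. Returns ``(a, k)`` where ``a`` are the
    prediction coefficients of ``A(z) = 1 + a_1 z^-1 + ... + a_p z^-p`` and
    ``k`` the reflection coefficients, all of magnitude < 1 for a
    non-degenerate frame.

    Raises ``DegenerateFrameError`` on constant/zero frames.
    """
    x = np.asarray(frame, dtype=float)
    n = x.size
    if n <= order:
        raise ValueError(f"frame length {n} must exceed order {order}")
    if not np.any(x != x[0]):
        raise DegenerateFrameError("constant frame has no spectral structure")
    f = x.copy()  # forward error
    b = x.copy()  # backward error
    a = np.zeros(order)
    ks = np.zeros(order)
    for m in range(order):
        fm = f[m + 1 :]
        bm = b[m:-1]
        den = np.dot(fm, fm) + np.dot(bm, bm)
        if den <= 0:
            raise DegenerateFrameError("prediction error vanished before full order")
        k = -2.0 * np.dot(fm, bm) / den
        ks[m] = k
        # update AR coefficients: a_new = [a, 0] + k * [reversed(a), 1]
        a_prev = a[:m].copy()
        a[:m] = a_prev + k * a_prev[::-1]
        a[m] = k
        f_new = fm + k * bm
        b_new = bm + k * fm
        f[m + 1 :] = f_new
        b[m + 1 :] = b_new
    return a, ks


class DegenerateFrameError(ValueError):
    """Frame carries no usable spectral information (constant or silent)."""


def lpc_to_formants(
    a: np.ndarray,
    fs: float,
    min_hz: float = 50.0,
    max_hz: float | None = None,
    merge_within_hz: float = 50.0,
) -> list[tuple[float, float]]:
    """Convert prediction coefficients to (frequency, bandwidth) candidates.

    Roots of ``A(z)`` with positive imaginary part map to
    ``freq = angle * fs / 2pi`` and ``bw = -fs/pi * ln|root|``; candidates
    outside ``(min_hz, max_hz)`` are dropped and near-coincident roots
    (within ``merge_within_hz``) are merged keeping the lower bandwidth.
    """
    max_hz = fs / 2.0 if max_hz is None else max_hz
    roots = np.roots(np.r_[1.0, np.asarray(a, dtype=float)])
    cands = []
    for r in roots:
        if r.imag <= 0 or abs(r) == 0:
            continue
        freq = np.angle(r) * fs / (2.0 * np.pi)
        bw = -fs / np.pi * np.log(np.abs(r))
        if min_hz < freq < max_hz:
            cands.append((float(freq), float(bw)))
    cands.sort()
    merged: list[tuple[float, float]] = []
    for freq, bw in cands:
        if merged and freq - merged[-1][0] < merge_within_hz:
            if bw < merged[-1][1]:
                merged[-1] = (freq, bw)
        else:
            merged.append((freq, bw))
    return merged


def _gaussian_window(n: int) -> np.ndarray:
    # Gaussian-like analysis window (near-zero at the edges), as used by
    # Praat's formant analysis
    t = (np.arange(n) + 0.5) / n - 0.5
    return np.exp(-12.0 * (2.0 * t) ** 2)


def track_formants(
    x: np.ndarray,
    fs: float,
    cfg: TrackerConfig | None = None,
    voc_id: str = "tracked",
    vocal_type: str = "BL",
    session_id: str = "",
    day: int = 1,
) -> FormantContour:
    """Extract F1..Fn contours from a mono waveform.

    Pipeline per frame (centre spacing ``time_step_s``): resample the
    band-limited signal to ``2 * max_formant_hz``, pre-emphasize from
    ``preemph_from_hz``, apply a Gaussian window, run Burg at ``lpc_order``,
    root-solve, and assign the lowest candidates to F1..Fn in ascending
    order. Frames without enough candidates yield missing values.
    """
    cfg = cfg or TrackerConfig()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("track_formants requires mono audio")
    if x.size < cfg.window_s * fs:
        raise ValueError("signal shorter than one analysis window")
    fs_t = 2.0 * cfg.max_formant_hz
    if fs > fs_t:
        # FFT (brick-wall) resampling avoids anti-alias rolloff biasing
        # formants near the new Nyquist
        n_new = int(round(x.size * fs_t / fs))
        fs_eff = fs * n_new / x.size
        x = signal.resample(x, n_new)
    else:
        fs_eff = fs
    # first-difference pre-emphasis with coefficient exp(-2*pi*f_c*dt)
    alpha = np.exp(-2.0 * np.pi * cfg.preemph_from_hz / fs_eff)
    xe = np.r_[x[0], x[1:] - alpha * x[:-1]]
    nwin = int(round(cfg.window_s * fs_eff))
    step = cfg.time_step_s * fs_eff
    win = _gaussian_window(nwin)
    n_frames = int(np.floor((xe.size - nwin) / step)) + 1
    if n_frames < 1:
        raise ValueError("signal shorter than one analysis window")
    times = np.empty(n_frames)
    f = np.full((cfg.n_formants, n_frames), np.nan)
    for i in range(n_frames):
        i0 = int(round(i * step))
        frame = xe[i0 : i0 + nwin] * win
        times[i] = (i0 + nwin / 2.0) / fs_eff
        try:
            a, _ = burg_coefficients(frame, cfg.lpc_order)
        except DegenerateFrameError:
            continue
        cands = lpc_to_formants(
            a,
            fs_eff,
            min_hz=cfg.min_formant_hz,
            max_hz=cfg.max_formant_hz,
            merge_within_hz=cfg.merge_within_hz,
        )
        cands = [(freq, bw) for freq, bw in cands if bw <= cfg.max_bandwidth_hz]
        for j, (freq, _bw) in enumerate(cands[: cfg.n_formants]):
            f[j, i] = freq
    if cfg.n_formants < 3:
        f = np.vstack([f, np.full((3 - f.shape[0], n_frames), np.nan)])
    return FormantContour(
        voc_id=voc_id,
        vocal_type=vocal_type,
        session_id=session_id,
        day=day,
        times_s=times,
        f_hz=f[:3],
    )
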