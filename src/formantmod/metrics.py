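"""Formant-modulation statistics.

Three complementary measures per formant contour:

* **Coefficient of variation** (CV = sigma/mu): overall within-vocalization
  variability, scale-free.
* **Modulation depth** (MD = |f_{k+1} - f_k|): per-step frequency shift
  between adjacent contour points, in Hz; steeper contours score higher.
* **Spectral entropy** (SE): Shannon entropy (bits) of the normalized
  windowed power spectrum of the contour. Predictable cyclic modulation
  concentrates spectral power in few bins (low entropy); unstructured
  variation spreads it (high entropy).

Window length for SE is chosen to cover at least one cycle of the dominant
contour periodicity, which :func:`dominant_period` estimates with a Morlet
continuous wavelet transform. With a 0.0125 s contour step, the default
40-point window spans 0.5 s — two cycles of a 4 Hz mouth-cycle modulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import pywt

from .synth import FORMANTS, FormantContour

__all__ = [
    "ModulationSummary",
    "coefficient_of_variation",
    "dominant_period",
    "modulation_depth",
    "spectral_entropy",
    "summarize",
    "summarize_dataset",
]

SE_WINDOW_PTS = 40
SE_STEP_PTS = 20
#: fraction of missing points above which an entropy window is skipped
SE_MAX_MISSING = 0.25


def _series(contour: FormantContour, formant: str) -> np.ndarray:
    return contour.f_hz[FORMANTS.index(formant)]


def coefficient_of_variation(contour: FormantContour, formant: str) -> float:
    """CV = sigma / mu over non-missing points (sample sd, n-1 denominator)."""
    v = _series(contour, formant)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("coefficient_of_variation needs >= 2 non-missing points")
    mu = float(np.mean(v))
    if mu <= 0:
        raise ValueError("non-positive mean frequency: corrupt contour")
    return float(np.std(v, ddof=1)) / mu


def modulation_depth(contour: FormantContour, formant: str) -> np.ndarray:
    """Absolute first differences between adjacent surviving samples.

    Pairs separated by a QC gap are excluded, not bridged; a contour with
    fewer than two surviving points yields an empty series.
    """
    v = _series(contour, formant)
    ok = np.isfinite(v)
    both = ok[:-1] & ok[1:]
    idx = np.nonzero(both)[0]
    return np.abs(v[idx + 1] - v[idx])


def dominant_period(
    contour: FormantContour,
    formant: str,
    n_scales: int = 64,
    wavelet: str = "cmor1.5-1.0",
) -> float:
    """Dominant contour periodicity via Morlet continuous wavelet transform.

    The mean-subtracted contour is decomposed on a logarithmic grid of
    scales spanning periods from 2*dt to the contour duration; the period
    of the maximum time-averaged power is returned, in seconds. Undefined
    (NaN) on an effectively constant contour.
    """
    v = _series(contour, formant)
    t = contour.times_s
    ok = np.isfinite(v)
    if ok.sum() < 8:
        return float("nan")
    # interpolate interior gaps so the transform sees a regular grid
    vv = np.interp(t, t[ok], v[ok])
    vv = vv - vv.mean()
    if np.allclose(vv, 0.0):
        return float("nan")
    dt = float(np.median(np.diff(t)))
    duration = t[-1] - t[0]
    periods = np.geomspace(2.0 * dt, duration, n_scales)
    # scale s maps to frequency fc/(s*dt) for the chosen wavelet
    fc = pywt.central_frequency(wavelet)
    scales = fc * periods / dt
    coef, _ = pywt.cwt(vv, scales, wavelet, sampling_period=dt)
    power = np.mean(np.abs(coef) ** 2, axis=1)
    return float(periods[int(np.argmax(power))])


def spectral_entropy(
    contour: FormantContour,
    formant: str,
    window_pts: int = SE_WINDOW_PTS,
    step_pts: int = SE_STEP_PTS,
    taper: str | None = None,
) -> np.ndarray:
    """Shannon entropy (bits) of the normalized windowed contour spectrum.

    Sliding windows of ``window_pts`` samples advance by ``step_pts`` (50%
    overlap at the defaults). Per window: linearly interpolate interior
    missing points (windows with more than 25% missing are skipped),
    subtract the mean, take a single periodogram, drop the DC bin, and
    normalize the remaining bin powers to a probability distribution p;
    H = -sum p_i log2 p_i. Contours shorter than one window yield a single
    entropy value over all available points. A window with (numerically)
    zero power scores 0 by convention.
    """
    v = _series(contour, formant)
    n = v.size
    if np.isfinite(v).sum() < 2:
        raise ValueError("spectral_entropy needs >= 2 non-missing points")
    if n < window_pts:
        h = _window_entropy(v, taper)
        return np.array([]) if h is None else np.array([h])
    out = []
    for start in range(0, n - window_pts + 1, step_pts):
        h = _window_entropy(v[start : start + window_pts], taper)
        if h is not None:
            out.append(h)
    return np.asarray(out)


def _window_entropy(w: np.ndarray, taper: str | None) -> float | None:
    ok = np.isfinite(w)
    if ok.sum() < 2 or (1.0 - ok.mean()) > SE_MAX_MISSING:
        return None
    idx = np.arange(w.size)
    ww = np.interp(idx, idx[ok], w[ok])
    ww = ww - ww.mean()
    if taper == "hann":
        ww = ww * np.hanning(ww.size)
    p = np.abs(np.fft.rfft(ww)) ** 2
    p = p[1:]  # drop DC
    total = p.sum()
    if total <= 1e-12 * max(1.0, float(np.abs(w[ok]).max()) ** 2):
        return 0.0
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _quartiles(series: np.ndarray) -> tuple[float, float, float, float]:
    """25th/50th/75th/100th percentiles (linear interpolation)."""
    if series.size == 0:
        return (float("nan"),) * 4
    q = np.percentile(series, [25, 50, 75, 100])
    return tuple(float(x) for x in q)


@dataclass
class ModulationSummary:
    """Per-vocalization modulation statistics, nine numbers per formant:
    CV, four MD quartiles and four SE quartiles."""

    voc_id: str
    vocal_type: str
    session_id: str
    day: int
    cv: dict[str, float]
    md_quartiles: dict[str, tuple[float, float, float, float]]
    se_quartiles: dict[str, tuple[float, float, float, float]]
    dominant_period_s: dict[str, float]

    def to_row(self) -> dict:
        row: dict = {
            "voc_id": self.voc_id,
            "vocal_type": self.vocal_type,
            "session_id": self.session_id,
            "day": self.day,
        }
        for f in FORMANTS:
            row[f"cv_{f}"] = self.cv.get(f, float("nan"))
            for q, val in zip((1, 2, 3, 4), self.md_quartiles.get(f, (float("nan"),) * 4)):
                row[f"md_q{q}_{f}"] = val
            for q, val in zip((1, 2, 3, 4), self.se_quartiles.get(f, (float("nan"),) * 4)):
                row[f"se_q{q}_{f}"] = val
            row[f"period_{f}"] = self.dominant_period_s.get(f, float("nan"))
        return row


def summarize(
    contour: FormantContour,
    window_pts: int = SE_WINDOW_PTS,
    step_pts: int = SE_STEP_PTS,
    with_period: bool = False,
) -> ModulationSummary:
    """All modulation statistics for one vocalization.

    The wavelet dominant period is comparatively slow and only needed for
    window-length validation, so it is opt-in.
    """
    cv, mdq, seq, per = {}, {}, {}, {}
    for f in FORMANTS:
        v = _series(contour, f)
        if np.isfinite(v).sum() >= 2:
            try:
                cv[f] = coefficient_of_variation(contour, f)
            except ValueError:
                pass
            mdq[f] = _quartiles(modulation_depth(contour, f))
            seq[f] = _quartiles(spectral_entropy(contour, f, window_pts, step_pts))
            if with_period:
                per[f] = dominant_period(contour, f)
    return ModulationSummary(
        voc_id=contour.voc_id,
        vocal_type=contour.vocal_type,
        session_id=contour.session_id,
        day=contour.day,
        cv=cv,
        md_quartiles=mdq,
        se_quartiles=seq,
        dominant_period_s=per,
    )


def summarize_dataset(
    contours: Sequence[FormantContour],
    window_pts: int = SE_WINDOW_PTS,
    step_pts: int = SE_STEP_PTS,
) -> pd.DataFrame:
    """One summary row per vocalization (wide format, metrics per formant)."""
    return pd.DataFrame([summarize(c, window_pts, step_pts).to_row() for c in contours])


def metric_long_table(contours: Sequence[FormantContour]) -> pd.DataFrame:
    """Long-format table of the raw metric series, one row per observation.

    ``metric`` is one of ``formant_hz`` (contour values), ``cv``, ``md``,
    ``se`` — the shapes the longitudinal models consume.
    """
    rows = []
    for c in contours:
        for f in FORMANTS:
            v = _series(c, f)
            meta = {
                "voc_id": c.voc_id,
                "vocal_type": c.vocal_type,
                "session_id": c.session_id,
                "day": c.day,
                "formant": f,
            }
            for x in v[np.isfinite(v)]:
                rows.append({**meta, "metric": "formant_hz", "value": float(x)})
            if np.isfinite(v).sum() >= 2:
                try:
                    rows.append({**meta, "metric": "cv", "value": coefficient_of_variation(c, f)})
                except ValueError:
                    pass
                for x in modulation_depth(c, f):
                    rows.append({**meta, "metric": "md", "value": float(x)})
                for x in spectral_entropy(c, f):
                    rows.append({**meta, "metric": "se", "value": float(x)})
    return pd.DataFrame(rows)
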