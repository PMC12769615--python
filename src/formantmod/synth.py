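"""Synthetic vocalization generator.

Emulates the two vocal types of a longitudinal operant-conditioning
experiment on a harbor seal:

* **BL** (baseline): flat formant tracks around the vocal-tract resonances,
  perturbed only by AR(1) tracking jitter.
* **CD** (conditioned): cyclic ~4 Hz formant modulation produced by
  open/close mouth cycles, whose amplitude grows over training days along a
  logistic learning ramp — strongest in F1 and F3.

The generator also reproduces the two tracking artifacts a Burg formant
tracker exhibits on real recordings: spurious excursions at vocalization
onset/offset, and within-time-point misassignment of the three formant
values. Ground truth is retained so the QC stage can be validated against it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ArtifactConfig",
    "FormantContour",
    "SynthConfig",
    "inject_tracking_errors",
    "render_audio",
    "simulate_contour",
    "simulate_dataset",
    "tube_formants",
]

#: canonical formant names, ascending frequency
FORMANTS = ("F1", "F2", "F3")

#: non-identity permutations of the (F1, F2, F3) triple
_MISASSIGN_PERMS = [p for p in itertools.permutations(range(3)) if p != (0, 1, 2)]


def tube_formants(length_m: float, c_ms: float = 343.0, i: int = 1) -> float:
    """Resonance frequency of a uniform quarter-wavelength tube.

    Models the vocal tract as a uniform tube closed at the glottis and open
    at the lips, which resonates at odd multiples of ``c / (4 L)``:

        F_i = (2 i - 1) * c / (4 L)

    Parameters
    ----------
    length_m : vocal tract length in metres.
    c_ms : speed of sound in m/s (343 m/s in air at 20 °C).
    i : formant index, 1-based.

    Returns
    -------
    Predicted formant frequency in Hz. For a 0.17 m tract this puts
    F1/F2/F3 near 500/1500/2500 Hz.
    """
    if length_m <= 0 or c_ms <= 0:
        raise ValueError("length_m and c_ms must be positive")
    if i < 1:
        raise ValueError("formant index must be >= 1")
    return (2 * i - 1) * c_ms / (4.0 * length_m)


@dataclass(frozen=True)
class ArtifactConfig:
    """Tracking-artifact injection parameters.

    edge_spike_prob
        Per-point probability of a spurious excursion within the first and
        last 5% of contour points (the poorly tracked onset/offset regions).
    edge_spike_mag_hz
        Magnitude of an edge excursion (sign randomized per spike).
    misassign_frac
        Fraction of time points at which the (F1, F2, F3) triple is replaced
        by a random non-identity permutation of itself; realistic trackers
        do this at roughly 2-10% of points when settings are suboptimal.
    seed_offset
        Added to the contour seed so artifact noise is decoupled from
        generation noise.
    """

    edge_spike_prob: float = 0.0
    edge_spike_mag_hz: float = 600.0
    misassign_frac: float = 0.0
    seed_offset: int = 104729

    def __post_init__(self) -> None:
        if not 0.0 <= self.edge_spike_prob <= 1.0:
            raise ValueError("edge_spike_prob must be in [0, 1]")
        if not 0.0 <= self.misassign_frac <= 1.0:
            raise ValueError("misassign_frac must be in [0, 1]")


# Defaults are the study conditions the pipeline emulates: 54 sampled days,
# >= 3 s vocalizations (the reinforcement minimum), 0.0125 s contour step,
# tube-model formant centers for a 0.17 m tract, 4 Hz mouth-cycle rate.
@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic longitudinal experiment."""

    n_days: int = 54
    #: ~10 vocalizations per type per sampled day reproduces the study's
    #: overall yield (~1100 vocalizations over 54 days)
    vocs_per_day_per_type: int = 10
    duration_s: float = 3.0
    dt_s: float = 0.0125
    centers_hz: tuple[float, float, float] = (
        tube_formants(0.17, 343.0, 1),
        tube_formants(0.17, 343.0, 2),
        tube_formants(0.17, 343.0, 3),
    )
    mod_rate_hz: float = 4.0
    #: asymptotic CD modulation amplitude per formant; F1 > F3 > F2 mirrors
    #: the finding that F1 and F3 modulation diverged most under training
    mod_amp_max_hz: tuple[float, float, float] = (150.0, 60.0, 120.0)
    #: day at which the CD amplitude reaches half its asymptote
    learning_halfday: float = 27.0
    #: logistic ramp steepness, 1/day
    learning_rate: float = 0.15
    noise_sd_hz: tuple[float, float, float] = (30.0, 30.0, 30.0)
    #: AR(1) coefficient of the jitter; 0 gives white noise
    noise_ar: float = 0.5
    #: optional slow baseline drift of BL centers, Hz/day (the experiment
    #: observed unintended BL changes; off by default)
    bl_drift_hz_per_day: tuple[float, float, float] = (0.0, 0.0, 0.0)
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.duration_s / self.dt_s < 40:
            raise ValueError("contour must hold at least one 40-point entropy window")
        c = self.centers_hz
        if not (0 < c[0] < c[1] < c[2] < 3000):
            raise ValueError("centers_hz must be strictly increasing and < 3000 Hz")
        if self.mod_rate_hz >= 0.5 / self.dt_s:
            raise ValueError("mod_rate_hz must be below the contour Nyquist 1/(2 dt)")
        if self.n_days < 1 or self.vocs_per_day_per_type < 1:
            raise ValueError("n_days and vocs_per_day_per_type must be >= 1")

    @property
    def n_points(self) -> int:
        return int(round(self.duration_s / self.dt_s))

    def amplitude(self, day: float) -> np.ndarray:
        """Per-formant CD modulation amplitude on a given day (logistic ramp)."""
        ramp = 1.0 / (1.0 + np.exp(-self.learning_rate * (day - self.learning_halfday)))
        return np.asarray(self.mod_amp_max_hz) * ramp


@dataclass
class FormantContour:
    """Per-vocalization time series of (time, F1, F2, F3) with metadata.

    ``f_hz`` is a (3, n) array in F1/F2/F3 order; NaN marks points removed
    by QC or never tracked. ``truth_hz`` carries the pre-artifact ground
    truth when the contour is synthetic.
    """

    voc_id: str
    vocal_type: str
    session_id: str
    day: int
    times_s: np.ndarray
    f_hz: np.ndarray
    truth_hz: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.f_hz = np.asarray(self.f_hz, dtype=float)
        if self.vocal_type not in ("BL", "CD"):
            raise ValueError(f"unknown vocal_type {self.vocal_type!r}")
        if self.f_hz.shape != (3, self.times_s.size):
            raise ValueError("f_hz must be a (3, n) array parallel to times_s")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times_s must be strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.any(self.f_hz[np.isfinite(self.f_hz)] <= 0):
                raise ValueError("formant frequencies must be positive")

    @property
    def n_points(self) -> int:
        return self.times_s.size

    def copy(self) -> "FormantContour":
        return FormantContour(
            self.voc_id,
            self.vocal_type,
            self.session_id,
            self.day,
            self.times_s.copy(),
            self.f_hz.copy(),
            None if self.truth_hz is None else self.truth_hz.copy(),
        )


def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    e = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for k in range(1, n):
        x[k] = rho * x[k - 1] + e[k]
    return x


def simulate_contour(
    vocal_type: str,
    day: int,
    cfg: SynthConfig,
    voc_index: int = 0,
) -> FormantContour:
    """Simulate one ground-truth formant contour.

    BL contours are flat at ``centers_hz`` plus AR(1) jitter (plus optional
    drift); CD contours add a sinusoid at ``mod_rate_hz`` whose amplitude
    follows the logistic learning ramp, with a phase drawn per vocalization.
    Deterministic given (cfg.seed, vocal_type, day, voc_index).
    """
    if vocal_type not in ("BL", "CD"):
        raise ValueError(f"unknown vocal_type {vocal_type!r}")
    if not 1 <= day <= cfg.n_days:
        raise ValueError(f"day {day} outside [1, {cfg.n_days}]")
    seed = np.random.SeedSequence(
        [cfg.seed, {"BL": 0, "CD": 1}[vocal_type], int(day), int(voc_index)]
    )
    rng = np.random.default_rng(seed)
    n = cfg.n_points
    t = np.arange(n) * cfg.dt_s
    phase = rng.uniform(0.0, 2.0 * np.pi)
    amp = cfg.amplitude(day) if vocal_type == "CD" else np.zeros(3)
    drift = np.asarray(cfg.bl_drift_hz_per_day) * (day - 1) if vocal_type == "BL" else 0.0
    f = np.empty((3, n))
    for j in range(3):
        f[j] = (
            cfg.centers_hz[j]
            + (drift[j] if vocal_type == "BL" else 0.0)
            + amp[j] * np.sin(2.0 * np.pi * cfg.mod_rate_hz * t + phase)
            + _ar1(rng, n, cfg.noise_sd_hz[j], cfg.noise_ar)
        )
    return FormantContour(
        voc_id=f"{vocal_type}_d{day:03d}_v{voc_index:03d}",
        vocal_type=vocal_type,
        session_id=f"s{day:03d}",
        day=day,
        times_s=t,
        f_hz=f,
        truth_hz=f.copy(),
    )


def inject_tracking_errors(
    contour: FormantContour,
    cfg: ArtifactConfig,
    seed: int | None = None,
) -> FormantContour:
    """Corrupt a complete contour with tracker-like artifacts.

    At ``round(misassign_frac * n)`` randomly chosen time points the
    (F1, F2, F3) triple is replaced by a random non-identity permutation of
    itself; edge spikes are added independently within the first/last 5% of
    points. The input's ground truth is preserved on the output.
    """
    if np.any(~np.isfinite(contour.f_hz)):
        raise ValueError("inject_tracking_errors requires a complete contour")
    out = contour.copy()
    if out.truth_hz is None:
        out.truth_hz = contour.f_hz.copy()
    rng = np.random.default_rng(
        np.random.SeedSequence([0 if seed is None else int(seed), cfg.seed_offset])
    )
    n = out.n_points
    n_swap = int(round(cfg.misassign_frac * n))
    if n_swap > 0:
        idx = rng.choice(n, size=n_swap, replace=False)
        perms = rng.integers(0, len(_MISASSIGN_PERMS), size=n_swap)
        for k, p in zip(idx, perms):
            out.f_hz[:, k] = out.f_hz[list(_MISASSIGN_PERMS[p]), k]
    if cfg.edge_spike_prob > 0:
        n_edge = max(1, int(np.floor(0.05 * n)))
        edge_idx = np.r_[np.arange(n_edge), np.arange(n - n_edge, n)]
        for k in edge_idx:
            for j in range(3):
                if rng.random() < cfg.edge_spike_prob:
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    out.f_hz[j, k] = max(out.f_hz[j, k] + sign * cfg.edge_spike_mag_hz, 1.0)
    return out


def simulate_dataset(cfg: SynthConfig, days: Sequence[int] | None = None) -> list[FormantContour]:
    """Simulate the full longitudinal dataset, optionally on a subset of days.

    Artifacts from ``cfg.artifact`` are injected per contour with seeds
    derived from the contour identity, so the run is reproducible.
    """
    days = range(1, cfg.n_days + 1) if days is None else days
    out: list[FormantContour] = []
    for day in days:
        for vt in ("BL", "CD"):
            for v in range(cfg.vocs_per_day_per_type):
                c = simulate_contour(vt, day, cfg, v)
                if cfg.artifact.misassign_frac > 0 or cfg.artifact.edge_spike_prob > 0:
                    art_seed = int(
                        np.random.SeedSequence(
                            [cfg.seed, {"BL": 0, "CD": 1}[vt], int(day), int(v), 7]
                        ).generate_state(1)[0]
                        % (2**31)
                    )
                    c = inject_tracking_errors(c, cfg.artifact, seed=art_seed)
                out.append(c)
    return out


def render_audio(
    contour: FormantContour,
    f0_hz: float = 100.0,
    fs_hz: int = 12000,
    bandwidths_hz: tuple[float, float, float] = (80.0, 120.0, 160.0),
    source: str = "pulse",
) -> np.ndarray:
    """Synthesize a waveform from a formant contour (source-filter model).

    An impulse ("pulse") or sawtooth train at ``f0_hz`` is passed through a
    cascade of time-varying second-order resonators centred at the contour's
    instantaneous formant frequencies, with fixed bandwidths. The output is
    peak-normalized to <= 1. Only complete (pre-QC) contours can be rendered.
    """
    if np.any(~np.isfinite(contour.f_hz)):
        raise ValueError("render_audio requires a complete contour (no missing values)")
    ceiling = float(np.max(contour.f_hz))
    if fs_hz < 2 * ceiling:
        raise ValueError("fs_hz must be at least twice the highest formant")
    if not 0 <= f0_hz < contour.f_hz[0].min():
        raise ValueError("f0_hz must be non-negative and below F1")
    dur = contour.times_s[-1] + (contour.times_s[1] - contour.times_s[0])
    n = int(round(dur * fs_hz))
    t = np.arange(n) / fs_hz
    if f0_hz == 0:
        return np.zeros(n)
    if source == "pulse":
        # impulse at every pitch period
        x = np.zeros(n)
        x[(np.floor(t * f0_hz) - np.floor(np.roll(t * f0_hz, 1))) > 0] = 1.0
        x[0] = 1.0
    elif source == "sawtooth":
        x = 2.0 * (t * f0_hz - np.floor(t * f0_hz + 0.5))
    else:
        raise ValueError(f"unknown source {source!r}")
    # per-sample formant targets, held constant outside the contour span
    f_inst = np.vstack(
        [np.interp(t, contour.times_s, contour.f_hz[j]) for j in range(3)]
    )
    y = x
    for j in range(3):
        y = _time_varying_resonator(y, f_inst[j], bandwidths_hz[j], fs_hz)
    peak = np.max(np.abs(y))
    return y / peak if peak > 0 else y


def _time_varying_resonator(x: np.ndarray, f_hz: np.ndarray, bw_hz: float, fs: float) -> np.ndarray:
    """Two-pole resonator y[n] = g x[n] + b1 y[n-1] + b2 y[n-2] with
    per-sample centre frequency (classic formant-synthesizer section)."""
    r = np.exp(-np.pi * bw_hz / fs)
    b2 = -(r**2)
    b1 = 2.0 * r * np.cos(2.0 * np.pi * f_hz / fs)
    g = 1.0 - b1 - b2  # unit gain at DC; relative shape is what matters
    y = np.zeros_like(x)
    y1 = y2 = 0.0
    for k in range(x.size):
        yk = g[k] * x[k] + b1[k] * y1 + b2 * y2
        y2 = y1
        y1 = yk
        y[k] = yk
    return y
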