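"""Annotation and contour I/O.

Reads Praat TextGrid annotations (long and short text dialects), segments
mono WAV recordings by labeled interval, and round-trips the pipeline's
long-format contour CSV schema.

Conventions: times in seconds, 0-based, half-open intervals
``[start, end)`` with sample index ``round(time * fs)`` — Praat semantics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .synth import FORMANTS, FormantContour

__all__ = [
    "AnnotationInterval",
    "Tier",
    "contours_to_table",
    "read_contours",
    "read_textgrid",
    "read_wav",
    "segment_audio",
    "table_to_contours",
    "write_contours",
    "write_wav",
]

#: interval labels treated as non-vocalization by default
DEFAULT_EXCLUDE_LABELS = frozenset({"", "noise", "silence"})

#: columns of the long-format contour CSV schema, in order
CONTOUR_COLUMNS = [
    "voc_id",
    "vocal_type",
    "session_id",
    "day",
    "time_s",
    "formant",
    "freq_hz",
    "is_outlier",
]


@dataclass(frozen=True)
class AnnotationInterval:
    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(f"interval end {self.end_s} <= start {self.start_s}")


@dataclass
class Tier:
    name: str
    intervals: list[AnnotationInterval] = field(default_factory=list)

    def validate(self) -> "Tier":
        ivs = sorted(self.intervals, key=lambda iv: iv.start_s)
        for a, b in zip(ivs, ivs[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise ValueError(
                    f"tier {self.name!r}: overlapping intervals "
                    f"({a.start_s}-{a.end_s}) and ({b.start_s}-{b.end_s})"
                )
        self.intervals = ivs
        return self


class TextGridParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


def read_textgrid(path: str | Path) -> list[Tier]:
    """Parse a Praat TextGrid file (long or short text format).

    Returns interval tiers only (point tiers are skipped); labels are
    preserved verbatim and times are in seconds.
    """
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    lines = text.splitlines()
    if not lines or "ooTextFile" not in text.split("\n", 1)[0]:
        raise TextGridParseError("not an ooTextFile TextGrid header", line=1)
    if not any("TextGrid" in ln for ln in lines[:3]):
        raise TextGridParseError("missing TextGrid object class", line=2)
    is_long = any(re.match(r"\s*xmin\s*=", ln) for ln in lines)
    tiers = _parse_long(lines) if is_long else _parse_short(lines)
    return [t.validate() for t in tiers]


_NUM = r"[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?"


def _parse_long(lines: list[str]) -> list[Tier]:
    tiers: list[Tier] = []
    cur: Tier | None = None
    pending: dict[str, float | str] = {}
    for i, raw in enumerate(lines, start=1):
        ln = raw.strip()
        m = re.match(r'class\s*=\s*"(.*)"', ln)
        if m:
            if m.group(1) == "IntervalTier":
                cur = Tier(name="")
                tiers.append(cur)
            elif m.group(1) == "TextTier":
                cur = None  # point tier: skip
            continue
        if cur is None:
            continue
        m = re.match(r'name\s*=\s*"(.*)"', ln)
        if m and not cur.name:
            cur.name = m.group(1)
            continue
        m = re.match(rf"xmin\s*=\s*({_NUM})", ln)
        if m and re.match(r"\s*intervals\s*\[", lines[i - 2].strip() if i >= 2 else ""):
            pending = {"xmin": float(m.group(1))}
            continue
        m = re.match(rf"xmax\s*=\s*({_NUM})", ln)
        if m and "xmin" in pending and "xmax" not in pending:
            pending["xmax"] = float(m.group(1))
            continue
        m = re.match(r'text\s*=\s*"(.*)"\s*$', ln)
        if m and "xmax" in pending:
            try:
                cur.intervals.append(
                    AnnotationInterval(
                        float(pending["xmin"]), float(pending["xmax"]), _unescape(m.group(1))
                    )
                )
            except ValueError as e:
                raise TextGridParseError(str(e), line=i) from e
            pending = {}
    return tiers


def _parse_short(lines: list[str]) -> list[Tier]:
    # short format: bare values in a fixed order
    toks = [ln.strip() for ln in lines[3:] if ln.strip() != ""]
    pos = 0

    def take() -> str:
        nonlocal pos
        if pos >= len(toks):
            raise TextGridParseError("unexpected end of file", line=len(lines))
        tok = toks[pos]
        pos += 1
        return tok

    take()  # global xmin
    take()  # global xmax
    if take() != "<exists>":
        return []
    n_tiers = int(take())
    tiers: list[Tier] = []
    for _ in range(n_tiers):
        klass = take().strip('"')
        name = _unescape(take().strip('"'))
        take()  # tier xmin
        take()  # tier xmax
        n_items = int(take())
        if klass == "IntervalTier":
            tier = Tier(name=name)
            for _ in range(n_items):
                try:
                    xmin = float(take())
                    xmax = float(take())
                    label = _unescape(take().strip('"'))
                    tier.intervals.append(AnnotationInterval(xmin, xmax, label))
                except ValueError as e:
                    raise TextGridParseError(str(e), line=pos + 3) from e
            tiers.append(tier)
        else:  # point tier: consume and skip
            for _ in range(n_items):
                take(), take()
    return tiers


def _unescape(s: str) -> str:
    return s.replace('""', '"')


def read_wav(path: str | Path) -> tuple[int, np.ndarray]:
    """Read a mono WAV file (PCM 16/24-bit or float32) as float64 in [-1, 1]."""
    fs, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got {data.ndim} channels")
    if data.dtype == np.int16:
        x = data / 32768.0
    elif data.dtype == np.int32:  # 24-bit PCM arrives as int32
        x = data / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        x = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported sample format {data.dtype}")
    return int(fs), x


def write_wav(path: str | Path, fs: int, x: np.ndarray, dtype: str = "int16") -> None:
    """Write a mono waveform scaled from [-1, 1] (PCM16 or float32)."""
    x = np.asarray(x, dtype=float)
    if dtype == "int16":
        wavfile.write(str(path), fs, np.clip(x * 32767, -32768, 32767).astype(np.int16))
    elif dtype == "float32":
        wavfile.write(str(path), fs, x.astype(np.float32))
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")


def segment_audio(
    wav: np.ndarray,
    fs: int,
    tiers: list[Tier],
    label_filter: set[str] | None = None,
    exclude_labels: frozenset[str] = DEFAULT_EXCLUDE_LABELS,
) -> list[tuple[str, np.ndarray, dict]]:
    """Cut a mono waveform into one segment per labeled annotation interval.

    Intervals whose label is in ``exclude_labels`` (noise/silence markers,
    empty labels) are dropped; if ``label_filter`` is non-empty only its
    labels are kept. Segment boundaries are half-open ``[start, end)`` at
    sample index ``round(time * fs)``.
    """
    if wav.ndim != 1:
        raise ValueError("segment_audio requires mono audio")
    dur = wav.size / fs
    out: list[tuple[str, np.ndarray, dict]] = []
    k = 0
    for tier in tiers:
        for iv in tier.intervals:
            if iv.label in exclude_labels:
                continue
            if label_filter and iv.label not in label_filter:
                continue
            if iv.end_s > dur + 0.5 / fs:
                raise ValueError(
                    f"interval ({iv.start_s}, {iv.end_s}) exceeds file duration {dur:.6f} s"
                )
            i0 = int(round(iv.start_s * fs))
            i1 = int(round(iv.end_s * fs))
            voc_id = f"{tier.name or 'tier'}_{k:04d}"
            out.append(
                (voc_id, wav[i0:i1], {"label": iv.label, "start_s": iv.start_s, "end_s": iv.end_s})
            )
            k += 1
    return out


def contours_to_table(contours: list[FormantContour]) -> pd.DataFrame:
    """Long-format table with one row per (voc_id, time, formant)."""
    frames = []
    for c in contours:
        n = c.n_points
        frames.append(
            pd.DataFrame(
                {
                    "voc_id": np.repeat(c.voc_id, 3 * n),
                    "vocal_type": c.vocal_type,
                    "session_id": c.session_id,
                    "day": c.day,
                    "time_s": np.tile(c.times_s, 3),
                    "formant": np.repeat(FORMANTS, n),
                    "freq_hz": c.f_hz.reshape(-1),
                    "is_outlier": False,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return table


def table_to_contours(table: pd.DataFrame, drop_outliers: bool = True) -> list[FormantContour]:
    """Rebuild FormantContour objects from a long-format table.

    Rows flagged ``is_outlier`` become missing (NaN) when ``drop_outliers``.
    """
    out = []
    for voc_id, g in table.groupby("voc_id", sort=False):
        times = np.sort(g["time_s"].unique())
        f = np.full((3, times.size), np.nan)
        t_index = {t: i for i, t in enumerate(times)}
        for _, row in g.iterrows():
            j = FORMANTS.index(row["formant"])
            v = row["freq_hz"]
            if drop_outliers and row["is_outlier"]:
                v = np.nan
            f[j, t_index[row["time_s"]]] = v
        out.append(
            FormantContour(
                voc_id=str(voc_id),
                vocal_type=str(g["vocal_type"].iloc[0]),
                session_id=str(g["session_id"].iloc[0]),
                day=int(g["day"].iloc[0]),
                times_s=times,
                f_hz=f,
            )
        )
    return out


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CONTOUR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"contour table missing columns: {missing}")
    bad = set(table["formant"].unique()) - set(FORMANTS)
    if bad:
        raise ValueError(f"unknown formant codes: {sorted(bad)}")
    finite = table["freq_hz"].notna()
    if (table.loc[finite, "freq_hz"] <= 0).any():
        raise ValueError("freq_hz must be positive or missing")
    if table.duplicated(subset=["voc_id", "time_s", "formant"]).any():
        raise ValueError("duplicate (voc_id, time_s, formant) keys")
    return table[CONTOUR_COLUMNS]


def write_contours(table: pd.DataFrame, path: str | Path) -> None:
    """Write the contour table as UTF-8 CSV; missing frequencies are empty fields."""
    _validate_table(table).to_csv(path, index=False, float_format="%.6f")


def read_contours(path: str | Path) -> pd.DataFrame:
    """Read and validate a contour CSV written by :func:`write_contours`."""
    table = pd.read_csv(
        path,
        dtype={"voc_id": str, "vocal_type": str, "session_id": str, "formant": str},
    )
    table["is_outlier"] = table["is_outlier"].astype(bool)
    return _validate_table(table)
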