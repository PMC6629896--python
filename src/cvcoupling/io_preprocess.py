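"""Beat-series containers, delimited I/O, artifact filtering and resampling.

The beat-aligned representation of a recording is three parallel per-beat
series: the tachogram (BBI, ms), the systogram (SBP, mmHg) and the diastogram
(DBP, mmHg).  Coupling estimators downstream consume either the beat-domain
series directly (symbolic dynamics, Poincare plots, baroreflex sequences) or
an equidistantly resampled, z-normalized version (partial directed coherence,
spectral indices).

Artifact handling follows adaptive-variance practice: a beat is flagged when
it deviates from a local rolling mean by more than ``lambda_sd`` rolling
standard deviations (plus a small floor proportional to the local mean, so
that clean low-noise stretches are never flagged), and flagged beats are
replaced by linear interpolation between the nearest clean neighbours.
Recordings with more than 5% flagged beats are conventionally excluded.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateInputError,
    FormatError,
    InsufficientDataError,
    ParameterError,
    ValidationError,
)

GROUPS = ("CON", "IDC_LR", "IDC_HR", "UNKNOWN")
CHANNELS = ("BBI", "SBP", "DBP")

#: fraction of flagged beats above which a recording is excluded
DEFAULT_EXCLUSION_FRACTION = 0.05

_CSV_COLUMNS = ("subject_id", "group", "beat_index", "bbi_ms", "sbp_mmhg", "dbp_mmhg")


@dataclass
class BeatSeries:
    """Beat-aligned BBI/SBP/DBP series for one subject.

    Invariants (checked in ``__post_init__``): equal lengths >= 1, positive
    BBI, SBP strictly above DBP at every beat.
    """

    subject_id: str
    group: str
    bbi: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    artifact_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.bbi = np.asarray(self.bbi, dtype=float)
        self.sbp = np.asarray(self.sbp, dtype=float)
        self.dbp = np.asarray(self.dbp, dtype=float)
        if self.artifact_flags is None:
            self.artifact_flags = np.zeros(len(self.bbi), dtype=bool)
        self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group label {self.group!r}")
        n = len(self.bbi)
        if n < 1:
            raise ValidationError("beat series must contain at least one beat")
        if not (len(self.sbp) == len(self.dbp) == len(self.artifact_flags) == n):
            raise ValidationError("bbi, sbp, dbp and artifact_flags must have equal length")
        if np.any(self.bbi <= 0):
            raise ValidationError("all beat-to-beat intervals must be positive")
        if np.any(self.sbp <= self.dbp):
            bad = int(np.argmax(self.sbp <= self.dbp))
            raise ValidationError(f"sbp must exceed dbp at every beat (violated at beat {bad})")

    def __len__(self) -> int:
        return len(self.bbi)

    def channel(self, name: str) -> np.ndarray:
        """Return the per-beat values of one channel (``BBI``/``SBP``/``DBP``)."""
        try:
            return {"BBI": self.bbi, "SBP": self.sbp, "DBP": self.dbp}[name]
        except KeyError:
            raise ParameterError(f"unknown channel {name!r}") from None

    def beat_times(self) -> np.ndarray:
        """Beat occurrence times in seconds, first beat at t = 0.

        ``bbi[n]`` is the interval *ending* at beat ``n``; the interval before
        the first recorded beat carries no placement information, so beat 0 is
        anchored at zero and later beats at the cumulative sum of the
        subsequent intervals.
        """
        t = np.concatenate(([0.0], np.cumsum(self.bbi[1:]))) / 1000.0
        return t

    @property
    def artifact_fraction(self) -> float:
        return float(np.mean(self.artifact_flags))


@dataclass
class UniformSeries:
    """One channel sampled on an equidistant grid (default 2 Hz)."""

    values: np.ndarray
    channel: str
    sample_rate: float = 2.0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.channel not in CHANNELS:
            raise ParameterError(f"unknown channel {self.channel!r}")
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be positive")
        if self.normalized:
            if abs(float(np.mean(self.values))) > 1e-9:
                raise ValidationError("normalized series must have zero mean")
            if abs(float(np.var(self.values)) - 1.0) > 1e-9:
                raise ValidationError("normalized series must have unit variance")

    def __len__(self) -> int:
        return len(self.values)


def read_beat_series(path: str | Path, delimiter: str = ",") -> list[BeatSeries]:
    """Read one or more subjects from a delimited beat-series file.

    The file must carry a header with at least ``bbi_ms``, ``sbp_mmhg`` and
    ``dbp_mmhg`` columns; ``subject_id`` and ``group`` are optional for
    single-subject files.  Row order is preserved; artifact flags start false.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for col in ("bbi_ms", "sbp_mmhg", "dbp_mmhg"):
            if col not in header:
                raise FormatError(f"missing required column {col!r} in {path}")
        rows = list(reader)
    if not rows:
        raise ValidationError(f"{path} contains a header but no beats")

    def parse(row: dict, col: str, idx: int) -> float:
        try:
            return float(row[col])
        except (TypeError, ValueError):
            raise FormatError(f"non-numeric value {row.get(col)!r} in column {col!r} at data row {idx + 1}") from None

    subjects: dict[str, dict[str, list]] = {}
    order: list[str] = []
    for i, row in enumerate(rows):
        sid = row.get("subject_id") or "S0"
        if sid not in subjects:
            subjects[sid] = {"group": row.get("group") or "UNKNOWN", "bbi": [], "sbp": [], "dbp": []}
            order.append(sid)
        rec = subjects[sid]
        rec["bbi"].append(parse(row, "bbi_ms", i))
        rec["sbp"].append(parse(row, "sbp_mmhg", i))
        rec["dbp"].append(parse(row, "dbp_mmhg", i))
    return [
        BeatSeries(subject_id=sid, group=subjects[sid]["group"],
                   bbi=subjects[sid]["bbi"], sbp=subjects[sid]["sbp"], dbp=subjects[sid]["dbp"])
        for sid in order
    ]


def write_beat_series(series: Iterable[BeatSeries], path: str | Path, delimiter: str = ",") -> None:
    """Write subjects to a delimited file readable by :func:`read_beat_series`."""
    path = Path(path)
    frames = []
    for s in series:
        frames.append(pd.DataFrame({
            "subject_id": s.subject_id,
            "group": s.group,
            "beat_index": np.arange(len(s)),
            "bbi_ms": s.bbi,
            "sbp_mmhg": s.sbp,
            "dbp_mmhg": s.dbp,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep=delimiter, index=False, columns=list(_CSV_COLUMNS))


def filter_artifacts(
    series: BeatSeries,
    lambda_sd: float = 3.0,
    window: int = 20,
    rel_floor: float = 0.05,
) -> tuple[BeatSeries, float]:
    """Flag and interpolate ectopic beats / artifacts; return (new series, fraction).

    A beat is flagged on any channel when its absolute deviation from the
    centred rolling mean exceeds ``lambda_sd`` rolling standard deviations
    plus ``rel_floor`` times the local mean magnitude (the floor keeps clean
    low-noise recordings flag-free).  Flagged beats are replaced per channel
    by linear interpolation between the nearest unflagged beats.  The input
    object is not modified.
    """
    if window < 3:
        raise ParameterError("window must be at least 3 beats")
    if lambda_sd <= 0:
        raise ParameterError("lambda_sd must be positive")
    if len(series) < window:
        raise InsufficientDataError(f"series of {len(series)} beats shorter than window {window}")

    flags = np.zeros(len(series), dtype=bool)
    for name in CHANNELS:
        x = pd.Series(series.channel(name))
        mean = x.rolling(window, center=True, min_periods=3).mean()
        sd = x.rolling(window, center=True, min_periods=3).std()
        threshold = lambda_sd * sd.to_numpy() + rel_floor * np.abs(mean.to_numpy())
        dev = np.abs(x.to_numpy() - mean.to_numpy())
        flags |= dev > threshold

    if flags.all():
        raise DegenerateInputError("every beat flagged as artifact")

    idx = np.arange(len(series))
    good = ~flags

    def interp(x: np.ndarray) -> np.ndarray:
        out = x.copy()
        out[flags] = np.interp(idx[flags], idx[good], x[good])
        return out

    filtered = BeatSeries(
        subject_id=series.subject_id,
        group=series.group,
        bbi=interp(series.bbi),
        sbp=interp(series.sbp),
        dbp=np.minimum(interp(series.dbp), interp(series.sbp) - 1e-6),
        artifact_flags=flags,
    )
    return filtered, float(np.mean(flags))


def exclusion_mask(fractions: Sequence[float], max_fraction: float = DEFAULT_EXCLUSION_FRACTION) -> np.ndarray:
    """Boolean mask of recordings to *exclude* (artifact fraction above cutoff)."""
    return np.asarray(fractions, dtype=float) > max_fraction


def resample_2hz(series: BeatSeries, channel: str, sample_rate: float = 2.0) -> UniformSeries:
    """Linearly interpolate one channel onto a uniform grid (default 2 Hz).

    Beat times come from the cumulative tachogram (first beat at t = 0); the
    grid runs t = 0, 1/fs, ... up to the last beat time, giving
    ``floor(duration * fs) + 1`` samples.
    """
    if len(series) < 2:
        raise InsufficientDataError("resampling requires at least 2 beats")
    t = series.beat_times()
    x = series.channel(channel)
    duration = t[-1]
    n_samples = int(np.floor(duration * sample_rate)) + 1
    grid = np.arange(n_samples) / sample_rate
    values = np.interp(grid, t, x)
    return UniformSeries(values=values, channel=channel, sample_rate=sample_rate)


def znormalize(series: UniformSeries) -> UniformSeries:
    """Return a zero-mean unit-variance copy (population-SD convention).

    The population standard deviation (divide by N) is used so the output
    variance is exactly 1; idempotent within 1e-9.
    """
    x = series.values
    sd = float(np.std(x))
    if sd == 0.0:
        raise DegenerateInputError("cannot z-normalize a constant series")
    values = (x - float(np.mean(x))) / sd
    return replace(series, values=values, normalized=True)
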