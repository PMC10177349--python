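"""Reading, validation and cleaning of GPS collar fixes.

A *fix* is a single collar position record: animal id, timezone-aware
timestamp, projected easting/northing in metres, and time-to-fix (the seconds
the receiver needed to obtain the position, a quality proxy).  Collars record
bursts of fixes at fixed offsets within a minute, then sleep; see
:class:`FixSchedule`.

Cleaning follows the standard collar-QC recipe for fenced paddocks: drop
fixes whose time-to-fix exceeds a threshold (slow fixes are positionally
unreliable), drop fixes outside the paddock boundary, and drop duplicate
(animal, timestamp) records.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

#: canonical column names used throughout the package
FIX_COLUMNS = ("animal_id", "timestamp", "easting", "northing", "ttf")

#: default mapping from on-disk CSV headers to canonical names
DEFAULT_SCHEMA = {
    "animal_id": "animal_id",
    "timestamp": "timestamp",
    "easting": "easting_m",
    "northing": "northing_m",
    "ttf": "ttf_s",
}


@dataclass
class FixSchedule:
    """Collar duty cycle: a burst of fixes at ``burst_offsets`` seconds within a
    minute, followed by ``sleep`` seconds of sleep (default 0/15/30/45/60 s then
    4 min sleep, i.e. five fixes per five-minute cycle)."""

    burst_offsets: tuple[float, ...] = (0.0, 15.0, 30.0, 45.0, 60.0)
    sleep: float = 240.0

    def __post_init__(self) -> None:
        if any(b > a for a, b in zip(self.burst_offsets[1:], self.burst_offsets)):
            raise ValueError("burst_offsets must be nondecreasing")
        if self.sleep <= 0:
            raise ValueError("sleep must be positive")

    @property
    def cycle_seconds(self) -> float:
        """Length of one full duty cycle (burst span + sleep)."""
        return self.burst_offsets[-1] - self.burst_offsets[0] + self.sleep

    @property
    def fixes_per_hour(self) -> float:
        return 3600.0 / self.cycle_seconds * len(self.burst_offsets)


@dataclass
class PaddockBoundary:
    """A closed paddock polygon in projected coordinates (metres)."""

    polygon: Polygon
    name: str = "paddock"

    def __post_init__(self) -> None:
        if not isinstance(self.polygon, Polygon):
            self.polygon = Polygon(self.polygon)
        if not self.polygon.is_valid:
            raise ValueError(f"boundary polygon for {self.name!r} is invalid (self-intersecting?)")
        if self.polygon.area <= 0:
            raise ValueError(f"boundary polygon for {self.name!r} has zero area")

    def contains(self, easting, northing) -> np.ndarray:
        """Vectorised point-in-polygon test; points on the ring count as inside."""
        pts = shapely.points(np.asarray(easting, dtype=float), np.asarray(northing, dtype=float))
        return shapely.covers(self.polygon, pts)


@dataclass
class Trajectory:
    """Time-ordered fixes of one animal within one trial."""

    animal_id: str
    fixes: pd.DataFrame  # columns FIX_COLUMNS (+ hour_index once assigned)
    treatment: str | None = None  # e.g. "IP" (improved pasture) / "NP" (native pasture)
    trial: str | None = None  # e.g. "T1".."T4"

    def __post_init__(self) -> None:
        missing = [c for c in FIX_COLUMNS if c not in self.fixes.columns]
        if missing:
            raise ValueError(f"fix table missing columns: {missing}")
        if not self.fixes["timestamp"].is_monotonic_increasing:
            self.fixes = self.fixes.sort_values("timestamp", kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.fixes)


@dataclass
class CleanReport:
    """Bookkeeping of a cleaning pass; removal counts are per rule."""

    n_input: int
    n_retained: int
    n_slow_fix: int  # time-to-fix above threshold
    n_outside: int  # outside the paddock boundary
    n_duplicate: int  # duplicate (animal, timestamp)
    max_ttf: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def __add__(self, other: "CleanReport") -> "CleanReport":
        if self.max_ttf != other.max_ttf:
            raise ValueError("cannot combine reports with different thresholds")
        return CleanReport(
            *(getattr(self, f) + getattr(other, f) for f in
              ("n_input", "n_retained", "n_slow_fix", "n_outside", "n_duplicate")),
            max_ttf=self.max_ttf,
        )


def read_fixes(
    path: str | Path,
    schema: dict[str, str] | None = None,
    treatment: str | None = None,
    trial: str | None = None,
) -> list[Trajectory]:
    """Read a delimited fix table into one :class:`Trajectory` per animal.

    Parameters
    ----------
    path
        CSV file with one row per fix.
    schema
        Mapping from canonical names (``animal_id``, ``timestamp``, ``easting``,
        ``northing``, ``ttf``) to the file's column headers; defaults to
        ``animal_id, timestamp, easting_m, northing_m, ttf_s``.

    Rows with unparseable timestamps or non-numeric coordinates are rejected
    and counted in a log warning rather than aborting the read.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    df = pd.read_csv(path)
    missing = [v for v in schema.values() if v not in df.columns]
    if missing:
        raise ValueError(f"fix table {path} is missing required columns: {missing}")
    df = df.rename(columns={v: k for k, v in schema.items()})[list(FIX_COLUMNS)]
    if df.empty:
        warnings.warn(f"fix table {path} contains no rows", stacklevel=2)
        return []

    n_raw = len(df)
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    for col in ("easting", "northing", "ttf"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = df["timestamp"].notna() & np.isfinite(df[["easting", "northing", "ttf"]]).all(axis=1)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("rejected %d malformed rows of %d in %s", n_bad, n_raw, path)
    df = df[ok]

    out = []
    for animal, grp in df.groupby("animal_id", sort=True):
        fixes = grp.sort_values("timestamp", kind="stable").reset_index(drop=True)
        out.append(Trajectory(str(animal), fixes, treatment=treatment, trial=trial))
    return out


def clean_fixes(
    traj: Trajectory,
    boundary: PaddockBoundary,
    max_ttf: float = 16.0,
) -> tuple[Trajectory, CleanReport]:
    """Apply the collar-QC rules and return the cleaned trajectory plus a report.

    Rules, applied in order:

    1. duplicate (animal, timestamp) rows: keep the first occurrence;
    2. time-to-fix strictly greater than ``max_ttf`` seconds (default 16 s):
       removed; a fix at exactly the threshold is retained;
    3. position outside the paddock boundary: removed; a fix exactly on the
       boundary ring is retained (fence-line residency is a real signal).

    The retained set is a subset of the input in the original order, so the
    operation is idempotent. All fixes removed is reported as a warning, not
    an error.
    """
    fx = traj.fixes
    n_input = len(fx)

    dup = fx.duplicated(subset="timestamp", keep="first").to_numpy()
    slow = (fx["ttf"].to_numpy() > max_ttf) & ~dup
    inside = boundary.contains(fx["easting"].to_numpy(), fx["northing"].to_numpy())
    outside = ~inside & ~dup & ~slow

    keep = ~(dup | slow | outside)
    report = CleanReport(
        n_input=n_input,
        n_retained=int(keep.sum()),
        n_slow_fix=int(slow.sum()),
        n_outside=int(outside.sum()),
        n_duplicate=int(dup.sum()),
        max_ttf=max_ttf,
    )
    if n_input and report.n_retained == 0:
        warnings.warn(
            f"all {n_input} fixes of animal {traj.animal_id!r} removed by cleaning",
            stacklevel=2,
        )
    cleaned = Trajectory(
        traj.animal_id,
        fx[keep].reset_index(drop=True),
        treatment=traj.treatment,
        trial=traj.trial,
    )
    return cleaned, report


def assign_hours(traj: Trajectory, trial_start: pd.Timestamp) -> Trajectory:
    """Attach a 1-based categorical ``hour_index`` to every fix.

    Hour bins are half-open: hour ``h`` covers
    ``[trial_start + (h-1)*3600 s, trial_start + h*3600 s)``, so hour 1 is the
    first hour of recording. Re-application is a no-op.
    """
    trial_start = pd.Timestamp(trial_start)
    if trial_start.tzinfo is None:
        raise ValueError("trial_start must be timezone-aware")
    fx = traj.fixes
    delta = (fx["timestamp"] - trial_start).dt.total_seconds()
    if (delta < 0).any():
        bad = fx.loc[delta.idxmin()]
        raise ValueError(
            f"fix of animal {traj.animal_id!r} at {bad['timestamp']} precedes trial start {trial_start}"
        )
    fx = fx.assign(hour_index=(np.floor(delta / 3600.0).astype(int) + 1))
    return Trajectory(traj.animal_id, fx, treatment=traj.treatment, trial=traj.trial)


def pool_fixes(trajs: list[Trajectory]) -> pd.DataFrame:
    """Concatenate trajectories into one tidy fix table (one row per fix)."""
    if not trajs:
        return pd.DataFrame(columns=list(FIX_COLUMNS) + ["treatment", "trial"])
    frames = []
    for t in trajs:
        df = t.fixes.copy()
        df["animal_id"] = t.animal_id
        df["treatment"] = t.treatment
        df["trial"] = t.trial
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
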