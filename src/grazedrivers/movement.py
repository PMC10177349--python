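"""Movement metrics from cleaned trajectories.

Distances between consecutive fixes are Euclidean in the projected plane;
speed is distance over elapsed seconds. Hourly summaries average first within
an animal-hour and then across the collared animals of a treatment, so every
animal carries equal weight regardless of fix dropout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trajectory import Trajectory

#: behaviour recoding used for scan-sampled observations; drinking is dropped
#: (vanishingly rare in the field protocol this mirrors)
BEHAVIOR_RECODE = {
    "S": "S",
    "standing": "S",
    "L": "L",
    "lying": "L",
    "standing-grazing": "G",
    "walking-grazing": "G",
    "standing-walking-grazing": "G",
    "walking": "M",
    "running": "M",
    "drinking": None,
}


def step_distance(a, b, aa, bb):
    """Euclidean distance in metres between fixes (a, b) and (aa, bb).

    ``a``/``aa`` are the first and second eastings, ``b``/``bb`` the first and
    second northings. Vectorised over array inputs.
    """
    a, b, aa, bb = (np.asarray(v, dtype=float) for v in (a, b, aa, bb))
    if not all(np.all(np.isfinite(v)) for v in (a, b, aa, bb)):
        raise ValueError("coordinates must be finite")
    return np.hypot(aa - a, bb - b)


def step_records(traj: Trajectory, schedule_spacing: float = 15.0) -> pd.DataFrame:
    """Distances and speeds between consecutive retained fixes of one animal.

    Returns a frame with one row per step: ``t0, t1, distance, elapsed, speed,
    hour_index`` (hour of the step start, if assigned) and ``gap`` — True when
    the elapsed time exceeds twice the collar schedule spacing, i.e. the step
    spans fixes removed by cleaning or a sleep period, so its "distance" is a
    chord rather than a path length.
    """
    fx = traj.fixes
    if len(fx) < 2:
        cols = ["animal_id", "t0", "t1", "distance", "elapsed", "speed", "gap"]
        return pd.DataFrame(columns=cols)
    e = fx["easting"].to_numpy()
    n = fx["northing"].to_numpy()
    t = fx["timestamp"]
    elapsed = t.diff().dt.total_seconds().to_numpy()[1:]
    if np.any(elapsed <= 0):
        raise ValueError("non-increasing timestamps; clean duplicates first")
    dist = step_distance(e[:-1], n[:-1], e[1:], n[1:])
    out = pd.DataFrame(
        {
            "animal_id": traj.animal_id,
            "t0": t.to_numpy()[:-1],
            "t1": t.to_numpy()[1:],
            "distance": dist,
            "elapsed": elapsed,
            "speed": dist / elapsed,
            "gap": elapsed > 2 * schedule_spacing,
        }
    )
    if "hour_index" in fx.columns:
        out["hour_index"] = fx["hour_index"].to_numpy()[:-1]
    return out


def step_speed(t0, t1, a, b, aa, bb) -> float:
    """Speed (m/s) of a single step between two timestamped fixes."""
    elapsed = (pd.Timestamp(t1) - pd.Timestamp(t0)).total_seconds()
    if elapsed <= 0:
        raise ValueError("step must have strictly positive elapsed time")
    return float(step_distance(a, b, aa, bb)) / elapsed


def hourly_mean_speed(trajs: list[Trajectory], include_gaps: bool = False) -> pd.DataFrame:
    """Mean speed per hour, averaged per animal-hour then across animals.

    Steps are binned by the hour of their starting fix. Hours with no steps
    are absent from the result (missing, not zero). Gap-spanning steps are
    excluded by default since their chord speed understates true movement.
    """
    frames = [step_records(t) for t in trajs]
    steps = pd.concat([f for f in frames if len(f)], ignore_index=True) if frames else pd.DataFrame()
    if steps.empty:
        return pd.DataFrame(columns=["hour_index", "mean_speed", "n_animals"])
    if "hour_index" not in steps.columns:
        raise ValueError("assign hours before computing hourly summaries")
    if not include_gaps:
        steps = steps[~steps["gap"]]
    per_animal = (
        steps.groupby(["hour_index", "animal_id"], observed=True)["speed"].mean().reset_index()
    )
    out = (
        per_animal.groupby("hour_index")["speed"]
        .agg(mean_speed="mean", n_animals="count")
        .reset_index()
    )
    return out


def classify_movement_state(speed, threshold: float = 0.15) -> np.ndarray:
    """Label speeds as ``"fast"`` (strictly above threshold m/s) or ``"slow"``.

    The default 0.15 m/s separates travelling/active grazing from resting in
    collar-speed summaries.
    """
    speed = np.asarray(speed, dtype=float)
    if np.any(speed < 0):
        raise ValueError("speed must be nonnegative")
    return np.where(speed > threshold, "fast", "slow")


def recode_behavior(raw_code: str) -> str | None:
    """Collapse scan-sampling codes to {S, L, G, M}; drinking returns None (dropped).

    Grazing variants (standing/walking/standing-walking grazing) merge to G;
    walking and running merge to M (moving). Codes are matched after
    lowercasing and normalising separators.
    """
    key = str(raw_code).strip().lower().replace(" ", "-").replace("_", "-")
    if key in ("s", "l"):
        key = key.upper()
    if key not in BEHAVIOR_RECODE and raw_code in BEHAVIOR_RECODE:
        key = raw_code
    if key not in BEHAVIOR_RECODE:
        raise ValueError(
            f"unknown behaviour code {raw_code!r}; expected one of {sorted(BEHAVIOR_RECODE)}"
        )
    return BEHAVIOR_RECODE[key]


def recode_behavior_table(obs: pd.DataFrame, code_col: str = "raw_code") -> pd.DataFrame:
    """Recode a scan-observation table; drinking rows are dropped."""
    recoded = obs[code_col].map(recode_behavior)
    out = obs.assign(recoded=recoded)
    return out[out["recoded"].notna()].reset_index(drop=True)


def hourly_activity_counts(counts: pd.DataFrame, trial_start: pd.Timestamp) -> pd.DataFrame:
    """Aggregate per-minute accelerometer counts to per-animal-hour totals.

    ``counts`` has columns ``animal_id, minute_timestamp, steps, lying``.
    Returns per (animal, hour) sums plus a treatment-level mean across animals
    (columns ``step_count``, ``lying_count``). Hours with no records for an
    animal are simply absent. Overlapping minutes for one animal are an error.
    """
    df = counts.copy()
    df["minute_timestamp"] = pd.to_datetime(df["minute_timestamp"], utc=True)
    if df.duplicated(subset=["animal_id", "minute_timestamp"]).any():
        raise ValueError("overlapping per-minute records for an animal")
    trial_start = pd.Timestamp(trial_start)
    delta = (df["minute_timestamp"] - trial_start).dt.total_seconds()
    if (delta < 0).any():
        raise ValueError("count records precede trial start")
    df["hour_index"] = np.floor(delta / 3600.0).astype(int) + 1
    per_animal = (
        df.groupby(["animal_id", "hour_index"], observed=True)[["steps", "lying"]]
        .sum()
        .rename(columns={"steps": "step_count", "lying": "lying_count"})
        .reset_index()
    )
    return per_animal


def mean_activity_by_hour(per_animal: pd.DataFrame) -> pd.DataFrame:
    """Across-animal mean of hourly activity counts (one row per hour)."""
    return (
        per_animal.groupby("hour_index")[["step_count", "lying_count"]].mean().reset_index()
    )
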