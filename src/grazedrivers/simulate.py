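"""Synthetic paddock trials with known residency drivers.

No public collar dataset accompanies the analysis this package implements, so
validation rests on simulation: a rectangular paddock with trees, a water
trough, an elevation surface and an NDVI surface; hourly weather; and a flock
of collared animals moving as a biased correlated random walk whose bias is
the gradient of a utility surface

    U(x, t) = w_NDVI z(NDVI) + w_EL z(EL) + w_NT z(-NT) + w_NW z(-NW)
              + w_shelter z(-NT) · 1[chill(t) > threshold]

over standardised covariate fields (``z``), plus optional attraction to the
flock centroid. The driver weights are the ground truth that the
random-forest importance analysis must recover. Activity states
(resting / grazing / travelling) follow a diurnal schedule with dawn and dusk
grazing peaks and set the per-minute step length.

A collar observation model then turns the minute-resolution truth into raw
fix tables with the real duty cycle (a burst of fixes within a minute, then
sleep), positional jitter, slow time-to-fix draws and dropout — so the
cleaning stage has genuine work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon

from .covariates import LandscapeFeatures, near_distance, wind_chill
from .raster import Raster
from .residency import build_grid
from .trajectory import FixSchedule, PaddockBoundary, Trajectory

STATES = ("resting", "grazing", "travelling")


@dataclass
class SimConfig:
    """Full description of one simulated trial; the seed fixes everything."""

    seed: int = 0
    # paddock (~22.5 ha, the scale of a small grazing trial paddock)
    width: float = 500.0
    height: float = 450.0
    cell_size: float = 5.0
    n_trees: int = 40
    trees_clustered_north: bool = False  # native-pasture style shelter belt
    trough_xy: tuple[float, float] = (15.0, 15.0)  # southwestern corner
    elevation_range: tuple[float, float] = (930.0, 985.0)
    ndvi_range: tuple[float, float] = (0.1, 0.4)
    field_smoothness: float = 10.0  # gaussian sigma of random fields, in cells
    # flock & trial
    n_animals: int = 15
    n_days: int = 6
    trial_start: str = "2014-04-23T00:00:00+10:00"
    # driver weights on standardised covariates (the ground truth)
    w_ndvi: float = 0.0
    w_el: float = 0.0
    w_nt: float = 0.0  # attraction to trees
    w_nw: float = 0.0  # attraction to the water trough
    w_shelter: float = 0.0  # extra tree attraction when chill exceeds threshold
    chill_threshold: float = 950.0  # kJ m^-2 h^-1
    # movement (m/s by activity state; travelling is above the 0.15 m/s cutoff)
    speed_resting: float = 0.01
    speed_grazing: float = 0.08
    speed_travelling: float = 0.30
    heading_persistence: float = 0.6
    heading_noise: float = 0.6
    bias_strength: float = 1.5
    cohesion: float = 0.15
    state_persistence: float = 0.85
    # weather
    temp_mean: float = 8.0
    temp_amplitude: float = 6.0
    temp_peak_hour: int = 14
    rain_prob: float = 0.08
    rain_mean_mm: float = 1.5
    wind_mean: float = 4.0
    wind_sd: float = 1.5
    wind_ar: float = 0.8
    # collar observation model
    schedule: FixSchedule = field(default_factory=FixSchedule)
    jitter_sd: float = 0.8
    p_slow_fix: float = 0.05  # P(time-to-fix > 16 s)
    dropout: float = 0.02

    @property
    def n_minutes(self) -> int:
        return self.n_days * 1440


@dataclass
class SimTruth:
    """Ground truth of a simulated trial: what the pipeline must recover."""

    config: SimConfig
    states: np.ndarray  # (n_minutes, n_animals) int codes into STATES
    positions: np.ndarray  # (n_minutes + 1, n_animals, 2) metres
    weights: dict[str, float]
    hourly_utility: np.ndarray | None = None  # (n_hours, n_rows, n_cols)

    def grazing_fraction_by_hour(self) -> pd.Series:
        g = (self.states == STATES.index("grazing")).mean(axis=1)
        hours = np.arange(len(g)) // 60 + 1
        return pd.Series(g).groupby(hours).mean().rename_axis("hour_index")


def _smooth_field(shape: tuple[int, int], sigma: float, lo: float, hi: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Smooth random surface scaled exactly into [lo, hi]."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    f = (f - f.min()) / (f.max() - f.min() + 1e-300)
    return lo + f * (hi - lo)


def generate_landscape(config: SimConfig) -> LandscapeFeatures:
    """Deterministic paddock layers for a config (seeded sub-stream)."""
    rng = np.random.default_rng([config.seed, 1])
    boundary = PaddockBoundary(
        Polygon([(0, 0), (config.width, 0), (config.width, config.height), (0, config.height)]),
        name="synthetic-paddock",
    )
    spec = build_grid(boundary, config.cell_size)
    shape = (spec.n_rows, spec.n_cols)

    lo, hi = config.elevation_range
    # gentle north-rising plane plus smooth relief, rescaled into the range
    rows = np.arange(shape[0])[:, None] / max(shape[0] - 1, 1)
    plane = rows * np.ones(shape)
    relief = _smooth_field(shape, config.field_smoothness, 0.0, 1.0, rng)
    z = 0.6 * plane + 0.4 * relief
    elevation = lo + (z - z.min()) / (z.max() - z.min()) * (hi - lo)

    ndvi = _smooth_field(shape, config.field_smoothness, *config.ndvi_range, rng)

    if config.trees_clustered_north:
        n_north = int(round(0.9 * config.n_trees))
        xs = rng.uniform(0, config.width, config.n_trees)
        ys = np.concatenate([
            rng.uniform(2 * config.height / 3, config.height, n_north),
            rng.uniform(0, 2 * config.height / 3, config.n_trees - n_north),
        ])
        trees = np.column_stack([xs, ys])
    else:
        trees = np.column_stack([
            rng.uniform(0, config.width, config.n_trees),
            rng.uniform(0, config.height, config.n_trees),
        ])

    return LandscapeFeatures(
        boundary=boundary,
        trees=trees,
        troughs=np.asarray([config.trough_xy], dtype=float),
        fences=None,  # boundary edges serve as fence lines
        elevation=Raster(spec.origin_x, spec.origin_y, config.cell_size, elevation),
        ndvi=Raster(spec.origin_x, spec.origin_y, config.cell_size, ndvi),
    )


def generate_weather(config: SimConfig) -> pd.DataFrame:
    """Hourly weather: sinusoidal diurnal temperature, sparse rain, AR(1) wind."""
    if config.n_days < 1:
        raise ValueError("n_days must be at least 1")
    rng = np.random.default_rng([config.seed, 2])
    n_hours = config.n_days * 24
    start = pd.Timestamp(config.trial_start)
    times = pd.date_range(start, periods=n_hours, freq="h")
    hod = times.hour.to_numpy()
    temp = config.temp_mean + config.temp_amplitude * np.cos(
        2 * np.pi * (hod - config.temp_peak_hour) / 24.0
    )
    temp = temp + rng.normal(0, 0.3, n_hours)
    rain = np.where(
        rng.random(n_hours) < config.rain_prob,
        rng.exponential(config.rain_mean_mm, n_hours),
        0.0,
    )
    wind = np.empty(n_hours)
    wind[0] = config.wind_mean
    eps = rng.normal(0, config.wind_sd, n_hours)
    for i in range(1, n_hours):
        wind[i] = config.wind_mean + config.wind_ar * (wind[i - 1] - config.wind_mean) + eps[i]
    wind = np.clip(wind, 0.0, None)
    if config.temp_amplitude == 0 and config.rain_prob == 0 and config.wind_sd == 0:
        temp = np.full(n_hours, config.temp_mean)
    return pd.DataFrame({"timestamp": times, "temp_c": temp, "rain_mm": rain, "wind_ms": wind})


def _standardize(f: np.ndarray) -> np.ndarray:
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def _grazing_prob(hour_of_day: int) -> tuple[float, float]:
    """(P(grazing), P(travelling)) for an hour of day: dawn/dusk grazing peaks."""
    if 6 <= hour_of_day < 10 or 15 <= hour_of_day < 19:
        return 0.70, 0.12
    if 10 <= hour_of_day < 15:
        return 0.35, 0.10
    if 5 <= hour_of_day < 6 or 19 <= hour_of_day < 21:
        return 0.25, 0.08
    return 0.05, 0.02


def simulate_flock(
    landscape: LandscapeFeatures,
    weather: pd.DataFrame,
    config: SimConfig,
    keep_utility: bool = False,
) -> SimTruth:
    """Minute-resolution biased correlated random walk for the whole flock.

    Headings mix the previous heading (persistence), the local utility
    gradient (driver bias), attraction to the flock centroid (cohesion) and
    circular noise; step length is the state speed times 60 s. The boundary
    reflects; positions never leave the paddock.
    """
    if landscape.boundary.polygon.area <= 0:
        raise ValueError("zero-area paddock")
    rng = np.random.default_rng([config.seed, 3])
    elev = landscape.elevation
    s = elev.cell_size
    shape = elev.values.shape

    # standardised covariate fields on the grid
    X, Y = elev.cell_centers()
    cx, cy = X.ravel(), Y.ravel()
    ndvi_z = _standardize(landscape.ndvi.values)
    el_z = _standardize(elev.values)
    nt_z = _standardize(-near_distance(cx, cy, landscape.trees).reshape(shape))
    nw_z = _standardize(-near_distance(cx, cy, landscape.troughs).reshape(shape))

    base_u = (
        config.w_ndvi * ndvi_z + config.w_el * el_z + config.w_nt * nt_z + config.w_nw * nw_z
    )
    chill = wind_chill(
        weather["temp_c"].to_numpy(), weather["wind_ms"].to_numpy(), weather["rain_mm"].to_numpy()
    )

    n_min, n_a = config.n_minutes, config.n_animals
    n_hours = len(weather)
    if n_hours * 60 < n_min:
        raise ValueError("weather series shorter than the trial")

    # hourly utility gradients (chill toggles the shelter term); the gradient
    # keeps its magnitude — scaled by the field correlation length — so the
    # driver weights set the *strength* of attraction, not just its direction
    gain = 0.25 * config.field_smoothness * config.cell_size
    grads = {}
    utilities = np.empty((n_hours, *shape)) if keep_utility else None
    for h in range(n_hours):
        u = base_u + (config.w_shelter * nt_z if chill[h] > config.chill_threshold else 0.0)
        if keep_utility:
            utilities[h] = u
        gy, gx = np.gradient(u, s)
        grads[h] = (gain * gx, gain * gy)

    speeds = np.array([config.speed_resting, config.speed_grazing, config.speed_travelling])
    pos = np.empty((n_min + 1, n_a, 2))
    pos[0, :, 0] = rng.uniform(0.05 * config.width, 0.95 * config.width, n_a)
    pos[0, :, 1] = rng.uniform(0.05 * config.height, 0.95 * config.height, n_a)
    heading = rng.uniform(0, 2 * np.pi, n_a)
    states = np.empty((n_min, n_a), dtype=np.int8)
    state = np.full(n_a, STATES.index("resting"), dtype=np.int8)
    start_hod = pd.Timestamp(config.trial_start).hour

    for t in range(n_min):
        hour = t // 60
        hod = (start_hod + hour) % 24
        pg, pt = _grazing_prob(hod)
        resample = rng.random(n_a) >= config.state_persistence
        if resample.any():
            u01 = rng.random(n_a)
            new_state = np.where(u01 < pg, 1, np.where(u01 < pg + pt, 2, 0)).astype(np.int8)
            state = np.where(resample, new_state, state)
        states[t] = state

        p = pos[t]
        row, col = elev.cell_of(p[:, 0], p[:, 1])
        gx, gy = grads[hour]
        bias = np.column_stack([gx[row, col], gy[row, col]])
        centroid = p.mean(axis=0)
        to_c = centroid - p
        c_norm = np.linalg.norm(to_c, axis=1, keepdims=True)
        to_c = np.divide(to_c, c_norm, out=np.zeros_like(to_c), where=c_norm > 0)
        noise_ang = rng.uniform(0, 2 * np.pi, n_a)
        desired = (
            config.heading_persistence * np.column_stack([np.cos(heading), np.sin(heading)])
            + config.bias_strength * bias
            + config.cohesion * to_c
            + config.heading_noise * np.column_stack([np.cos(noise_ang), np.sin(noise_ang)])
        )
        d_norm = np.linalg.norm(desired, axis=1)
        zero = d_norm == 0
        if zero.any():
            desired[zero] = np.column_stack([np.cos(noise_ang[zero]), np.sin(noise_ang[zero])])
            d_norm[zero] = 1.0
        desired /= d_norm[:, None]
        heading = np.arctan2(desired[:, 1], desired[:, 0])

        step = desired * (speeds[state] * 60.0)[:, None]
        new = p + step
        # reflect at the rectangular boundary
        new[:, 0] = np.abs(new[:, 0])
        new[:, 0] = config.width - np.abs(config.width - new[:, 0])
        new[:, 1] = np.abs(new[:, 1])
        new[:, 1] = config.height - np.abs(config.height - new[:, 1])
        pos[t + 1] = new

    return SimTruth(
        config=config,
        states=states,
        positions=pos,
        weights={
            "w_ndvi": config.w_ndvi,
            "w_el": config.w_el,
            "w_nt": config.w_nt,
            "w_nw": config.w_nw,
            "w_shelter": config.w_shelter,
        },
        hourly_utility=utilities,
    )


def observe_gps(truth: SimTruth, config: SimConfig | None = None) -> tuple[pd.DataFrame, dict]:
    """Sample the collar duty cycle from minute-resolution truth.

    Each cycle emits fixes at the burst offsets (positions linearly
    interpolated within the minute) with Gaussian positional jitter; each fix
    draws a time-to-fix that exceeds 16 s with probability ``p_slow_fix`` and
    is dropped entirely with probability ``dropout``. Returns the raw fix
    table (animal_id, timestamp, easting, northing, ttf) and a conservation
    report: scheduled = emitted + dropped.
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 4])
    sched = config.schedule
    start = pd.Timestamp(config.trial_start)
    cycle_min = sched.cycle_seconds / 60.0
    if cycle_min != int(cycle_min):
        raise ValueError("duty cycle must be a whole number of minutes")
    burst_starts = np.arange(0, config.n_minutes, int(cycle_min))
    offsets = np.asarray(sched.burst_offsets)

    rows = []
    n_scheduled = 0
    for a in range(config.n_animals):
        mins = burst_starts[:, None] + offsets[None, :] / 60.0  # fractional minutes
        mins = mins.ravel()
        mins = mins[mins <= config.n_minutes]
        n_scheduled += len(mins)
        m0 = np.floor(mins).astype(int)
        frac = mins - m0
        m0 = np.minimum(m0, config.n_minutes - 1)
        frac = np.where(m0 < np.floor(mins), 1.0, frac)  # exact end-of-trial fix
        p0 = truth.positions[m0, a]
        p1 = truth.positions[m0 + 1, a]
        xy = p0 + frac[:, None] * (p1 - p0)
        xy = xy + rng.normal(0, config.jitter_sd, xy.shape)
        slow = rng.random(len(mins)) < config.p_slow_fix
        ttf = np.where(slow, rng.uniform(17.0, 45.0, len(mins)), rng.uniform(2.0, 15.0, len(mins)))
        keep = rng.random(len(mins)) >= config.dropout
        ts = start + pd.to_timedelta(np.round(mins[keep] * 60.0).astype(int), unit="s")
        rows.append(
            pd.DataFrame(
                {
                    "animal_id": f"A{a + 1:02d}",
                    "timestamp": ts,
                    "easting": xy[keep, 0],
                    "northing": xy[keep, 1],
                    "ttf": ttf[keep],
                }
            )
        )
    fixes = pd.concat(rows, ignore_index=True)
    report = {
        "n_scheduled": int(n_scheduled),
        "n_emitted": int(len(fixes)),
        "n_dropped": int(n_scheduled - len(fixes)),
        "n_slow_planted": int(np.sum(fixes["ttf"] > 16.0)),
    }
    return fixes, report


def fixes_to_trajectories(fixes: pd.DataFrame, treatment: str | None = None,
                          trial: str | None = None) -> list[Trajectory]:
    """Group a raw fix table into per-animal trajectories."""
    out = []
    for animal, grp in fixes.groupby("animal_id", sort=True):
        out.append(
            Trajectory(str(animal), grp.reset_index(drop=True), treatment=treatment, trial=trial)
        )
    return out


def grazing_intervals_from_truth(truth: SimTruth, min_fraction: float = 0.25) -> list[tuple]:
    """Hour intervals in which grazing was prevalent (the GH observation set)."""
    start = pd.Timestamp(truth.config.trial_start)
    frac = truth.grazing_fraction_by_hour()
    out = []
    for hour_index, f in frac.items():
        if f >= min_fraction:
            h0 = start + pd.Timedelta(hours=int(hour_index) - 1)
            out.append((h0, h0 + pd.Timedelta(hours=1)))
    return out


def scenario_library() -> dict[str, SimConfig]:
    """Named study conditions with known ground truth.

    - ``ip-like``: improved-pasture style — residency driven by pasture
      greenness (dominant NDVI weight), sparse scattered trees.
    - ``np-like``: native-pasture style — residency driven by elevation and
      tree shelter, trees clustered in the northern end.
    - ``null``: no drivers, no cohesion; an unbiased correlated random walk.
    - ``weather-driven``: shelter-seeking switches on when the chill index
      crosses the threshold, on top of a mild greenness preference.
    """
    base = SimConfig()
    return {
        "ip-like": replace(base, w_ndvi=2.0, w_el=0.1, w_nw=0.2, n_trees=25),
        "np-like": replace(base, w_el=1.8, w_nt=1.4, w_ndvi=0.2, trees_clustered_north=True),
        "null": replace(base, cohesion=0.0),
        "weather-driven": replace(
            base, w_ndvi=0.5, w_shelter=2.0, chill_threshold=850.0, trees_clustered_north=True
        ),
    }


def get_scenario(name: str, **overrides) -> SimConfig:
    lib = scenario_library()
    if name not in lib:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(lib)}")
    return replace(lib[name], **overrides) if overrides else lib[name]
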