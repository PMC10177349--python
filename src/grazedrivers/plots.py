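"""Figure helpers: residency maps, hourly activity curves, PDP panels."""

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .residency import ResidencyGrid


def plot_residency_map(residency: ResidencyGrid, level_key: str | None = None, ax=None):
    """Aggregate LRI heat map on the paddock grid (masked cells blank)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    agg = residency.aggregate(level_key=level_key)
    vals = np.where(residency.spec.mask, agg, np.nan)
    xmin, ymin, xmax, ymax = residency.spec.extent
    im = ax.imshow(vals, origin="lower", extent=(xmin, xmax, ymin, ymax), cmap="viridis")
    ax.set_xlabel("easting (m)")
    ax.set_ylabel("northing (m)")
    ax.set_title("livestock residency index")
    plt.colorbar(im, ax=ax, label="mean hourly LRI")
    return ax


def plot_hourly_speed(hourly, ax=None):
    """Mean speed by hour of recording (output of ``hourly_mean_speed``)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    ax.plot(hourly["hour_index"], hourly["mean_speed"], marker="o", ms=3)
    ax.axhline(0.15, ls="--", lw=0.8, color="grey")  # slow/fast cutoff
    ax.set_xlabel("hour of recording")
    ax.set_ylabel("mean speed (m/s)")
    return ax


def plot_pdp(curve, ax=None):
    """One partial-dependence curve (output of ``partial_dependence``)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    predictor = curve.columns[0]
    ax.plot(curve[predictor], curve["mean_prediction"])
    ax.set_xlabel(predictor)
    ax.set_ylabel("mean predicted LRI")
    return ax
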