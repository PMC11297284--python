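"""Growth-rate, lag-time and chronological-lifespan computations.

Rates are local specific growth rates: ``mu_log_i = (ln OD_{i+1} - ln OD_i)
/ (t_{i+1} - t_i)``, with the maximal rate taken inside a time window that
excludes lag and stationary phases (default 5-20 h).  Optionally the rates
are computed on a least-squares logistic fit of the curve rather than on
the raw ODs.  Lag time is the pseudo-lag: the earliest time, on a discrete
grid, at which the culture has achieved two doublings (a fourfold OD
increase over the starting OD).  Viability is the fraction of events below
a propidium-iodide threshold set from an all-live rich-media control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .flow import _require_channels
from .synthetic import GrowthCurve, logistic_od

log = logging.getLogger(__name__)

DEFAULT_WINDOW_H = (5.0, 20.0)
DEFAULT_GRID_H = 0.5
DEFAULT_CONTROL_QUANTILE = 0.995
PI_CHANNEL = "YL1-H"

__all__ = [
    "GrowthCurve", "GrowthFit", "LagResult", "ViabilityPoint", "ClsSummary",
    "local_growth_rates", "max_growth_rate", "lag_time",
    "viability_fraction", "cls_summary", "read_growth_csv",
]


def read_growth_csv(path) -> dict:
    """Read long-format growth curves (well, time_h, od600) into curves."""
    df = pd.read_csv(path)
    need = {"well", "time_h", "od600"}
    if not need.issubset(df.columns):
        raise ValueError(f"growth CSV needs columns {sorted(need)}")
    out = {}
    for well, grp in df.groupby("well"):
        grp = grp.sort_values("time_h")
        out[well] = GrowthCurve(time_h=grp["time_h"].to_numpy(),
                                od=grp["od600"].to_numpy(),
                                replicate=str(well))
    return out


# --------------------------------------------------------------------------
# local rates and maximal rate
# --------------------------------------------------------------------------

def _positive_od(curve: GrowthCurve):
    ok = curve.od > 0
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("dropping %d non-positive OD points", n_bad)
    t, od = curve.time_h[ok], curve.od[ok]
    if t.size < 2:
        raise ValueError("fewer than 2 positive OD points")
    return t, od


def local_growth_rates(curve: GrowthCurve):
    """Per-interval specific growth rates and interval midpoints."""
    t, od = _positive_od(curve)
    mu = np.diff(np.log(od)) / np.diff(t)
    mid = 0.5 * (t[:-1] + t[1:])
    return mu, mid


@dataclass
class GrowthFit:
    """Local rate series with the windowed maximal rate."""

    mu_log: np.ndarray
    mu_mid_h: np.ndarray
    mu_max: float
    window_h: tuple
    smoothed: tuple | None      # (od0, capacity, rate) of the logistic fit
    used_smoothed: bool


def _fit_logistic(t, od):
    """3-parameter logistic least squares; raises on non-convergence."""
    od0 = max(float(od[0]), 1e-9)
    cap = max(float(od.max()), od0 * 2)
    # crude rate guess from the steepest log-slope
    mu0 = max(float(np.nanmax(np.diff(np.log(np.maximum(od, 1e-12)))
                              / np.diff(t))), 0.05)

    def model(tt, o0, K, r):
        return logistic_od(tt, o0, 0.0, r, K)

    popt, _ = curve_fit(model, t, od, p0=[od0, cap, mu0],
                        bounds=([1e-12, 1e-9, 1e-6], [np.inf] * 3),
                        maxfev=10000)
    return tuple(float(v) for v in popt)


def max_growth_rate(curve: GrowthCurve, window_h=DEFAULT_WINDOW_H,
                    smooth: bool = True) -> GrowthFit:
    """Maximal local rate within a window excluding lag and stationary.

    With ``smooth`` a logistic is least-squares fitted first and the local
    rates are computed on the fitted curve at the original sampling times;
    if the fit fails the raw rates are used with a warning.  ``mu_max`` is
    the maximum of the rates whose interval midpoint lies in the window.
    """
    t, od = _positive_od(curve)
    lo, hi = window_h
    if hi <= lo:
        raise ValueError("window must satisfy t_start < t_end")
    if lo > t[-1] or hi < t[0]:
        raise ValueError("window does not intersect curve span")

    smoothed = None
    used = False
    od_eval = od
    if smooth:
        try:
            smoothed = _fit_logistic(t, od)
            od_eval = logistic_od(t, smoothed[0], 0.0, smoothed[2],
                                  smoothed[1])
            used = True
        except (RuntimeError, ValueError):
            log.warning("logistic fit failed; using raw mu_log")
    mu = np.diff(np.log(od_eval)) / np.diff(t)
    mid = 0.5 * (t[:-1] + t[1:])
    in_win = (mid >= lo) & (mid <= hi)
    if not in_win.any():
        raise ValueError("no rate interval midpoint inside the window")
    return GrowthFit(mu_log=mu, mu_mid_h=mid,
                     mu_max=float(mu[in_win].max()), window_h=(lo, hi),
                     smoothed=smoothed, used_smoothed=used)


# --------------------------------------------------------------------------
# lag time
# --------------------------------------------------------------------------

@dataclass
class LagResult:
    """Discretised pseudo-lag time (two doublings, fourfold OD)."""

    lag_h: float | None          # None when the threshold is never reached
    reached: bool
    threshold_od: float
    grid_h: float


def lag_time(curve: GrowthCurve, od0: float, grid_h: float = DEFAULT_GRID_H
             ) -> LagResult:
    """Earliest grid time with OD >= 4 * od0 (previous-sample hold)."""
    if od0 <= 0:
        raise ValueError("od0 must be positive")
    if grid_h <= 0:
        raise ValueError("grid_h must be positive")
    threshold = 4.0 * od0
    t, od = curve.time_h, curve.od
    grid = np.arange(0.0, t[-1] + 0.5 * grid_h, grid_h)
    grid = grid[grid >= t[0]]
    # previous-sample hold: value at grid time g is od at the last t <= g
    idx = np.searchsorted(t, grid, side="right") - 1
    held = od[idx]
    hit = np.flatnonzero(held >= threshold)
    if hit.size == 0:
        return LagResult(lag_h=None, reached=False, threshold_od=threshold,
                         grid_h=grid_h)
    return LagResult(lag_h=float(grid[hit[0]]), reached=True,
                     threshold_od=threshold, grid_h=grid_h)


# --------------------------------------------------------------------------
# viability and chronological lifespan
# --------------------------------------------------------------------------

@dataclass
class ViabilityPoint:
    day: float
    viable_fraction: float
    threshold: float
    n_events: int


def viability_fraction(pi_events: pd.DataFrame,
                       control_events: pd.DataFrame,
                       quantile: float = DEFAULT_CONTROL_QUANTILE,
                       channel: str = PI_CHANNEL,
                       day: float = 0.0) -> ViabilityPoint:
    """Fraction of events at or below the control-derived PI threshold.

    The threshold is the ``quantile`` (default 0.995) of the PI intensity
    of an all-live rich-media control measured alongside the samples.
    """
    _require_channels(pi_events, [channel])
    _require_channels(control_events, [channel])
    if len(control_events) < 100:
        raise ValueError("control needs at least 100 events")
    if not (0.0 < quantile <= 1.0):
        raise ValueError("quantile must be in (0, 1]")
    threshold = float(np.quantile(
        control_events[channel].to_numpy(dtype=float), quantile))
    pi = pi_events[channel].to_numpy(dtype=float)
    return ViabilityPoint(day=day,
                          viable_fraction=float(np.mean(pi <= threshold)),
                          threshold=threshold, n_events=int(pi.size))


@dataclass
class ClsSummary:
    """Chronological lifespan: fraction viable per day plus half-life."""

    table: pd.DataFrame          # day, viable_fraction
    half_life_day: float | None  # None = censored (never fell below 0.5)
    censored: bool


def cls_summary(course) -> ClsSummary:
    """Half-life by linear interpolation of the first crossing below 0.5."""
    days = np.array([p.day for p in course], dtype=float)
    fracs = np.array([p.viable_fraction for p in course], dtype=float)
    if days.size < 2:
        raise ValueError("need at least 2 timepoints")
    if np.unique(days).size != days.size:
        raise ValueError("duplicate days in viability course")
    order = np.argsort(days)
    days, fracs = days[order], fracs[order]
    table = pd.DataFrame({"day": days, "viable_fraction": fracs})

    below = np.flatnonzero(fracs < 0.5)
    if below.size == 0:
        return ClsSummary(table=table, half_life_day=None, censored=True)
    i = below[0]
    if i == 0:
        return ClsSummary(table=table, half_life_day=float(days[0]),
                          censored=False)
    f0, f1 = fracs[i - 1], fracs[i]
    d0, d1 = days[i - 1], days[i]
    half = d0 + (f0 - 0.5) * (d1 - d0) / (f0 - f1)
    return ClsSummary(table=table, half_life_day=float(half), censored=False)
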