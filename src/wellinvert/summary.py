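"""Well-group summary curves, steady-state extraction and model comparison.

Replicate wells are summarized by mean / sd / sem curves on a common time
grid.  Steady-state growth rates and reporter concentrations are extracted
over a window of background-corrected absorbance (0.01-0.1 by convention,
where cultures grow exponentially at their maximal rate), with growth rates
converted to doublings per hour (mu * 60 / ln 2).  A model-predicted
concentration-vs-growth-rate curve can be scored against observed points by
a coefficient of determination R^2 = 1 - RSS/TSS (negative when the model
does worse than predicting the observed mean).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .estimators import EstimationResult
from .plate import WellSeries

__all__ = [
    "SummaryCurve",
    "SteadyStatePoint",
    "group_statistics",
    "steady_state_summary",
    "model_comparison_r2",
    "doublings_per_hour",
]

LN2 = float(np.log(2.0))


def doublings_per_hour(mu_per_min: float | np.ndarray):
    """Convert a growth rate in 1/min to doublings per hour (mu * 60 / ln 2)."""
    return np.asarray(mu_per_min, dtype=float) * 60.0 / LN2


@dataclass
class SummaryCurve:
    """Mean and dispersion of several wells' curves on a common grid."""

    grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    sem: np.ndarray
    n: np.ndarray


def group_statistics(
    results: dict[str, EstimationResult],
    members: Sequence[str],
    grid_points: int | None = None,
) -> SummaryCurve:
    """Summarize one quantity over a well group.

    Each member's curve is linearly interpolated onto a common grid — the
    union of member grid points clipped to the intersection of their valid
    time ranges (or ``grid_points`` uniform points over that intersection).
    Standard deviation is the n-1 sample deviation; sem = sd / sqrt(n).
    """
    curves = []
    for label in members:
        if label in results:
            r = results[label]
            t, v = r.valid_points()
            if t.size >= 1:
                curves.append((t, v))
    if not curves:
        raise ValueError("no member has a computed result")
    lo = max(t[0] for t, _ in curves)
    hi = min(t[-1] for t, _ in curves)
    if hi <= lo:
        raise ValueError("member time ranges do not intersect")
    if grid_points is not None:
        grid = np.linspace(lo, hi, int(grid_points))
    else:
        grid = np.unique(np.concatenate([t for t, _ in curves]))
        grid = grid[(grid >= lo) & (grid <= hi)]
    values = np.vstack([np.interp(grid, t, v) for t, v in curves])
    n_wells = values.shape[0]
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1) if n_wells > 1 else np.zeros_like(mean)
    n = np.full(grid.size, n_wells)
    sem = sd / np.sqrt(n)
    return SummaryCurve(grid=grid, mean=mean, sd=sd, sem=sem, n=n)


@dataclass
class SteadyStatePoint:
    """Steady-state summary of one growth condition.

    Growth rate in doublings per hour; reporter concentration normalized so
    the reference condition equals 1.
    """

    condition: str
    mu_mean: float
    mu_sd: float
    conc_mean: float
    conc_sd: float


def steady_state_summary(
    growth: EstimationResult,
    concentration: EstimationResult,
    abs_series: WellSeries,
    od_window: tuple[float, float] = (0.01, 0.1),
    condition: str = "",
    reference_conc: float | None = None,
) -> SteadyStatePoint:
    """Mean/sd of growth rate and concentration over the steady-state window.

    Timepoints are those where the (background-corrected, non-outlier)
    absorbance lies inside ``od_window``; the growth-rate and concentration
    curves are interpolated at them.  Growth rates are returned in
    doublings per hour.  If ``reference_conc`` is given (the reference
    condition's own mean concentration), concentrations are normalized by
    it, so the reference condition maps to exactly 1.
    """
    low, high = od_window
    if not low < high:
        raise ValueError("od_window must satisfy low < high")
    t, v = abs_series.inlier_points()
    sel = (v >= low) & (v <= high)
    if not sel.any():
        raise ValueError(f"no timepoints with corrected absorbance in [{low}, {high}]")
    t_sel = t[sel]
    mu = growth.interpolate(t_sel)
    conc = concentration.interpolate(t_sel)
    mu_dh = doublings_per_hour(mu)
    conc_mean = float(conc.mean())
    conc_sd = float(conc.std(ddof=1)) if conc.size > 1 else 0.0
    if reference_conc is not None:
        if reference_conc == 0:
            raise ValueError("reference concentration must be nonzero")
        conc_mean /= reference_conc
        conc_sd /= abs(reference_conc)
    return SteadyStatePoint(
        condition=condition,
        mu_mean=float(mu_dh.mean()),
        mu_sd=float(mu_dh.std(ddof=1)) if mu_dh.size > 1 else 0.0,
        conc_mean=conc_mean,
        conc_sd=conc_sd,
    )


def _interp_extrap(x, xp, fp):
    """Piecewise-linear interpolation with linear extrapolation at the ends."""
    x = np.asarray(x, dtype=float)
    out = np.interp(x, xp, fp)
    if xp.size >= 2:
        slope_lo = (fp[1] - fp[0]) / (xp[1] - xp[0])
        slope_hi = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        out = np.where(x < xp[0], fp[0] + slope_lo * (x - xp[0]), out)
        out = np.where(x > xp[-1], fp[-1] + slope_hi * (x - xp[-1]), out)
    return out


def model_comparison_r2(
    observed: Sequence[tuple[float, float]],
    predicted: Sequence[tuple[float, float]],
) -> float:
    """R^2 of a predicted concentration-vs-growth-rate curve.

    The predicted curve is interpolated (linearly, with linear extrapolation
    beyond its ends) at each observed growth rate; R^2 = 1 - RSS/TSS with
    TSS about the observed mean.  May be negative.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape[0] < 2 or pred.shape[0] < 2:
        raise ValueError("need >= 2 observed and >= 2 predicted points")
    order = np.argsort(pred[:, 0])
    xp, fp = pred[order, 0], pred[order, 1]
    yhat = _interp_extrap(obs[:, 0], xp, fp)
    y = obs[:, 1]
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("zero total sum of squares: all observations equal")
    rss = float(np.sum((y - yhat) ** 2))
    return 1.0 - rss / tss
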