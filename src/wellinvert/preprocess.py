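"""Outlier filtering and background correction for plate time series.

Outliers in plate-reader curves come mostly from the glass beads used for
aeration deflecting the light beam; they appear as isolated spikes.  The
automatic filter smooths the curve with a Savitzky-Golay local-polynomial
fit and iteratively flags points whose residual exceeds a multiple of the
residual standard deviation.  A band filter flags everything outside a
tolerance band around a user-sketched piecewise-linear trend.

Background correction offers three procedures: subtracting a fixed
baseline, subtracting the signal of a reporter-free background well, or —
when the background strain grows differently — subtracting autofluorescence
read off a calibration curve mapping absorbance to the autofluorescence of
the reporter-free strain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import UnivariateSpline
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator

from .plate import WellSeries

__all__ = [
    "OutlierFilterParams",
    "SavitzkyGolayOutlierFilter",
    "sg_smooth",
    "detect_outliers_auto",
    "detect_outliers_band",
    "CalibrationCurve",
    "build_calibration_curve",
    "BackgroundSpec",
    "apply_background_correction",
]


@dataclass
class OutlierFilterParams:
    """Parameters of the automatic iterative Savitzky-Golay filter."""

    window: int = 15
    polyorder: int = 3
    cutoff_sigma: float = 3.0
    iterations: int = 3
    #: Relative residual floor: residuals below this fraction of the series'
    #: largest magnitude are never flagged.  Keeps the systematic (noise-free)
    #: bias of the local-polynomial smooth from being mistaken for outliers.
    min_residual_fraction: float = 1e-5

    def validate(self) -> None:
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ValueError(
                f"window must be odd and > polyorder, got window={self.window}, "
                f"polyorder={self.polyorder}"
            )
        if self.polyorder < 1:
            raise ValueError("polyorder must be >= 1")
        if self.cutoff_sigma <= 0 or self.iterations < 1:
            raise ValueError("cutoff_sigma must be > 0 and iterations >= 1")


def _sg_on_points(times, values, window, polyorder, eval_times):
    """Savitzky-Golay smooth of (times, values), evaluated at eval_times.

    The filter is applied in index space; plate readers sample nearly
    uniformly so the local polynomial fit in index space is a close
    approximation of the fit in time.  Masked points are absent from
    (times, values) and get interpolated from the smooth.
    """
    smooth = savgol_filter(values, window_length=window, polyorder=polyorder)
    return np.interp(eval_times, times, smooth)


def sg_smooth(series: WellSeries, window: int = 15, polyorder: int = 3) -> np.ndarray:
    """Least-squares local-polynomial smooth at the series' own timestamps.

    Outlier-masked points are excluded from the fit; their smoothed value is
    interpolated from the smooth of the inliers.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValueError(
            f"window must be odd and > polyorder (window={window}, polyorder={polyorder})"
        )
    t_in, v_in = series.inlier_points(corrected=False)
    if t_in.size < window:
        raise ValueError(
            f"need at least window={window} non-outlier points, have {t_in.size}"
        )
    return _sg_on_points(t_in, v_in, window, polyorder, series.times)


def detect_outliers_auto(
    series: WellSeries, params: OutlierFilterParams | None = None
) -> np.ndarray:
    """Iterative Savitzky-Golay outlier detection.

    Each round smooths the current inliers, computes their residuals and
    the residual standard deviation sigma, and flags points with
    ``|residual| > cutoff_sigma * sigma``.  Sigma is recomputed from the
    current inliers only, so already-flagged spikes no longer inflate it.
    The mask is monotone: points are never unflagged.  Stops after
    ``iterations`` rounds or as soon as a round adds no new flags.

    Returns the full outlier mask (including any pre-existing flags).
    """
    params = params or OutlierFilterParams()
    params.validate()
    mask = series.outlier_mask.copy()
    values = series.values
    floor = params.min_residual_fraction * np.max(np.abs(values), initial=0.0)
    for _ in range(params.iterations):
        keep = ~mask
        if keep.sum() < params.window:
            raise ValueError(
                f"fewer inliers ({int(keep.sum())}) than window ({params.window})"
            )
        smooth_in = savgol_filter(
            values[keep], window_length=params.window, polyorder=params.polyorder
        )
        resid = values[keep] - smooth_in
        sigma = resid.std()
        new = np.zeros_like(mask)
        new[keep] = np.abs(resid) > np.maximum(params.cutoff_sigma * sigma, floor)
        if not new.any():
            break
        mask |= new
    return mask


class SavitzkyGolayOutlierFilter(BaseEstimator):
    """Iterative Savitzky-Golay spike detector, scikit-learn style.

    Parameters
    ----------
    window : int, default 15
        Odd smoothing-window length in points.
    polyorder : int, default 3
        Local polynomial order; must be < window.
    cutoff_sigma : float, default 3.0
        Flag points whose residual exceeds this multiple of the residual
        standard deviation.
    iterations : int, default 3
        Maximum number of smoothing/flagging rounds.

    Attributes
    ----------
    outlier_mask_ : ndarray of bool
        True where a point was flagged.
    smoothed_ : ndarray
        Final Savitzky-Golay smooth evaluated at every input time.
    """

    def __init__(self, window=15, polyorder=3, cutoff_sigma=3.0, iterations=3):
        self.window = window
        self.polyorder = polyorder
        self.cutoff_sigma = cutoff_sigma
        self.iterations = iterations

    def _params(self) -> OutlierFilterParams:
        return OutlierFilterParams(
            window=self.window,
            polyorder=self.polyorder,
            cutoff_sigma=self.cutoff_sigma,
            iterations=self.iterations,
        )

    def fit(self, X, y):
        """Fit on times X (shape (n,) or (n, 1)) and readings y."""
        t = np.asarray(X, dtype=float).reshape(-1)
        v = np.asarray(y, dtype=float).reshape(-1)
        series = WellSeries("A1", "absorbance", t, v)
        self.outlier_mask_ = detect_outliers_auto(series, self._params())
        masked = series.replace(outlier_mask=self.outlier_mask_)
        self.smoothed_ = sg_smooth(masked, self.window, self.polyorder)
        return self

    def predict(self, X=None):
        """Return the boolean outlier mask of the fitted series."""
        return self.outlier_mask_

    def fit_predict(self, X, y):
        return self.fit(X, y).predict()


def detect_outliers_band(
    series: WellSeries,
    trend: Sequence[tuple[float, float]],
    tolerance: float,
) -> np.ndarray:
    """Band filter: flag points outside ``trend(t) +/- tolerance``.

    ``trend`` is a list of (time, value) anchors defining a piecewise-linear
    trend line; outside the anchor range the nearest anchor's value is used.
    The band boundary is inclusive: a residual exactly equal to the
    tolerance is kept.
    """
    if len(trend) < 2:
        raise ValueError("need at least 2 trend anchors")
    anchor_t = np.array([p[0] for p in trend], dtype=float)
    anchor_v = np.array([p[1] for p in trend], dtype=float)
    if not np.all(np.diff(anchor_t) > 0):
        raise ValueError("trend anchor times must be strictly increasing")
    trend_at = np.interp(series.times, anchor_t, anchor_v)
    return np.abs(series.values - trend_at) > tolerance


# ---------------------------------------------------------------------------
# Background correction
# ---------------------------------------------------------------------------


@dataclass
class CalibrationCurve:
    """Smooth map from absorbance to background-strain autofluorescence.

    Inside the observed absorbance range ``support`` the smoothing spline is
    evaluated directly.  Inside ``extrapolation_interval`` (when set) the
    curve continues linearly from the nearest support boundary with the
    boundary slope, so the curve is continuous across the boundary.  Outside
    both, the boundary value is held constant.
    """

    support: tuple[float, float]
    spline: UnivariateSpline
    smoothing: float
    extrapolation_interval: tuple[float, float] | None = None

    def __call__(self, absorbance) -> np.ndarray:
        a = np.asarray(absorbance, dtype=float)
        lo, hi = self.support
        out = self.spline(np.clip(a, lo, hi))
        slope_lo = float(self.spline.derivative()(lo))
        slope_hi = float(self.spline.derivative()(hi))
        val_lo = float(self.spline(lo))
        val_hi = float(self.spline(hi))
        if self.extrapolation_interval is not None:
            elo, ehi = self.extrapolation_interval
            below = (a < lo) & (a >= elo)
            above = (a > hi) & (a <= ehi)
            out = np.where(below, val_lo + slope_lo * (a - lo), out)
            out = np.where(above, val_hi + slope_hi * (a - hi), out)
        return out if out.shape else float(out)


def build_calibration_curve(
    bg_absorbance: WellSeries,
    bg_fluorescence: WellSeries,
    smoothing: float = 1e-3,
    extrapolation_interval: tuple[float, float] | None = None,
) -> CalibrationCurve:
    """Fit a smoothing spline mapping absorbance to autofluorescence.

    Pairs (absorbance_i, fluorescence_i) are formed at timestamps where both
    background-well series have non-outlier points, sorted by absorbance;
    exact duplicates in the abscissa are averaged.  The smoothing parameter
    is a residual sum-of-squares budget per point, normalized by the
    variance of the fluorescence values (so ``smoothing=0`` interpolates and
    ``smoothing=1`` would admit residuals as large as the signal's own
    spread).
    """
    ta, va = bg_absorbance.inlier_points()
    tf, vf = bg_fluorescence.inlier_points()
    shared, ia, if_ = np.intersect1d(ta, tf, return_indices=True)
    if shared.size < 5:
        raise ValueError(
            f"need >= 5 shared non-outlier timestamps, found {shared.size}"
        )
    a, f = va[ia], vf[if_]
    order = np.argsort(a, kind="stable")
    a, f = a[order], f[order]
    # average exact duplicates in the abscissa (spline abscissa must increase)
    uniq, inverse, counts = np.unique(a, return_inverse=True, return_counts=True)
    fsum = np.zeros_like(uniq)
    np.add.at(fsum, inverse, f)
    a, f = uniq, fsum / counts
    if a.size < 5:
        raise ValueError("fewer than 5 distinct absorbance values")
    s = smoothing * a.size * float(np.var(f))
    k = min(3, a.size - 1)
    spline = UnivariateSpline(a, f, k=k, s=s)
    return CalibrationCurve(
        support=(float(a[0]), float(a[-1])),
        spline=spline,
        smoothing=smoothing,
        extrapolation_interval=extrapolation_interval,
    )


@dataclass
class BackgroundSpec:
    """Which background-correction procedure to apply, and its data.

    Exactly the fields of the chosen method must be set: ``baseline`` for
    ``fixed``, ``background_series`` for ``background_well``, ``curve`` for
    ``calibration``.
    """

    method: str
    baseline: float | None = None
    background_series: WellSeries | None = None
    curve: CalibrationCurve | None = None

    def validate(self) -> None:
        required = {"fixed": "baseline", "background_well": "background_series",
                    "calibration": "curve"}
        if self.method not in required:
            raise ValueError(f"unknown background method {self.method!r}")
        fields = {"baseline": self.baseline,
                  "background_series": self.background_series,
                  "curve": self.curve}
        for name, val in fields.items():
            if name == required[self.method]:
                if val is None:
                    raise ValueError(f"method {self.method!r} requires {name}")
            elif val is not None:
                raise ValueError(
                    f"method {self.method!r} must not set {name}"
                )


def apply_background_correction(
    series: WellSeries,
    spec: BackgroundSpec,
    paired_absorbance: WellSeries | None = None,
) -> WellSeries:
    """Return a copy of ``series`` with ``corrected_values`` filled in.

    fixed
        corrected = value - baseline, at every point.
    background_well
        corrected = value - background value linearly interpolated at the
        same time; the background well's non-outlier points must cover the
        series' time range.
    calibration
        corrected = value - curve(paired corrected absorbance at the same
        time); requires ``paired_absorbance`` (the reporter strain's own
        absorbance series, already background-corrected) with an exact
        timestamp match at every non-outlier point.

    Raw values are left untouched; negative corrected values are retained.
    """
    spec.validate()
    if spec.method == "fixed":
        corrected = series.values - spec.baseline
    elif spec.method == "background_well":
        bt, bv = spec.background_series.inlier_points()
        keep_t = series.times[series.inlier]
        if keep_t.size and (keep_t[0] < bt[0] - 1e-9 or keep_t[-1] > bt[-1] + 1e-9):
            raise ValueError(
                "background series does not cover the series' time range "
                f"([{bt[0]}, {bt[-1]}] vs [{keep_t[0]}, {keep_t[-1]}])"
            )
        corrected = series.values - np.interp(series.times, bt, bv)
    else:  # calibration
        if paired_absorbance is None:
            raise ValueError("calibration correction requires paired_absorbance")
        pa_t = paired_absorbance.times
        pa_v = paired_absorbance.active_values()
        lookup = {float(t): float(v) for t, v in zip(pa_t, pa_v)}
        corrected = series.values.astype(float).copy()
        for i, t in enumerate(series.times):
            if series.outlier_mask[i]:
                continue
            if float(t) not in lookup:
                raise ValueError(
                    f"no paired absorbance at t={t} for calibration correction"
                )
            corrected[i] = series.values[i] - spec.curve(lookup[float(t)])
    return series.replace(corrected_values=corrected)
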