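"""Growth-rate, promoter-activity and protein-concentration estimators.

The three inversion-based estimators are scikit-learn style: construct with
hyperparameters, ``fit(times, values)``, read fitted attributes with a
trailing underscore, ``predict(times)`` returns the model output (the
regularized fit to the measured channel).  Thin module-level functions wrap
them for use with :class:`~wellinvert.plate.WellSeries` objects.

Scales: absorbance is only proportional to the population volume and
fluorescence to the reporter amount (instrument constants alpha, beta are
unknown), so the promoter activity and the concentrations are estimated up
to a fixed multiplicative constant.  The growth rate is an absolute
quantity (per minute) because it is the logarithmic derivative of the
volume, on which the unknown scale cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .inversion import (
    ControlGrid,
    LinearSystem,
    PiecewiseLinear,
    RegularizedSolution,
    _observation_row,
    build_input_system,
    default_lambda_grid,
    gcv_select,
    solve_tikhonov,
)
from .plate import WellSeries

__all__ = [
    "DEFAULT_GAMMA_R",
    "DEFAULT_MIN_ABSORBANCE",
    "EstimationResult",
    "GrowthRateEstimator",
    "PromoterActivityEstimator",
    "ProteinConcentrationEstimator",
    "estimate_growth_rate",
    "estimate_promoter_activity",
    "estimate_protein_concentration",
    "reporter_concentration",
]

#: GFP reporter degradation constant, per minute (half-life ~18 h).
DEFAULT_GAMMA_R = 0.00065

#: Absorbance reliability floor; defaults to the plate's medium background.
DEFAULT_MIN_ABSORBANCE = 0.084


@dataclass
class EstimationResult:
    """An estimated quantity on its grid, with diagnostics.

    ``values[i]`` is meaningful where ``validity_mask[i]`` is True; invalid
    entries are NaN.  ``lam`` is the regularization weight actually used
    (None for the ratio-based reporter concentration, which involves no
    inversion).  For growth-rate results ``denoised_volume`` is the fitted
    population-volume curve alpha*V-hat, reusable as the forcing of the
    expression-kernel estimators.
    """

    quantity: str
    times: np.ndarray
    values: np.ndarray
    validity_mask: np.ndarray
    lam: float | None = None
    well_label: str = ""
    denoised_volume: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.validity_mask = np.asarray(self.validity_mask, dtype=bool)
        if not (self.times.size == self.values.size == self.validity_mask.size):
            raise ValueError("times, values, validity_mask must share length")
        if np.any(~np.isfinite(self.values[self.validity_mask])):
            raise ValueError("non-finite values marked valid")

    def valid_points(self) -> tuple[np.ndarray, np.ndarray]:
        return self.times[self.validity_mask], self.values[self.validity_mask]

    def interpolate(self, at_times: np.ndarray) -> np.ndarray:
        """Linear interpolation of the valid part of the curve."""
        t, v = self.valid_points()
        if t.size == 0:
            raise ValueError("no valid points to interpolate")
        return np.interp(np.asarray(at_times, dtype=float), t, v)


def _as_times(X) -> np.ndarray:
    t = np.asarray(X, dtype=float)
    if t.ndim == 2 and t.shape[1] == 1:
        t = t[:, 0]
    if t.ndim != 1:
        raise ValueError("times must be 1-D or a single-column 2-D array")
    return t


def _cap_control_points(requested: int, n: int) -> int:
    """Cap m so the system stays overdetermined: m + 1 <= n / 2."""
    m = min(int(requested), n // 2 - 1)
    if m < 2:
        raise ValueError(
            f"too few usable points ({n}) for an inversion with >= 2 control intervals"
        )
    return m


class _InversionEstimator(BaseEstimator, RegressorMixin):
    """Shared fit machinery: build system, pick lambda, solve."""

    def _solve(self, system: LinearSystem):
        reg = self.regularization
        if isinstance(reg, str):
            if reg != "gcv":
                raise ValueError(f"regularization must be 'gcv' or a number, got {reg!r}")
            grid = (
                default_lambda_grid()
                if self.lambda_grid is None
                else np.asarray(self.lambda_grid, dtype=float)
            )
            lam, curve = gcv_select(system, lambda_grid=grid)
            self.gcv_lambdas_, self.gcv_scores_ = grid, curve
        else:
            lam = float(reg)
            self.gcv_lambdas_ = self.gcv_scores_ = None
        positive = getattr(self, "positive", False)
        if positive == "clip":
            sol = solve_tikhonov(system, lam, nonneg=False)
            sol.u = np.maximum(sol.u, 0.0)
            sol.fitted = system.A @ sol.x
        else:
            sol = solve_tikhonov(system, lam, nonneg=bool(positive))
        return lam, sol


class GrowthRateEstimator(_InversionEstimator):
    """Time-varying growth rate mu(t) from an absorbance curve.

    The background-corrected absorbance y(t) is modeled as the output of
    ``d/dt (alpha V) = mu(t) * Vbar(t)`` with Vbar the piecewise-linear
    interpolant of the measurements; mu is piecewise-constant on
    ``n_control_points`` uniform intervals and obtained by Tikhonov-
    regularized least squares with a first-difference penalty.

    Parameters
    ----------
    n_control_points : int, default 50
        Requested number of control intervals; capped so the system stays
        overdetermined (m + 1 <= n/2).
    regularization : 'gcv' or float, default 'gcv'
        Fixed regularization weight, or GCV selection over ``lambda_grid``.
    positive : bool or 'clip', default False
        Constrain mu >= 0 (bounded least squares), or clip the
        unconstrained solution as a fast approximation.
    min_absorbance : float, default 0.084
        Reliability floor; points with corrected absorbance below it are
        excluded from the fit.

    Attributes
    ----------
    growth_rate_ : ndarray, shape (m,)
        Estimated mu per control interval [1/min].
    control_times_ : ndarray
        Interval midpoints.
    lambda_ : float
        Regularization weight used.
    volume_ : callable
        Denoised population volume alpha*V-hat(t) (the fitted accumulated
        output), a by-product reusable as forcing for expression kernels.
    """

    def __init__(
        self,
        n_control_points: int = 50,
        regularization="gcv",
        positive=False,
        min_absorbance: float = DEFAULT_MIN_ABSORBANCE,
        lambda_grid=None,
    ):
        self.n_control_points = n_control_points
        self.regularization = regularization
        self.positive = positive
        self.min_absorbance = min_absorbance
        self.lambda_grid = lambda_grid

    def fit(self, X, y):
        t = _as_times(X)
        v = np.asarray(y, dtype=float).reshape(-1)
        usable = np.isfinite(v) & (v >= self.min_absorbance)
        t_u, v_u = t[usable], v[usable]
        m = _cap_control_points(self.n_control_points, t_u.size)
        if t_u.size < m + 1:
            raise ValueError(f"fewer than m+1={m + 1} usable points ({t_u.size})")
        grid = ControlGrid.uniform(t_u[0], t_u[-1], m)
        forcing = PiecewiseLinear(t_u, v_u)
        system = build_input_system({"type": "growth", "volume": forcing}, t_u, v_u, grid)
        lam, sol = self._solve(system)
        self.system_, self.solution_ = system, sol
        self.lambda_ = lam
        self.growth_rate_ = sol.u
        self.c0_ = sol.c0
        self.edof_ = sol.edof
        self.control_times_ = grid.midpoints
        self.control_edges_ = grid.edges
        self.validity_mask_ = forcing(grid.midpoints) >= self.min_absorbance
        self.n_points_used_ = t_u.size
        t0 = t_u[0]
        x = sol.x

        def volume(at):
            at = np.atleast_1d(np.asarray(at, dtype=float))
            out = np.array(
                [
                    x[-1]
                    if s <= t0
                    else _observation_row(min(s, t_u[-1]), t0, grid, forcing, 0.0) @ x
                    for s in at
                ]
            )
            return out

        volume.support = (float(t_u[0]), float(t_u[-1]))
        self.volume_ = volume
        return self

    def predict(self, X):
        """Absorbance predicted by the model (denoised volume) at times X."""
        return self.volume_(_as_times(X))

    def result(self, well_label: str = "") -> EstimationResult:
        vals = np.where(self.validity_mask_, self.growth_rate_, np.nan)
        return EstimationResult(
            quantity="growth_rate",
            times=self.control_times_,
            values=vals,
            validity_mask=self.validity_mask_,
            lam=self.lambda_,
            well_label=well_label,
            denoised_volume=self.volume_,
        )


def _as_forcing(volume, times: np.ndarray) -> tuple[PiecewiseLinear, tuple | None]:
    """Normalize the accepted volume representations to knots + support.

    The support is the time window on which the volume is backed by data
    (e.g. the usable-point range of a growth-rate fit); None means
    unrestricted.
    """
    if isinstance(volume, PiecewiseLinear):
        return volume, (float(volume.t[0]), float(volume.t[-1]))
    if isinstance(volume, GrowthRateEstimator):
        volume = volume.volume_
    if isinstance(volume, EstimationResult):
        if volume.denoised_volume is None:
            raise ValueError("EstimationResult carries no denoised volume")
        volume = volume.denoised_volume
    if callable(volume):
        support = getattr(volume, "support", None)
        return PiecewiseLinear(times, np.asarray(volume(times), dtype=float)), support
    t, v = volume  # (times, values) pair
    t = np.asarray(t, float)
    return PiecewiseLinear(t, np.asarray(v, float)), (float(t[0]), float(t[-1]))


class PromoterActivityEstimator(_InversionEstimator):
    """Promoter activity a(t) (up to a constant) from corrected fluorescence.

    Models the reporter amount as ``dR/dt = u(t) * W(t) - gamma_r R`` with
    W the denoised population volume from a growth-rate fit; the estimated
    piecewise-constant input u is proportional to the promoter activity
    (scale beta/alpha unidentifiable).

    ``fit(X, y, volume=...)`` accepts the volume as a fitted
    GrowthRateEstimator, its result, a callable, or a (times, values) pair.
    """

    def __init__(
        self,
        gamma_r: float = DEFAULT_GAMMA_R,
        n_control_points: int = 50,
        regularization="gcv",
        positive=False,
        lambda_grid=None,
    ):
        self.gamma_r = gamma_r
        self.n_control_points = n_control_points
        self.regularization = regularization
        self.positive = positive
        self.lambda_grid = lambda_grid

    def _fit_shared_input(self, X, y, volume):
        if self.gamma_r < 0:
            raise ValueError("gamma_r must be >= 0")
        t = _as_times(X)
        v = np.asarray(y, dtype=float).reshape(-1)
        forcing, support = _as_forcing(volume, t)
        w = forcing(t)
        ok = np.isfinite(v) & (w > 0)
        if support is not None:
            # only fit where the volume is backed by data
            ok &= (t >= support[0]) & (t <= support[1])
        if not ok.any():
            raise ValueError(
                "population volume non-positive or unsupported over the whole range"
            )
        t_u, v_u = t[ok], v[ok]
        m = _cap_control_points(self.n_control_points, t_u.size)
        grid = ControlGrid.uniform(t_u[0], t_u[-1], m)
        system = build_input_system(
            {"type": "expression", "gamma": self.gamma_r, "volume": forcing},
            t_u, v_u, grid,
        )
        lam, sol = self._solve(system)
        self.system_, self.solution_ = system, sol
        self.lambda_ = lam
        self.c0_ = sol.c0
        self.edof_ = sol.edof
        self.control_times_ = grid.midpoints
        self.control_edges_ = grid.edges
        self.forcing_ = forcing
        self.validity_mask_ = forcing(grid.midpoints) > 0
        self._t0 = t_u[0]
        self._t_last = t_u[-1]
        return self

    def fit(self, X, y, volume=None):
        if volume is None:
            raise ValueError("fit requires volume= (the denoised population volume)")
        self._fit_shared_input(X, y, volume)
        self.activity_ = self.solution_.u
        return self

    def predict(self, X):
        """Fluorescence predicted by the model at times X."""
        t = _as_times(X)
        x = self.solution_.x
        grid = ControlGrid(self.control_edges_)
        return np.array(
            [
                _observation_row(min(s, self._t_last), self._t0, grid, self.forcing_, self.gamma_r) @ x
                if s > self._t0
                else x[-1]
                for s in t
            ]
        )

    def result(self, well_label: str = "") -> EstimationResult:
        vals = np.where(self.validity_mask_, self.activity_, np.nan)
        return EstimationResult(
            quantity="promoter_activity",
            times=self.control_times_,
            values=vals,
            validity_mask=self.validity_mask_,
            lam=self.lambda_,
            well_label=well_label,
        )


class ProteinConcentrationEstimator(PromoterActivityEstimator):
    """Host-protein concentration from reporter fluorescence.

    Assumes the host gene shares the reporter's promoter activity but may
    have a different degradation constant gamma_p.  The shared input u and
    the reporter initial condition are estimated from the fluorescence
    (exactly as for promoter activity, with gamma_r), then propagated
    through the host equation ``dP/dt = u W - gamma_p P`` with
    ``P(t0) = c0``; the reported concentration is P(t)/W(t) on the control
    grid, proportional to the true concentration.  With
    ``gamma_p == gamma_r`` this reduces to a smoothed version of the
    ratio-based reporter concentration.
    """

    def __init__(
        self,
        gamma_r: float = DEFAULT_GAMMA_R,
        gamma_p: float = DEFAULT_GAMMA_R,
        n_control_points: int = 50,
        regularization="gcv",
        positive=False,
        lambda_grid=None,
    ):
        super().__init__(
            gamma_r=gamma_r,
            n_control_points=n_control_points,
            regularization=regularization,
            positive=positive,
            lambda_grid=lambda_grid,
        )
        self.gamma_p = gamma_p

    def fit(self, X, y, volume=None):
        if self.gamma_p <= 0:
            raise ValueError("gamma_p must be > 0")
        if volume is None:
            raise ValueError("fit requires volume= (the denoised population volume)")
        self._fit_shared_input(X, y, volume)
        self.activity_ = self.solution_.u
        x = self.solution_.x
        grid = ControlGrid(self.control_edges_)
        tmid = grid.midpoints
        # host-protein amount: same input, degradation gamma_p, P(t0) = c0
        amount = np.array(
            [
                _observation_row(s, self._t0, grid, self.forcing_, self.gamma_p) @ x
                for s in tmid
            ]
        )
        w = self.forcing_(tmid)
        self.validity_mask_ = w > 0
        conc = np.full_like(amount, np.nan)
        conc[self.validity_mask_] = amount[self.validity_mask_] / w[self.validity_mask_]
        self.protein_amount_ = amount
        self.concentration_ = conc
        return self

    def result(self, well_label: str = "") -> EstimationResult:
        return EstimationResult(
            quantity="protein_concentration",
            times=self.control_times_,
            values=self.concentration_,
            validity_mask=self.validity_mask_,
            lam=self.lambda_,
            well_label=well_label,
        )


# ---------------------------------------------------------------------------
# WellSeries-level wrappers
# ---------------------------------------------------------------------------


def estimate_growth_rate(
    abs_series: WellSeries,
    n_control_points: int = 50,
    regularization="gcv",
    positive=False,
    min_absorbance: float = DEFAULT_MIN_ABSORBANCE,
    lambda_grid=None,
) -> EstimationResult:
    """Growth rate [1/min] from a background-corrected absorbance series."""
    t, v = abs_series.inlier_points()
    est = GrowthRateEstimator(
        n_control_points=n_control_points,
        regularization=regularization,
        positive=positive,
        min_absorbance=min_absorbance,
        lambda_grid=lambda_grid,
    ).fit(t, v)
    return est.result(well_label=abs_series.well_label)


def estimate_promoter_activity(
    fluo_series: WellSeries,
    volume,
    gamma_r: float = DEFAULT_GAMMA_R,
    **opts,
) -> EstimationResult:
    """Promoter activity (arbitrary units / min) from corrected fluorescence."""
    t, v = fluo_series.inlier_points()
    est = PromoterActivityEstimator(gamma_r=gamma_r, **opts).fit(t, v, volume=volume)
    return est.result(well_label=fluo_series.well_label)


def estimate_protein_concentration(
    fluo_series: WellSeries,
    volume,
    gamma_r: float = DEFAULT_GAMMA_R,
    gamma_p: float = DEFAULT_GAMMA_R,
    **opts,
) -> EstimationResult:
    """Host-protein concentration (arbitrary units) from corrected fluorescence."""
    t, v = fluo_series.inlier_points()
    est = ProteinConcentrationEstimator(
        gamma_r=gamma_r, gamma_p=gamma_p, **opts
    ).fit(t, v, volume=volume)
    return est.result(well_label=fluo_series.well_label)


def reporter_concentration(
    fluo_series: WellSeries,
    abs_series: WellSeries,
    min_absorbance: float = DEFAULT_MIN_ABSORBANCE,
) -> EstimationResult:
    """Ratio-based reporter concentration: corrected fluorescence / absorbance.

    Computed pointwise at timestamps shared by both series' non-outlier
    points; masked (no division performed) where the corrected absorbance is
    below ``min_absorbance``.
    """
    if min_absorbance <= 0:
        raise ValueError("min_absorbance must be > 0")
    tf, vf = fluo_series.inlier_points()
    ta, va = abs_series.inlier_points()
    shared, if_, ia = np.intersect1d(tf, ta, return_indices=True)
    if shared.size == 0:
        raise ValueError("no overlapping timestamps between the two series")
    f, a = vf[if_], va[ia]
    valid = a >= min_absorbance
    if not valid.any():
        raise ValueError("no valid points: absorbance below the reliability floor")
    values = np.full(shared.size, np.nan)
    values[valid] = f[valid] / a[valid]
    return EstimationResult(
        quantity="reporter_concentration",
        times=shared,
        values=values,
        validity_mask=valid,
        lam=None,
        well_label=fluo_series.well_label,
    )
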