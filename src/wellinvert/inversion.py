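"""Regularized linear inversion of first-order growth/expression kinetics.

Both estimation problems solved by the package are instances of one scheme.
A measured output y(t_i) is the response of a linear first-order system

    d/dt x(t) = u(t) * w(t) - gamma * x(t),      y(t_i) ~ x(t_i),

driven by an unknown input u(t) (the growth rate, with w = the interpolated
absorbance and gamma = 0; or the promoter activity, with w = the denoised
population volume and gamma = the reporter degradation constant).  The
input is taken piecewise-constant on m uniform control intervals, which
turns the model into a linear observation system

    y = A [u_1 .. u_m, x0]^T + noise,

whose entries are exact integrals of the exponential kernel against the
piecewise-linear forcing w.  The ill-posed inversion is stabilized by a
Tikhonov penalty on the first differences of u (discrete first derivative),
with the weight lambda chosen by generalized cross-validation (GCV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import linalg as sla
from scipy.optimize import lsq_linear

__all__ = [
    "ControlGrid",
    "PiecewiseLinear",
    "LinearSystem",
    "RegularizedSolution",
    "build_input_system",
    "solve_tikhonov",
    "gcv_select",
    "predict_output",
    "default_lambda_grid",
]


def default_lambda_grid(num: int = 61, low: float = 1e-5, high: float = 1e5) -> np.ndarray:
    """Log-spaced candidate grid for the regularization weight."""
    return np.logspace(np.log10(low), np.log10(high), num)


@dataclass
class ControlGrid:
    """Uniform discretization of the analysis window for the input.

    ``edges`` holds the m+1 boundaries of the m control intervals; the
    input is constant on ``[edges[k], edges[k+1])``, the last interval
    closed at the right.  ``m`` control coefficients parametrize the input.
    """

    edges: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.size < 3 or not np.all(np.diff(self.edges) > 0):
            raise ValueError("control grid needs >= 3 strictly increasing edges")

    @classmethod
    def uniform(cls, t_start: float, t_end: float, m: int) -> "ControlGrid":
        if m < 2:
            raise ValueError("need at least m=2 control intervals")
        return cls(np.linspace(t_start, t_end, m + 1))

    @property
    def m(self) -> int:
        return self.edges.size - 1

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def delta(self) -> float:
        return float(self.edges[1] - self.edges[0])


class PiecewiseLinear:
    """Piecewise-linear function given by knots, constant beyond the ends."""

    def __init__(self, t: np.ndarray, v: np.ndarray):
        t = np.asarray(t, dtype=float)
        v = np.asarray(v, dtype=float)
        if t.size < 2 or not np.all(np.diff(t) > 0):
            raise ValueError("knot times must be strictly increasing, >= 2 knots")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite knot values in forcing function")
        self.t = t
        self.v = v
        # cumulative exact integral at knots (trapezoid is exact here)
        self.cum = np.concatenate(
            [[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(t))]
        )

    def __call__(self, x) -> np.ndarray:
        return np.interp(x, self.t, self.v)

    def integral(self, a: float, b: float) -> float:
        """Exact integral over [a, b] of the interpolant (constant beyond ends)."""
        if b <= a:
            return 0.0
        return self._antideriv(b) - self._antideriv(a)

    def _antideriv(self, x: float) -> float:
        t, v = self.t, self.v
        if x <= t[0]:
            return v[0] * (x - t[0])
        if x >= t[-1]:
            return self.cum[-1] + v[-1] * (x - t[-1])
        j = int(np.searchsorted(t, x, side="right") - 1)
        dt = x - t[j]
        slope = (v[j + 1] - v[j]) / (t[j + 1] - t[j])
        return self.cum[j] + v[j] * dt + 0.5 * slope * dt * dt

    def exp_integral(self, a: float, b: float, t_obs: float, gamma: float) -> float:
        """Exact ``int_a^b exp(-gamma (t_obs - s)) w(s) ds`` for this interpolant."""
        if b <= a:
            return 0.0
        if gamma == 0.0:
            return self.integral(a, b)
        total = 0.0
        # split [a, b] at interior knots so w is linear on each piece
        cuts = self.t[(self.t > a) & (self.t < b)]
        pts = np.concatenate([[a], cuts, [b]])
        for p, q in zip(pts[:-1], pts[1:]):
            wp, wq = self(p), self(q)
            d = (wq - wp) / (q - p)
            # substitute x = t_obs - s, integrand exp(-gamma x) * (c - d x)
            c = wp + d * (t_obs - p)
            x0, x1 = t_obs - q, t_obs - p
            delta = x1 - x0
            g = gamma
            e0 = np.exp(-g * x0)
            gd = g * delta
            if gd < 1e-6:
                j0 = e0 * delta * (1.0 - gd / 2.0 + gd * gd / 6.0)
                j1 = x0 * j0 + e0 * delta * delta * (0.5 - gd / 3.0 + gd * gd / 8.0)
            else:
                j0 = e0 * (-np.expm1(-gd)) / g
                j1 = x0 * j0 + e0 * (-np.expm1(-gd) - gd * np.exp(-gd)) / (g * g)
            total += c * j0 - d * j1
        return total


@dataclass
class LinearSystem:
    """Observation system ``y ~ A [u; x0]`` with first-difference penalty D."""

    A: np.ndarray
    D: np.ndarray
    y: np.ndarray
    times: np.ndarray
    grid: ControlGrid
    kernel: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def m(self) -> int:
        return self.A.shape[1] - 1


@dataclass
class RegularizedSolution:
    """Solution of one Tikhonov-regularized inversion."""

    u: np.ndarray
    c0: float
    lam: float
    fitted: np.ndarray
    gcv: float
    edof: float

    @property
    def x(self) -> np.ndarray:
        return np.concatenate([self.u, [self.c0]])


def _observation_row(
    t_obs: float,
    t0: float,
    grid: ControlGrid,
    forcing: PiecewiseLinear,
    gamma: float,
) -> np.ndarray:
    """Row of A for one observation time: kernel integrals + x0 coefficient."""
    row = np.empty(grid.m + 1)
    for k in range(grid.m):
        a = max(grid.edges[k], t0)
        b = min(grid.edges[k + 1], t_obs)
        row[k] = forcing.exp_integral(a, b, t_obs, gamma) if b > a else 0.0
    row[grid.m] = np.exp(-gamma * (t_obs - t0)) if gamma != 0.0 else 1.0
    return row


def build_input_system(
    kernel: dict,
    times: np.ndarray,
    y: np.ndarray,
    grid: ControlGrid,
) -> LinearSystem:
    """Assemble the observation matrix for a piecewise-constant input.

    Parameters
    ----------
    kernel : dict
        ``{"type": "growth", "volume": PiecewiseLinear}`` for the growth
        equation (gamma = 0, forcing = interpolated absorbance), or
        ``{"type": "expression", "gamma": float, "volume": PiecewiseLinear}``
        for reporter synthesis (forcing = denoised population volume).
    times, y : ndarray
        Strictly increasing measurement times (minutes) and observations.
    grid : ControlGrid
        Control intervals; must lie within ``[times[0], times[-1]]``.
    """
    times = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    if times.size != y.size or not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing and match y")
    if grid.m + 1 > times.size:
        raise ValueError(
            f"control grid too fine: m+1={grid.m + 1} unknowns for {times.size} points"
        )
    if grid.edges[0] < times[0] - 1e-9 or grid.edges[-1] > times[-1] + 1e-9:
        raise ValueError("control grid must lie within the measurement window")
    ktype = kernel.get("type")
    if ktype == "growth":
        gamma = 0.0
    elif ktype == "expression":
        gamma = float(kernel["gamma"])
        if gamma < 0:
            raise ValueError("gamma must be >= 0")
    else:
        raise ValueError(f"unknown kernel type {ktype!r}")
    forcing: PiecewiseLinear = kernel["volume"]
    if not np.all(np.isfinite(forcing.v)):
        raise ValueError("non-finite forcing values")

    t0 = times[0]
    A = np.vstack([_observation_row(t, t0, grid, forcing, gamma) for t in times])
    m = grid.m
    D = np.zeros((m - 1, m + 1))
    idx = np.arange(m - 1)
    D[idx, idx] = -1.0 / grid.delta
    D[idx, idx + 1] = 1.0 / grid.delta
    return LinearSystem(A=A, D=D, y=y, times=times, grid=grid, kernel=dict(kernel))


def _penalized_normal_matrix(system: LinearSystem, lam: float) -> np.ndarray:
    return system.A.T @ system.A + lam * (system.D.T @ system.D)


def _gcv_value(system: LinearSystem, lam: float, y: np.ndarray) -> float:
    """GCV(lambda) = n ||(I - H) y||^2 / tr(I - H)^2 with H the hat matrix."""
    A = system.A
    n = A.shape[0]
    M = _penalized_normal_matrix(system, lam)
    try:
        Minv_At = sla.solve(M, A.T, assume_a="pos")
    except sla.LinAlgError:
        return np.inf
    Hy = A @ (Minv_At @ y)
    trH = float(np.sum(A * Minv_At.T))
    denom = (n - trH) ** 2
    if denom <= 0:
        return np.inf
    return n * float(np.sum((y - Hy) ** 2)) / denom


def solve_tikhonov(
    system: LinearSystem, lam: float, nonneg: bool = False
) -> RegularizedSolution:
    """Minimize ``||y - A x||^2 + lam ||D x||^2`` over x = [u; x0].

    With ``nonneg=True`` the input coefficients u are constrained to be
    nonnegative (the initial condition stays free), solved as a bounded
    least-squares problem on the augmented system.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    A, D, y = system.A, system.D, system.y
    m = system.m
    K = np.vstack([A, np.sqrt(lam) * D])
    rhs = np.concatenate([y, np.zeros(D.shape[0])])
    if nonneg:
        lb = np.concatenate([np.zeros(m), [-np.inf]])
        ub = np.full(m + 1, np.inf)
        res = lsq_linear(K, rhs, bounds=(lb, ub), tol=1e-12)
        x = res.x
    else:
        x, _, rank, _ = sla.lstsq(K, rhs)
        if rank < m + 1:
            raise np.linalg.LinAlgError(
                f"rank-deficient system (rank {rank} < {m + 1}) at lambda={lam}; "
                "increase lambda or coarsen the control grid"
            )
    fitted = A @ x
    M = _penalized_normal_matrix(system, lam)
    try:
        Minv_At = sla.solve(M, A.T, assume_a="pos")
        edof = float(np.sum(A * Minv_At.T))
    except sla.LinAlgError:
        edof = float(m + 1)
    return RegularizedSolution(
        u=x[:m],
        c0=float(x[m]),
        lam=float(lam),
        fitted=fitted,
        gcv=_gcv_value(system, lam, y),
        edof=edof,
    )


def gcv_select(
    system: LinearSystem,
    y: np.ndarray | None = None,
    lambda_grid: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Pick lambda minimizing generalized cross-validation over a grid.

    Returns ``(lambda_star, gcv_curve)``; ties are broken toward the larger
    (smoother) lambda.  Deterministic for fixed inputs.
    """
    y = system.y if y is None else np.asarray(y, dtype=float)
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0) or not np.all(np.diff(grid) > 0):
        raise ValueError("lambda_grid must be positive and sorted increasing")
    curve = np.array([_gcv_value(system, lam, y) for lam in grid])
    if not np.any(np.isfinite(curve)):
        raise ValueError("GCV is non-finite over the whole lambda grid")
    best = np.nanmin(np.where(np.isfinite(curve), curve, np.nan))
    # ties -> larger lambda: take the last grid index attaining the minimum
    idx = int(np.max(np.nonzero(curve == best)[0]))
    return float(grid[idx]), curve


def predict_output(system: LinearSystem, solution: RegularizedSolution) -> np.ndarray:
    """Model output at the measurement times (the regularized fit to y)."""
    if solution.u.size != system.m:
        raise ValueError("solution does not match system dimensions")
    return system.A @ solution.x
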