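"""Forward simulation of reporter-gene microplate experiments.

Generates plate experiments with known ground truth by integrating the
population-growth and reporter-expression kinetics

    dV/dt = mu(t) V,    dR/dt = a(t) V - gamma_r R,   dP/dt = a(t) V - gamma_p P,

with a fixed-step RK4 scheme, then applying the instrument model:
absorbance = alpha*V + background + noise, fluorescence = beta*R +
autofluorescence-per-volume * alpha*V + noise, plus optional bead-like
outlier spikes.  Everything is driven by a seed, so fixtures are exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .plate import ABSORBANCE, PlateExperiment, WellSeries, fluorescence_channel

__all__ = ["SyntheticTruth", "simulate_experiment", "scenario_constitutive"]

FLUO = fluorescence_channel("gfp")


@dataclass
class SyntheticTruth:
    """Ground truth and instrument model for one simulated condition."""

    mu: Callable[[float], float]
    a: Callable[[float], float]
    gamma_r: float = 0.00065
    gamma_p: float = 0.00065
    alpha: float = 1.0
    beta: float = 1.0
    V0: float = 0.002
    R0: float = 0.0
    abs_background: float = 0.084
    autofluo_per_volume: float = 50.0
    noise_sd_abs: float = 0.01
    noise_sd_fluo: float = 5.0
    #: optional multiplicative noise component (coefficient of variation);
    #: 0 keeps the default purely additive homoscedastic model
    noise_cv: float = 0.0
    outlier_rate: float = 0.0
    outlier_amplitude: float = 8.0
    sampling: np.ndarray = field(default_factory=lambda: np.arange(0.0, 901.0, 2.0))
    seed: int = 0

    def __post_init__(self) -> None:
        self.sampling = np.asarray(self.sampling, dtype=float)
        if not np.all(np.diff(self.sampling) > 0):
            raise ValueError("sampling times must be strictly increasing")
        for name in ("gamma_r", "gamma_p", "alpha", "beta", "V0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def with_seed(self, seed: int) -> "SyntheticTruth":
        return replace(self, seed=int(seed))


def _integrate(truth: SyntheticTruth, step: float):
    """Fixed-step RK4 for (V, R, P) over the sampling window."""
    t0, t_end = truth.sampling[0], truth.sampling[-1]
    n_steps = int(np.ceil((t_end - t0) / step))
    mu, a = truth.mu, truth.a
    gr, gp = truth.gamma_r, truth.gamma_p

    def rhs(t, y):
        V, R, P = y
        aV = a(t) * V
        return np.array([mu(t) * V, aV - gr * R, aV - gp * P])

    mu_max = max(abs(mu(t)) for t in np.linspace(t0, t_end, 256))
    if mu_max * step > 0.5:
        raise ValueError(
            f"integration step {step} unstable for growth rate {mu_max:.3g}"
        )
    ts = np.empty(n_steps + 1)
    ys = np.empty((n_steps + 1, 3))
    y = np.array([truth.V0, truth.R0, truth.R0], dtype=float)
    t = t0
    ts[0], ys[0] = t, y
    for i in range(n_steps):
        h = min(step, t_end - t)
        k1 = rhs(t, y)
        k2 = rhs(t + h / 2, y + h / 2 * k1)
        k3 = rhs(t + h / 2, y + h / 2 * k2)
        k4 = rhs(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = t + h
        ts[i + 1], ys[i + 1] = t, y
    return ts, ys


def simulate_experiment(
    truth: SyntheticTruth,
    n_replicate_wells: int = 1,
    include_background_well: bool = False,
    step: float = 0.1,
) -> tuple[PlateExperiment, dict]:
    """Simulate a plate experiment with known ground truth.

    Replicate wells share the same kinetics and differ only in their noise
    and outlier draws (seed offsets).  The optional background well carries
    a reporter-free twin culture: beta = 0, same growth and autofluorescence.

    Returns the experiment and a truth record holding, at the sampling
    times, the true growth rate, promoter activity, scaled volume alpha*V,
    reporter signal beta*R, concentrations R/V and P/V, and the indices of
    every injected outlier spike per well and channel.
    """
    ts, ys = _integrate(truth, step)
    t_s = truth.sampling
    V = np.interp(t_s, ts, ys[:, 0])
    R = np.interp(t_s, ts, ys[:, 1])
    P = np.interp(t_s, ts, ys[:, 2])
    alphaV = truth.alpha * V
    record: dict = {
        "times": t_s,
        "mu": np.array([truth.mu(t) for t in t_s]),
        "a": np.array([truth.a(t) for t in t_s]),
        "alphaV": alphaV,
        "betaR": truth.beta * R,
        "reporter_concentration": np.where(V > 0, R / np.where(V > 0, V, 1.0), np.nan),
        "protein_concentration": np.where(V > 0, P / np.where(V > 0, V, 1.0), np.nan),
        "outliers": {},
        "truth": truth,
    }

    rows = "ABCDEFGH"
    labels = [f"{rows[i // 8]}{5 + i % 8}" for i in range(n_replicate_wells)]
    exp = PlateExperiment()

    def make_well(label: str, beta: float, rng: np.random.Generator):
        out_idx = {}
        abs_clean = alphaV + truth.abs_background
        fluo_clean = beta * R + truth.autofluo_per_volume * alphaV
        for channel, clean, sd in (
            (ABSORBANCE, abs_clean, truth.noise_sd_abs),
            (FLUO, fluo_clean, truth.noise_sd_fluo),
        ):
            vals = clean + rng.normal(0.0, sd, size=t_s.size) if sd > 0 else clean.copy()
            if truth.noise_cv > 0:
                vals = vals + rng.normal(0.0, truth.noise_cv * np.abs(clean))
            spikes = np.zeros(t_s.size, dtype=bool)
            if truth.outlier_rate > 0 and sd > 0:
                spikes = rng.random(t_s.size) < truth.outlier_rate
                signs = rng.choice([-1.0, 1.0], size=t_s.size)
                vals = vals + spikes * signs * truth.outlier_amplitude * sd
            out_idx[channel] = np.nonzero(spikes)[0]
            exp.add_series(WellSeries(label, channel, t_s.copy(), vals))
        record["outliers"][label] = out_idx

    for i, label in enumerate(labels):
        rng = np.random.default_rng((truth.seed + 1000003 * (i + 1)) % 2**31)
        make_well(label, truth.beta, rng)
    if include_background_well:
        rng = np.random.default_rng((truth.seed + 999983) % 2**31)
        make_well("A3", 0.0, rng)
        record["background_well"] = "A3"
        exp.define_group("background", ["A3"])
    exp.define_group("replicates", labels)
    exp.metadata["simulated"] = "true"
    exp.metadata["seed"] = str(truth.seed)
    return exp, record


def scenario_constitutive(
    growth_rate_max: float = 0.0125,
    substrate_exhaustion_time: float = 500.0,
    decline_duration: float = 100.0,
    activity_coupling: float = 1000.0,
    activity_basal: float = 5.0,
    second_phase_rate: float = 0.0,
    second_phase_duration: float = 150.0,
    **overrides,
) -> SyntheticTruth:
    """Constitutive-promoter scenario: exponential growth until substrate
    exhaustion, then a smooth decline of the growth rate within
    ``decline_duration`` minutes.

    With ``second_phase_rate > 0`` the decline levels off at that slower
    rate for ``second_phase_duration`` minutes before dropping to zero — a
    diauxic-like second growth phase (e.g. on overflow acetate after the
    primary sugar runs out).

    The promoter activity tracks the gene-expression machinery:
    ``a(t) = activity_coupling * mu(t) + activity_basal``.  The basal term
    exceeds ``activity_coupling * gamma_r`` so the steady-state reporter
    concentration a/(mu+gamma_r) decreases with the growth rate — the
    dilution effect characteristic of constitutive expression.  The initial
    reporter amount is set at its exponential-phase quasi-steady state.
    """
    if growth_rate_max <= 0 or substrate_exhaustion_time <= 0:
        raise ValueError("growth_rate_max and substrate_exhaustion_time must be > 0")
    if not 0 <= second_phase_rate < growth_rate_max:
        raise ValueError("second_phase_rate must be in [0, growth_rate_max)")
    T, d = substrate_exhaustion_time, decline_duration
    mu2 = second_phase_rate

    def ramp(t: float, hi: float, lo: float, start: float) -> float:
        # smooth cosine decline from hi to lo over d minutes
        return lo + (hi - lo) * 0.5 * (1.0 + np.cos(np.pi * (t - start) / d))

    def mu(t: float) -> float:
        if t < T:
            return growth_rate_max
        if t < T + d:
            return ramp(t, growth_rate_max, mu2, T)
        if mu2 > 0:
            t2 = T + d + second_phase_duration
            if t < t2:
                return mu2
            if t < t2 + d:
                return ramp(t, mu2, 0.0, t2)
        return 0.0

    def a(t: float) -> float:
        return activity_coupling * mu(t) + activity_basal

    gamma_r = overrides.pop("gamma_r", 0.00065)
    V0 = overrides.pop("V0", 0.002)
    R0 = overrides.pop("R0", a(0.0) * V0 / (growth_rate_max + gamma_r))
    return SyntheticTruth(mu=mu, a=a, gamma_r=gamma_r, V0=V0, R0=R0, **overrides)
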