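# Methods

## The estimation problems

A growing microbial population of volume V(t) expressing a fluorescent
reporter is observed in a plate reader through two noisy, scale-unknown
channels:

    Ṽ(tᵢ) = α V(tᵢ) + νᵢ              (absorbance / optical density)
    R̃(tᵢ) = β R(tᵢ) + ν′ᵢ             (fluorescence intensity)

where R(t) is the total reporter amount, governed by

    dR/dt = a(t) V(t) − γᵣ R(t),

with a(t) the promoter activity (synthesis rate per unit volume) and γᵣ
the reporter's first-order degradation constant (half-life t₁/₂ = ln 2/γᵣ).
The instrument constants α, β are unknown, so fluorescence-derived
quantities are estimated up to one fixed multiplicative constant; the
growth rate μ(t) = d ln V/dt is absolute because the scale cancels.

All three estimators in this package are instances of one linear inverse
problem: a first-order system dx/dt = u(t) w(t) − γ x(t) driven by an
unknown input u(t), observed through x(tᵢ).

1. **Growth rate** — x = αV, u = μ, w = V̄ (the piecewise-linear
   interpolant of the corrected absorbance), γ = 0. This is the
   approximation d(αV)/dt ≈ μ(t) V̄(t), which replaces the unknown true
   volume by its interpolated measurement and makes the system linear.
2. **Promoter activity** — x = βR, u ∝ a, w = the *denoised volume*
   αV̂(t) produced as a by-product of the growth fit, γ = γᵣ.
3. **Protein concentration** — the host protein P shares the reporter's
   input a(t) but has its own degradation constant γₚ. The shared input
   and the reporter's initial amount are estimated from the fluorescence
   (with γᵣ), then propagated through dP/dt = u w − γₚ P; the reported
   concentration is P(t)/αV̂(t) on the control grid. With γₚ = γᵣ this is
   algebraically the regularized fit of the fluorescence divided by the
   volume — a smoothed version of the pointwise ratio estimate.

The ratio-based **reporter concentration** R̃/Ṽ needs no inversion and is
computed pointwise at shared timestamps.

### Discretization and regularization

The input is piecewise-constant on m uniform control intervals spanning
the usable measurement window (default m = 50, capped so that
m + 1 ≤ n/2 and the least-squares system stays overdetermined). Each
observation row of the design matrix is the exact integral of the kernel
e^{−γ(tᵢ−s)} against the piecewise-linear forcing w over
[τₖ, τₖ₊₁) ∩ [t₀, tᵢ]; the integrals are evaluated in closed form per
linear segment (with `expm1`-based stable forms and a series branch for
γ·Δ < 1e−6), so there is no quadrature tolerance anywhere in the hot
path. The last column carries the initial condition x(t₀): 1 for the
growth kernel, e^{−γ(tᵢ−t₀)} for expression kernels.

The inversion minimizes ‖y − Ax‖² + λ‖Dx‖², where D takes first
differences of the input coefficients scaled by 1/Δτ (a discrete first
derivative; the initial-condition column is not penalized). λ is chosen
by generalized cross-validation,

    GCV(λ) = n‖(I − H(λ))y‖² / tr(I − H(λ))²,  H = A(AᵀA + λDᵀD)⁻¹Aᵀ,

minimized over 61 log-spaced values in [1e−5, 1e5]; ties break toward
the larger (smoother) λ. The hat-matrix trace is computed exactly —
plates are small (n ≲ 500), so no stochastic trace estimation is needed.
The solver itself works on the augmented least-squares system
[A; √λ D] x ≈ [y; 0] (QR-based `lstsq`), which is better conditioned
than forming normal equations; the normal-equations form serves as an
independent oracle in the tests. An optional positivity constraint on
the growth rate is solved as bounded least squares
(`scipy.optimize.lsq_linear`) on the same augmented system — the
established equivalent of an active-set iteration — with plain clipping
available as a fast approximation (`positive="clip"`).

### Reliability masking

Absorbance values near or below the medium background (default 0.084)
carry little information and large relative noise, so growth-rate fits
exclude points with corrected absorbance below `min_absorbance`
(default = the background value) and the result's validity mask records
the usable window. The denoised volume exposes this window as its
`support`; expression-kernel estimators restrict their fits to it, since
outside it the volume is extrapolated, not estimated. Concentrations are
reported as NaN and masked wherever the volume is non-positive.

## Preprocessing

**Automatic outlier filtering.** Plate cultures often contain a glass
bead for aeration; when it crosses the light path the reading spikes.
The filter iteratively (default 3 rounds) smooths the current inliers
with a Savitzky–Golay local-polynomial fit (window 15 points, order 3),
computes residuals and their standard deviation σ over inliers only —
recomputing σ after each round so already-flagged spikes stop inflating
it — and flags points with |residual| > 3σ. The mask is monotone and
the procedure idempotent once converged. Two deliberate numerical
choices: (i) the filter operates in index space, exact only for uniform
sampling; plate readers sample near-uniformly (every 2 min here), and
the approximation error is far below the noise level. (ii) residuals
smaller than 1e−5 of the series' largest magnitude are never flagged —
on noise-free data σ collapses to the deterministic smoothing bias
(~1e−6 relative) and a pure σ-rule would flag smooth curvature at the
series ends; the floor is orders of magnitude below any real noise
level.

**Band filtering.** A piecewise-linear trend through user anchors with a
tolerance band; points strictly outside the band are flagged (boundary
inclusive). Beyond the anchor range the nearest anchor's value extends
constantly.

**Background correction.** Three procedures, matching the three
situations met in practice: a fixed baseline (background constant in
time, e.g. medium absorbance, default 0.084); subtraction of a
reporter-free background well interpolated at the same times (valid when
the background strain grows identically); and a calibration curve for
growth-dependent autofluorescence when the two strains grow differently
— a smoothing spline mapping the background strain's absorbance to its
fluorescence, evaluated at the strain of interest's own corrected
absorbance and subtracted. The spline's smoothing parameter is a
residual budget per point normalized by the variance of the
fluorescence values (0 interpolates; values near (σ_noise/σ_signal)²
are appropriate — 0.1 for the simulated fixtures). Outside the observed
absorbance support the curve continues linearly with the boundary slope
inside a user-set extrapolation interval and is clamped to the boundary
value beyond it, keeping it continuous. Negative corrected values are
retained rather than clipped; clipping would bias the inversion, and
the estimators handle low values by masking.

Calibration pairing requires exact timestamp matches (the two channels
of one well are read in the same cycle); interpolation is used only for
the background-well method, where the wells' clocks may differ.

## The synthetic generator

`scenario_constitutive` emulates the canonical validation experiment: a
constitutive-promoter GFP fusion growing in minimal medium with a single
carbon source read every 2 minutes for 900 minutes.

| parameter | default | rationale |
|---|---|---|
| μ_max | 0.0125 min⁻¹ | glucose minimal-medium growth (doubling ≈ 55 min) |
| exhaustion time | 500 min | substrate depletion break in the growth curve |
| decline duration | 100 min | smooth (cosine) arrest after depletion |
| γᵣ = γₚ | 0.00065 min⁻¹ | stable GFP, half-life ≈ 17.8 h |
| a(t) | 1000·μ(t) + 5 | activity tracks machinery activity plus basal |
| αV₀ | 0.002 | corrected absorbance reaches ≈ 1 at exhaustion |
| absorbance background | 0.084 | medium baseline |
| autofluorescence | 50 per unit αV | ~4% of the reporter signal, volume-dependent |
| noise sd | 0.01 (abs), 5 (fluo) | ≈1% of each channel's maximum, additive |
| sampling | every 2 min | instrument cycle time |

The basal activity term exceeds coupling·γᵣ, so the steady-state
concentration a/(μ+γᵣ) *decreases* with growth rate — the dilution
effect expected of constitutive expression. The initial reporter amount
starts at its quasi-steady state. A `second_phase_rate` option levels
the post-exhaustion decline at a slower rate (diauxic-like regrowth on
overflow products); `noise_cv` adds an optional multiplicative noise
component; `outlier_rate`/`outlier_amplitude` inject bead-like spikes of
the given multiple of the channel's noise sd at Bernoulli-sampled
timepoints, with the injected indices recorded in the truth record.

Kinetics are integrated with fixed-step RK4 at 0.1 min — step-halving
changes the solution by < 1e−6 relative — chosen over adaptive solvers
for bit-reproducibility across platforms; identical seeds give
bit-identical experiments, and replicate wells differ only by noise-seed
offsets. Measurement noise is Gaussian by assumption (the truth record
stores the spec).

What the generator does **not** emulate: oxygen-transfer limitation at
high density (real cultures slow above OD ≈ 0.1; simulated ones grow
exponentially until exhaustion), mechanistic substrate/acetate
metabolism, reporter maturation delay, temperature drift, and
evaporation. Passing tests therefore validate the inversion machinery
and the correction procedures, not these instrument- and
physiology-specific effects; on real data the user should expect the
low-OD window to be relatively *less* noisy than this generator's
homoscedastic noise makes it, and high-OD growth rates to decline
earlier.

## Summary statistics

Group curves interpolate each member onto the union of member grids
clipped to the intersection of valid ranges; sd is the n−1 sample
deviation and sem = sd/√n. Steady-state points select timepoints by a
corrected-absorbance window (0.01–0.1 by convention) and convert growth
rates to doublings per hour (μ·60/ln 2); concentrations are normalized
to a user-chosen reference condition. The model-comparison statistic
interpolates a predicted concentration-vs-growth-rate curve at the
observed growth rates (linear, with linear extrapolation beyond the
curve's ends) and reports R² = 1 − RSS/TSS about the observed mean,
which is negative when the prediction does worse than that mean.

## Known limitations and open choices

- GCV does not penalize the initial-condition coefficient (standard
  practice; a tool that includes it would select slightly different λ).
- The shared-input protein estimate is built sequentially (estimate u
  and c₀ from the reporter, then propagate the host equation) — when
  only the reporter is observed this is equivalent to a joint fit.
- The host protein's initial condition is set to the reporter's
  estimated initial amount, which makes the γₚ = γᵣ case reduce exactly
  to the smoothed reporter concentration.
- Savitzky–Golay in index space assumes near-uniform sampling; strongly
  non-uniform series should be filtered with the band method instead.
- The GCV hat matrix is formed densely; fine for plate-scale series
  (n ≤ ~2000), not intended for long time series beyond that.
- Problem sizes in the validation suite: 900-minute experiments at
  2-minute sampling (451 points/channel), 50 control intervals, 10
  replicate seeds per stochastic check.
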