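# wellinvert

Analysis engine for fluorescent **reporter-gene experiments in microplate
readers**: from raw absorbance and fluorescence time series, estimate the
time-varying growth rate, promoter activity, reporter concentration and
host-protein concentration of growing microbial cultures.

Reporter fluorescence is an indirect readout. The measured channels are
proportional to population volume V(t) and total reporter amount R(t),

    Ṽ(tᵢ) = α V(tᵢ) + νᵢ,        R̃(tᵢ) = β R(tᵢ) + ν′ᵢ,

while the quantities of biological interest — the growth rate
μ(t) = d ln V/dt and the promoter activity a(t) in

    dR/dt = a(t) V(t) − γᵣ R(t)

— are *inputs* of first-order kinetics and must be deconvolved from the
data. wellinvert does this by regularized linear inversion: the input is
piecewise-constant on a grid of control points, the observation matrix is
assembled from closed-form kernel integrals, a Tikhonov penalty on the
input's first derivative suppresses spurious oscillation, and the
regularization weight λ is selected by generalized cross-validation.
Around the core inversion the package provides the preprocessing a real
plate needs — iterative Savitzky–Golay outlier filtering (bead spikes),
fixed-baseline / background-well / calibration-curve background
correction — plus well groups with mean ± sd/sem summary curves,
steady-state growth-rate and concentration extraction (doublings per
hour = μ·60/ln 2), an R² model-comparison statistic, and a seeded forward
simulator that generates experiments with known ground truth.

Intended users: microbiologists and systems biologists running reporter
fusions in 96-well plate readers, and method developers who want a
self-validating inversion engine with scikit-learn-style estimators.

See `docs/methods.md` for the full model and numerical choices and
`docs/json_schema.md` for the experiment file format.

## Worked example

Simulate a glucose-like experiment (constitutive promoter, substrate
exhaustion at 500 min), correct backgrounds, and recover growth rate and
promoter activity:

```python
import numpy as np
import wellinvert as wi
from wellinvert.preprocess import (BackgroundSpec, apply_background_correction,
                                   build_calibration_curve)

truth = wi.scenario_constitutive(growth_rate_max=0.0125,
                                 substrate_exhaustion_time=500.0, seed=42)
exp, record = wi.simulate_experiment(truth, n_replicate_wells=3,
                                     include_background_well=True)

# absorbance: subtract the medium baseline
fixed = BackgroundSpec(method="fixed", baseline=0.084)
abs_a5 = apply_background_correction(exp.get_series("A5", "absorbance"), fixed)
abs_bg = apply_background_correction(exp.get_series("A3", "absorbance"), fixed)

# fluorescence: calibration curve built from the reporter-free well A3
curve = build_calibration_curve(abs_bg, exp.get_series("A3", "fluorescence:gfp"),
                                smoothing=0.1)
fluo_a5 = apply_background_correction(exp.get_series("A5", "fluorescence:gfp"),
                                      BackgroundSpec(method="calibration", curve=curve),
                                      paired_absorbance=abs_a5)

# growth rate, then promoter activity from the denoised volume
growth = wi.estimate_growth_rate(abs_a5)
act = wi.estimate_promoter_activity(fluo_a5, growth.denoised_volume)

t, mu = growth.valid_points()
expo = (t > 320) & (t < 480)
ta, va = act.valid_points()
print(f"lambda (GCV):            {growth.lam:.3g}")
print(f"exponential-phase mu:    {mu[expo].mean():.5f} per min")
print(f"doubling time:           {np.log(2)/mu[expo].mean():.1f} min")
print(f"doublings per hour:      {wi.doublings_per_hour(mu[expo].mean()):.3f}")
print(f"activity plateau (a.u.): {va[(ta>320)&(ta<480)].mean():.1f}")
print(f"true activity plateau:   {truth.a(400.0):.1f}")
```

prints

```
lambda (GCV):            2.15e+04
exponential-phase mu:    0.01250 per min
doubling time:           55.5 min
doublings per hour:      1.082
activity plateau (a.u.): 17.6
true activity plateau:   17.5
```

The growth rate is recovered at 0.0125/min (a 55-minute doubling time,
1.082 doublings/h) and the promoter-activity plateau within 1% of the
simulated truth — activity is identified up to the unknown instrument
constant β/α, here 1 by construction. `growth.lam` is the
regularization weight GCV selected; lower it for sharper temporal
features, raise it for smoother estimates.

The same pipeline is available from the shell:

```sh
wellinvert simulate --replicates 8 --seed 42 -o exp.json
wellinvert filter  -i exp.json -o exp.json --wells A5-A12
wellinvert correct -i exp.json -o exp.json --method fixed --wells A5-A12
wellinvert estimate -i exp.json --quantity growth_rate --wells A5-A12 -o growth.csv
```

Scikit-learn-style estimator classes (`GrowthRateEstimator`,
`PromoterActivityEstimator`, `ProteinConcentrationEstimator`,
`SavitzkyGolayOutlierFilter`) expose the same functionality with
`fit`/`predict`/`get_params` for composition with sklearn tooling.

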