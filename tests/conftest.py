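import numpy as np
import pytest

import wellinvert as wi
from wellinvert.preprocess import BackgroundSpec, apply_background_correction


@pytest.fixture(scope="session")
def constitutive_noiseless():
    """Noiseless constitutive-promoter simulation (no autofluorescence)."""
    truth = wi.scenario_constitutive(
        0.0125, 500.0, noise_sd_abs=0.0, noise_sd_fluo=0.0, autofluo_per_volume=0.0
    )
    exp, record = wi.simulate_experiment(truth, n_replicate_wells=1)
    return exp, record


@pytest.fixture(scope="session")
def constitutive_noisy():
    """Constitutive scenario at the default instrument noise, seeded."""
    truth = wi.scenario_constitutive(0.0125, 500.0, autofluo_per_volume=0.0, seed=7)
    exp, record = wi.simulate_experiment(truth, n_replicate_wells=1)
    return exp, record


@pytest.fixture(scope="session")
def corrected_growth_noiseless(constitutive_noiseless):
    """Background-corrected absorbance plus a fitted growth-rate result."""
    exp, record = constitutive_noiseless
    spec = BackgroundSpec(method="fixed", baseline=record["truth"].abs_background)
    corrected = apply_background_correction(exp.get_series("A5", "absorbance"), spec)
    growth = wi.estimate_growth_rate(corrected)
    return corrected, growth, record


def make_series(times, values, **kwargs) -> wi.WellSeries:
    return wi.WellSeries("A1", "absorbance", np.asarray(times, float),
                         np.asarray(values, float), **kwargs)
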