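"""Analysis parameter file (TOML), mirroring a parameters screen.

All knobs a routine analysis needs, with the package defaults:

.. code-block:: toml

    [background]
    default_value = 0.084          # medium absorbance baseline

    [model]
    gamma_r = 0.00065              # reporter degradation constant [1/min]
    gamma_p = 0.00065              # host-protein degradation constant [1/min]
    positive_growth_rate = false

    [inference]
    control_points = 50
    lambda = "gcv"                 # or a number
    lambda_grid_low = 1e-5
    lambda_grid_high = 1e5
    lambda_grid_num = 61
    min_absorbance = 0.084

    [outlier_filter]
    window = 15
    polyorder = 3
    cutoff_sigma = 3.0
    iterations = 3
"""

from __future__ import annotations

import copy
import tomllib

DEFAULTS: dict = {
    "background": {"default_value": 0.084},
    "model": {"gamma_r": 0.00065, "gamma_p": 0.00065, "positive_growth_rate": False},
    "inference": {
        "control_points": 50,
        "lambda": "gcv",
        "lambda_grid_low": 1e-5,
        "lambda_grid_high": 1e5,
        "lambda_grid_num": 61,
        "min_absorbance": 0.084,
    },
    "outlier_filter": {"window": 15, "polyorder": 3, "cutoff_sigma": 3.0, "iterations": 3},
}


def load_config(path: str | None = None) -> dict:
    """Load a TOML parameter file merged over the package defaults."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path, "rb") as fh:
            user = tomllib.load(fh)
        for section, entries in user.items():
            if section not in cfg:
                raise ValueError(f"unknown config section {section!r}")
            unknown = set(entries) - set(cfg[section])
            if unknown:
                raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
            cfg[section].update(entries)
    return cfg
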