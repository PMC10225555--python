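import numpy as np
import pandas as pd
import pytest

from hcscreen.plate_stats import ControlStats
from hcscreen.synthetic_data import FieldImageSpec, ScreenScenario, render_field, simulate_screen

TABLE1_ACTIVITIES = [47, 47, 51, 42, 44, 44, 44]
TABLE1_CELL_COUNTS = [3920, 3644, 3147, 4447, 4477, 3272, 3139]
TABLE1_WELLS = ["B4", "F2", "D11", "F8", "D9", "F6", "C11"]

PRINTED_DILUTIONS = [0.5, 0.167, 0.056, 0.0185, 0.0062, 0.0021, 0.00069]
PRINTED_DILUTION_SIG_FIGS = [1, 3, 2, 3, 2, 2, 2]

VALIDATION_ACTIVITIES = [49.5, 42.8, 68.6, 42.5]
VALIDATION_CONCENTRATIONS = [0.056, 0.056, 0.056, 0.0185]


@pytest.fixture
def small_scenario():
    """A fast 1-plate scenario with planted hits and cytotoxic decoys."""
    return ScreenScenario(
        n_extracts=80,
        n_true_hits=3,
        hit_effect=(50.0, 60.0, 70.0),
        n_cytotoxic=5,
        seed=11,
    )


@pytest.fixture
def small_screen(small_scenario):
    return simulate_screen(small_scenario)


@pytest.fixture
def clean_controls():
    """Exact control stats for hand-computable examples."""
    return ControlStats(
        mu_p=700.0, delta_p=10.0, mu_n=200.0, delta_n=10.0,
        n_pos=8, n_neg=8, cell_mu_n=4000.0, cell_delta_n=500.0,
    )


@pytest.fixture
def noisy_field():
    spec = FieldImageSpec(n_cells=50, noise_sd=15.0, cytoplasm_gfp_mean=300.0, seed=7)
    return render_field(spec)


@pytest.fixture
def noiseless_field():
    spec = FieldImageSpec(n_cells=50, noise_sd=0.0, cytoplasm_gfp_mean=300.0, seed=7)
    return render_field(spec)
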