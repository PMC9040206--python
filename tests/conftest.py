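import numpy as np
import pandas as pd
import pytest

from riskstrat import RatesTable
from riskstrat import io as rio


@pytest.fixture(scope="session")
def white_rates():
    return rio.load_bundled_rates("us_white_rates_synthetic.csv")


@pytest.fixture(scope="session")
def singapore_rates():
    return rio.load_bundled_rates()


@pytest.fixture(scope="session")
def gail_params():
    return rio.load_bundled_gail_params()


@pytest.fixture(scope="session")
def panel():
    """(PRSWeights, allele freqs) of the bundled synthetic 313-variant panel."""
    return rio.load_bundled_panel()


@pytest.fixture
def constant_rates():
    """Single-interval table with h = 0.002/yr, m = 0.01/yr over [50, 55)."""
    return RatesTable([50], [55], [0.002], [0.01])


@pytest.fixture
def tiny_cohort():
    """Six individuals spanning the risk-factor categories."""
    return pd.DataFrame({
        "individual_id": [f"S{i}" for i in range(6)],
        "age": [34.0, 42.0, 47.0, 52.0, 61.0, 74.0],
        "menarche": [">=14", "12-13", "<12", "unknown", "12-13", ">=14"],
        "first_birth": ["<20", "20-25", "25-30", ">=30", "nulliparous", "unknown"],
        "biopsy": ["no", "yes", "no", "unknown", "no", "no"],
        "fh_breast": [False, True, False, False, False, False],
        "fh_ovarian": [False, False, True, False, False, False],
        "ptv_carrier": [False, False, False, True, False, False],
    })


def euler_absolute_risk(h, m, r, dt=5.0, step=1e-4):
    """Fine-step Euler oracle for constant competing hazards."""
    t, surv, risk = 0.0, 1.0, 0.0
    n = int(round(dt / step))
    for _ in range(n):
        risk += surv * r * h * step
        surv *= 1.0 - (r * h + m) * step
        t += step
    return risk
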