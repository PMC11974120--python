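import numpy as np
import pandas as pd
import pytest

from seegtc.simulate import generate_cohort, scaled_config
from seegtc.workflow import analyze_cohort

# Reduced-scale study conditions shared by the statistical suites: default
# effect sizes and the 8:2 patient imbalance, with short (2 s) windows so
# seed-replicated runs stay within desk-scale budgets.
SCALED_WINDOW_S = 2.0
SCALED_TOTAL_S = 10.0


def make_scaled_cohort(seed: int, **overrides):
    return generate_cohort(scaled_config(seed=seed, **overrides))


def analyze_scaled(cohort, seed: int, **kwargs):
    kwargs.setdefault("window_s", SCALED_WINDOW_S)
    kwargs.setdefault("total_s", SCALED_TOTAL_S)
    return analyze_cohort(cohort, seed=seed, **kwargs)


@pytest.fixture(scope="session")
def scaled_cohort():
    return make_scaled_cohort(seed=1)


@pytest.fixture(scope="session")
def scaled_analysis(scaled_cohort):
    return analyze_scaled(scaled_cohort, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_recording():
    from seegtc.signal import Recording

    r = np.random.default_rng(0)
    data = r.standard_normal((4, 512 * 30))
    return Recording(data=data, fs=512.0, channel_names=["A1", "A2", "B1", "B2"],
                     period="pre", patient_id="P01")
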