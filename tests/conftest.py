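"""Shared fixtures: small study tables and fitting shortcuts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from storekin import FitConfig, NoiseSpec
from storekin.data_io import COLUMNS, StudyTable
from storekin.simulate import dark_design, generate
from storekin.reference import truth_for


@pytest.fixture(scope="session")
def fast_cfg():
    """Reduced multi-start count: plenty for the well-posed test problems."""
    return FitConfig(n_starts=4)


@pytest.fixture(scope="session")
def zero_truth():
    """Zero-order dark-storage truth (antheraxanthin in glass)."""
    return truth_for("antheraxanthin", "glass", "dark")


@pytest.fixture(scope="session")
def fractional_truth():
    """Fractional-conversion dark-storage truth (β-carotene in glass)."""
    return truth_for("beta-carotene", "glass", "dark")


@pytest.fixture(scope="session")
def noiseless_zero_table(zero_truth):
    model, truth = zero_truth
    return generate(model, truth, dark_design())


@pytest.fixture()
def noisy_zero_table(zero_truth):
    model, truth = zero_truth
    return generate(model, truth, dark_design(), NoiseSpec(sd=0.02, seed=7))


def small_table(concentrations, exposures=None, temperature=10.0, axis="time_days"):
    """Hand-rolled single-temperature table for parsing/validation tests."""
    n = len(concentrations)
    exposures = exposures if exposures is not None else list(range(n))
    unit = "day" if axis == "time_days" else "Mlux_h"
    df = pd.DataFrame(
        {
            "carotenoid": ["lutein"] * n,
            "packaging": ["glass"] * n,
            "condition": ["dark" if axis == "time_days" else "illuminated"] * n,
            "temperature_C": [temperature] * n,
            "exposure": [float(e) for e in exposures],
            "exposure_unit": [unit] * n,
            "replicate": [1] * n,
            "concentration_ug_per_g": [float(c) for c in concentrations],
        },
        columns=list(COLUMNS),
    )
    return StudyTable(df, axis)
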