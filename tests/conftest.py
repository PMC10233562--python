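import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from bloodhof import LabPanel, default_reference_intervals, default_registry
from bloodhof.compute import FeatureEngine

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def intervals():
    return default_reference_intervals()


@pytest.fixture(scope="session")
def engine(registry, intervals):
    return FeatureEngine(registry, intervals)


@pytest.fixture(scope="session")
def golden_cases():
    with open(DATA_DIR / "golden_values.json") as fh:
        return json.load(fh)


@pytest.fixture
def make_panel(registry):
    """Panel factory: values in canonical units unless (value, unit) given."""

    def _make(patient_id="p1", clinical=None, **measurements):
        m = {}
        for code, value in measurements.items():
            if isinstance(value, (tuple, list)):
                m[code] = (float(value[0]), str(value[1]))
            else:
                m[code] = (float(value), registry.units.canonical_unit(code))
        return LabPanel(patient_id, m, dict(clinical or {}))

    return _make


@pytest.fixture(scope="session")
def random_positive_table(registry):
    """1,000 synthetic patients with every analyte strictly positive,
    drawn log-normally around each reference interval."""
    rng = np.random.default_rng(20240917)
    intervals = default_reference_intervals()
    n = 1000
    cols = {}
    for code in registry.units.analytes:
        ri = intervals.get(code)
        if ri is not None and ri.lower and ri.upper:
            mu = 0.5 * (np.log(ri.lower) + np.log(ri.upper))
            sigma = (np.log(ri.upper) - np.log(ri.lower)) / 3.92
        else:
            mu, sigma = 0.0, 0.4
        cols[code] = np.exp(mu + sigma * rng.standard_normal(n))
    cols["Age"] = rng.uniform(30, 85, n).round(1)
    cols["Sex"] = rng.integers(0, 2, n).astype(float)
    cols["Height"] = rng.uniform(1.5, 1.9, n)
    cols["Weight"] = rng.uniform(45, 95, n)
    cols["BMI"] = cols["Weight"] / cols["Height"] ** 2
    cols["IdealWeight"] = rng.uniform(50, 80, n)
    return pd.DataFrame(cols, index=[f"r{i}" for i in range(n)])
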