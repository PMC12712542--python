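import math

import numpy as np
import pytest

import traitagg as ta


@pytest.fixture
def log_t():
    return ta.get_transform("log")


@pytest.fixture
def sqrt_t():
    return ta.get_transform("sqrt")


@pytest.fixture
def identity_t():
    return ta.get_transform("identity")


@pytest.fixture
def two_point_species():
    """Values {1, e^2}: logs are 0 and 2, raw mean (1 + e^2)/2."""
    return np.array([1.0, math.e**2])


@pytest.fixture
def small_table():
    """Three species, two traits, shared individuals, hand-set values."""
    records = []
    values = {
        "spA": [(0.2, 0.30), (0.25, 0.35), (0.3, 0.28)],
        "spB": [(0.4, 0.20), (0.5, 0.22)],
        "spC": [(0.35, 0.25), (0.30, 0.27), (0.33, 0.26), (0.4, 0.24)],
    }
    for sp, pairs in values.items():
        for i, (d, rtd) in enumerate(pairs, start=1):
            ind = f"{sp}_i{i}"
            records.append((sp, ind, "D", d))
            records.append((sp, ind, "RTD", rtd))
    return ta.TraitMeasurementTable.from_records(records)


@pytest.fixture
def default_table():
    """Default-configuration simulated table, fixed seed."""
    return ta.simulate_trait_table(ta.default_config(seed=42))
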