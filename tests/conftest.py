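import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import shelfkin as sk

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def ols_oracle(t, y):
    """Closed-form two-parameter least squares, independent of the package.

    Returns (slope, intercept, r_squared) from the textbook sums-of-squares
    formulas; the flat-response convention is R² = 0.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    tbar, ybar = t.mean(), y.mean()
    sxx = ((t - tbar) ** 2).sum()
    sxy = ((t - tbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * tbar
    residual = y - (intercept + slope * t)
    sst = ((y - ybar) ** 2).sum()
    r2 = 1.0 - (residual**2).sum() / sst if sst > 0 else 0.0
    return slope, intercept, r2


def make_series(times, values, attribute="color_acceptance",
                packaging="al_bag_n2", temperature_c=25.0, **kwargs):
    obs = tuple(
        sk.QualityObservation(float(t), float(v)) for t, v in zip(times, values)
    )
    return sk.QualitySeries(
        attribute=attribute,
        condition=sk.StorageCondition(packaging, temperature_c),
        observations=obs,
        **kwargs,
    )


@pytest.fixture(scope="session")
def sensory():
    return sk.builtin_fixture("table2_sensory")


@pytest.fixture(scope="session")
def microbial():
    return sk.builtin_fixture("table1_microbial")


@pytest.fixture(scope="session")
def color_rates():
    return sk.builtin_fixture("table4_color_k")


@pytest.fixture(scope="session")
def lstar_rates():
    return sk.builtin_fixture("table3_lstar_k")


@pytest.fixture(scope="session")
def shelf_table():
    return sk.builtin_fixture("table5_shelf_life")
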