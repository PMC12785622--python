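"""Zero/first-order fitting against closed-form OLS oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import shelfkin as sk
from shelfkin.errors import (
    ConsistencyError,
    DegenerateDesignError,
    DomainError,
    InsufficientDataError,
)

from conftest import make_series, ols_oracle

# random decaying-ish series: 4-9 points, positive values
series_strategy = st.integers(4, 9).flatmap(
    lambda n: st.tuples(
        st.just(np.arange(n) * 3.0),
        st.lists(
            st.floats(0.5, 9.0, allow_nan=False), min_size=n, max_size=n
        ),
    )
)


# --------------------------------------------------------------------------
# oracle equivalence

@given(data=series_strategy)
def test_zero_order_matches_closed_form_ols(data):
    t, q = data
    series = make_series(t, q)
    fit = sk.fit_zero_order(series)
    slope, intercept, r2 = ols_oracle(t, q)
    assert fit.k == pytest.approx(-slope, abs=1e-10)
    assert fit.q0_hat == pytest.approx(intercept, abs=1e-10)
    assert fit.r_squared == pytest.approx(r2, abs=1e-10)


@given(data=series_strategy)
def test_first_order_matches_closed_form_ols_on_log_scale(data):
    t, q = data
    series = make_series(t, q)
    fit = sk.fit_first_order(series)
    slope, intercept, r2 = ols_oracle(t, np.log(q))
    assert fit.k == pytest.approx(-slope, abs=1e-10)
    assert fit.q0_hat == pytest.approx(np.exp(intercept), rel=1e-10)
    assert fit.r_squared == pytest.approx(r2, abs=1e-10)


# --------------------------------------------------------------------------
# exact recovery on noise-free data

@pytest.mark.parametrize("k, q0", [(0.5, 10.0), (0.02, 6.3), (0.11, 7.5)])
def test_zero_order_recovers_generating_line(k, q0):
    t = np.array([0, 2, 4, 6.0])
    fit = sk.fit_zero_order(make_series(t, q0 - k * t))
    assert fit.k == pytest.approx(k, abs=1e-9)
    assert fit.q0_hat == pytest.approx(q0, abs=1e-9)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("k, q0", [(0.02, 6.3), (0.047, 6.3), (0.11, 8.0)])
def test_first_order_recovers_generating_exponential(k, q0):
    t = np.arange(0, 25, 3.0)
    fit = sk.fit_first_order(make_series(t, q0 * np.exp(-k * t)))
    assert fit.k == pytest.approx(k, abs=1e-9)
    assert fit.q0_hat == pytest.approx(q0, rel=1e-9)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_flat_series_has_zero_rate_and_zero_r_squared():
    flat = make_series([0, 3, 6, 9], [7.0, 7.0, 7.0, 7.0])
    for fit in (sk.fit_zero_order(flat), sk.fit_first_order(flat)):
        assert fit.k == 0.0
        assert fit.r_squared == 0.0


def test_collinear_hedonic_triplet_gives_exact_rate():
    # baseline 6.3 then two sessions falling exactly 0.7/3 weeks
    fit = sk.fit_zero_order(make_series([0, 3, 6], [6.3, 5.6, 4.9]))
    assert fit.k == pytest.approx(7 / 30, abs=1e-12)
    assert fit.q0_hat == pytest.approx(6.3, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_first_order_rate_of_chilled_nitrogen_series(sensory):
    # colour acceptance in the nitrogen-flushed bag at 4 °C, week-0
    # baseline included: the slow browning rate is a few 1e-3 per week
    series = sensory.get(
        "color_acceptance", sk.StorageCondition("al_bag_n2", 4.0)
    ).with_baseline(sensory.baseline["color_acceptance"])
    fit = sk.fit_first_order(series)
    t, q = series.arrays()
    slope, _, _ = ols_oracle(t, np.log(q))
    assert fit.n_points == 9
    assert fit.k == pytest.approx(-slope, abs=1e-12)
    assert fit.k == pytest.approx(4.30542643e-3, abs=1e-9)


# --------------------------------------------------------------------------
# error handling

def test_too_few_points_raises():
    with pytest.raises(InsufficientDataError):
        sk.fit_zero_order(make_series([0, 3], [6, 5]))


def test_below_detection_points_do_not_count_toward_the_minimum():
    obs = (
        sk.QualityObservation(0, 0.25, below_detection=True),
        sk.QualityObservation(3, 0.25, below_detection=True),
        sk.QualityObservation(6, 40.0),
        sk.QualityObservation(9, 55.0),
    )
    series = sk.QualitySeries("tbc", sk.StorageCondition("clear_plastic", 4.0), obs)
    with pytest.raises(InsufficientDataError):
        sk.fit_zero_order(series)


def test_nonpositive_value_names_week():
    with pytest.raises(DomainError, match="week 6"):
        sk.fit_first_order(make_series([0, 3, 6, 9], [6.0, 5.0, 0.0, 4.0]))


# --------------------------------------------------------------------------
# order selection

def test_select_order_prefers_larger_r_squared():
    # R² pairs as printed for the 35 °C L* fits: first order wins
    zero = sk.KineticFit("zero", 1.0, 40.6, 0.764, 9)
    first = sk.KineticFit("first", 0.045, 40.6, 0.980, 9)
    assert sk.select_order(zero, first).order == "first"


def test_select_order_can_pick_zero_order():
    zero = sk.KineticFit("zero", 1.0, 20.0, 0.95, 5)
    first = sk.KineticFit("first", 0.045, 20.0, 0.76, 5)
    assert sk.select_order(zero, first).order == "zero"


def test_select_order_tie_goes_to_first_order():
    zero = sk.KineticFit("zero", 0.1, 6.3, 0.9, 5)
    first = sk.KineticFit("first", 0.02, 6.3, 0.9, 5)
    assert sk.select_order(zero, first).order == "first"


def test_select_order_rejects_mismatched_provenance():
    zero = sk.KineticFit("zero", 0.1, 6.3, 0.9, 5, attribute="color_acceptance")
    first = sk.KineticFit("first", 0.02, 6.3, 0.95, 6, attribute="color_acceptance")
    with pytest.raises(ConsistencyError):
        sk.select_order(zero, first)
    with pytest.raises(ConsistencyError):
        sk.select_order(zero, zero)


# --------------------------------------------------------------------------
# prediction

@pytest.mark.parametrize(
    "order, k, q0, t, expected",
    [
        ("first", 0.028, 6.3, 0.0, 6.3),
        ("zero", 0.5, 10.0, 4.0, 8.0),
        ("first", 0.028, 6.3, 8.253990034406666, 5.0),
    ],
)
def test_predict_quality(order, k, q0, t, expected):
    assert sk.predict_quality(order, k, q0, t) == pytest.approx(expected, abs=1e-9)


def test_predict_quality_rejects_bad_inputs():
    with pytest.raises(DomainError):
        sk.predict_quality("first", 0.02, 6.3, -1.0)
    with pytest.raises(DomainError):
        sk.predict_quality("first", 0.02, 0.0, 1.0)
    with pytest.raises(DomainError):
        sk.predict_quality("second", 0.02, 6.3, 1.0)


# --------------------------------------------------------------------------
# invariance properties

@given(data=series_strategy, c=st.floats(0.1, 50, allow_nan=False))
def test_zero_order_scale_equivariance(data, c):
    t, q = data
    base = sk.fit_zero_order(make_series(t, q))
    scaled = sk.fit_zero_order(make_series(t, np.asarray(q) * c))
    assert scaled.k == pytest.approx(c * base.k, rel=1e-9, abs=1e-12)
    assert scaled.q0_hat == pytest.approx(c * base.q0_hat, rel=1e-9, abs=1e-12)
    assert scaled.r_squared == pytest.approx(base.r_squared, abs=1e-9)


@given(data=series_strategy, shift=st.floats(0, 100, allow_nan=False))
def test_time_shift_changes_intercept_not_rate(data, shift):
    t, q = data
    for fitter in (sk.fit_zero_order, sk.fit_first_order):
        base = fitter(make_series(t, q))
        moved = fitter(make_series(np.asarray(t) + shift, q))
        assert moved.k == pytest.approx(base.k, rel=1e-9, abs=1e-12)
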