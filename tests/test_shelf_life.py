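"""Shelf-life prediction, censored experimental shelf life, comparison table."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import shelfkin as sk
from shelfkin.errors import DomainError, InsufficientDataError

from conftest import make_series


# --------------------------------------------------------------------------
# predicted shelf life

@pytest.mark.parametrize(
    "order, q0, qe, k, t_s, reported",
    [
        ("first", 6.3, 5.0, 0.016, 14.444482560211664, 14),
        ("first", 6.3, 5.0, 0.028, 8.253990034406666, 8),
        ("first", 6.3, 5.0, 0.032, 7.222241280105832, 7),
        ("zero", 10.0, 5.0, 1.0, 5.0, 5),
    ],
)
def test_predict_shelf_life_closed_forms(order, q0, qe, k, t_s, reported):
    est = sk.predict_shelf_life(order, q0, qe, k)
    assert est.t_s_weeks == pytest.approx(t_s, rel=1e-12)
    assert est.reported_weeks == reported


def test_estimate_is_consistent_with_the_forward_model():
    est = sk.predict_shelf_life("first", 6.3, 5.0, 0.028)
    assert sk.predict_quality("first", est.k, est.q0, est.t_s_weeks) == pytest.approx(
        est.qe, abs=1e-9
    )


def test_already_rejected_product_has_zero_shelf_life():
    est = sk.predict_shelf_life("first", 5.0, 5.0, 0.02)
    assert est.t_s_weeks == 0.0 and est.already_rejected


def test_predict_shelf_life_rejects_nonpositive_rate():
    with pytest.raises(DomainError):
        sk.predict_shelf_life("first", 6.3, 5.0, 0.0)


def test_rounding_policy_nearest():
    est = sk.predict_shelf_life("first", 6.3, 5.0, 0.016, rounding="nearest")
    assert est.reported_weeks == 14
    est = sk.predict_shelf_life("zero", 6.3, 5.0, 0.49, rounding="nearest")
    assert est.reported_weeks == 3  # t_s ≈ 2.65


@given(
    q0=st.floats(5.5, 9.0),
    qe=st.floats(1.0, 5.0),
    k=st.floats(1e-3, 0.5),
    dk=st.floats(1e-3, 0.5),
    dq=st.floats(0.1, 2.0),
)
@pytest.mark.parametrize("order", ["zero", "first"])
def test_shelf_life_monotonicity(order, q0, qe, k, dk, dq):
    base = sk.predict_shelf_life(order, q0, qe, k).t_s_weeks
    assert sk.predict_shelf_life(order, q0, qe, k + dk).t_s_weeks < base
    assert sk.predict_shelf_life(order, q0 + dq, qe, k).t_s_weeks > base
    if qe + dq < q0:
        assert sk.predict_shelf_life(order, q0, qe + dq, k).t_s_weeks < base
    forward = sk.predict_quality(order, k, q0, base)
    assert forward == pytest.approx(qe, abs=1e-9)


# --------------------------------------------------------------------------
# experimental shelf life from censored panels

def _color(sensory, packaging, temp):
    return sensory.get("color_acceptance", sk.StorageCondition(packaging, temp))


@pytest.mark.parametrize(
    "packaging, temp, weeks, bound",
    [
        ("al_bag_n2", 4, 24, "greater_than"),
        ("al_bag_n2", 25, 15, "exact"),
        ("al_bag_n2", 35, 12, "exact"),
        ("al_bag_n2", 45, 3, "exact"),
        ("al_bag_air", 4, 24, "greater_than"),
        ("al_bag_air", 25, 15, "exact"),
        ("al_bag_air", 35, 3, "less_than"),
        ("al_bag_air", 45, 3, "less_than"),
        ("clear_plastic", 4, 21, "exact"),
        ("clear_plastic", 25, 9, "exact"),
        ("clear_plastic", 35, 3, "less_than"),
        ("clear_plastic", 45, 3, "less_than"),
    ],
)
def test_experimental_shelf_life_reproduces_every_observed_cell(
    sensory, packaging, temp, weeks, bound
):
    result = sk.experimental_shelf_life(_color(sensory, packaging, temp), 5.0)
    assert (result.weeks, result.bound) == (weeks, bound)


def test_score_of_exactly_five_passes(sensory):
    # air-packed bag at 4 °C ends week 24 on a mean of exactly 5.0: the
    # rejection rule is strictly "less than", so the series never fails
    series = _color(sensory, "al_bag_air", 4)
    assert series.observations[-1].value == 5.0
    assert sk.experimental_shelf_life(series, 5.0).bound == "greater_than"


def test_empty_series_is_an_error():
    series = sk.QualitySeries(
        "color_acceptance", sk.StorageCondition("al_bag_n2", 25.0), ()
    )
    with pytest.raises(InsufficientDataError):
        sk.experimental_shelf_life(series, 5.0)


@given(
    values=st.lists(st.floats(1.0, 9.0), min_size=1, max_size=10),
    lo=st.floats(2.0, 8.0),
    dt=st.floats(0.1, 2.0),
)
def test_raising_the_threshold_never_extends_shelf_life(values, lo, dt):
    series = make_series(3.0 * np.arange(1, len(values) + 1), values)
    low = sk.experimental_shelf_life(series, lo)
    high = sk.experimental_shelf_life(series, lo + dt)

    def effective(r):  # order bounds: below-lower < exact <= above-upper
        return {"less_than": r.weeks - 0.5, "exact": r.weeks, "greater_than": r.weeks + 0.5}[r.bound]

    assert effective(high) <= effective(low)
    if low.bound == "greater_than":
        assert all(v >= lo for v in values)


# --------------------------------------------------------------------------
# comparison table

def test_comparison_with_printed_rates_matches_reported_predictions(sensory):
    config = sk.AnalysisConfig(k_source="printed")
    table = sk.compare_actual_predicted(sensory, config)

    def row(pkg, temp):
        return table[
            (table["packaging"] == pkg) & (table["temperature_c"] == temp)
        ].iloc[0]

    assert row("clear_plastic", 25)["predicted_weeks"] == 8
    assert row("al_bag_n2", 35)["predicted_weeks"] == 7
    assert row("al_bag_air", 25)["predicted_weeks"] == 14
    assert row("al_bag_n2", 35)["actual_weeks"] == 12
    assert row("al_bag_air", 4)["actual_bound"] == "greater_than"
    assert set(table["order"].unique()) == {"first"}
    assert len(table) == 12


def test_comparison_with_fitted_rates_selects_first_order(sensory):
    table = sk.compare_actual_predicted(sensory, sk.AnalysisConfig(k_source="fitted"))
    assert len(table) == 12
    # every usable condition got a prediction consistent with its own k
    usable = table.dropna(subset=["t_s_raw"])
    assert (usable["t_s_raw"] > 0).all()
    for _, r in usable.iterrows():
        value = sk.predict_quality(r["order"], r["k"], 6.3, r["t_s_raw"])
        assert value == pytest.approx(5.0, abs=1e-9)


def test_comparison_empty_dataset_gives_empty_table():
    table = sk.compare_actual_predicted(sk.StudyDataset(), sk.AnalysisConfig())
    assert table.empty
    assert list(table.columns) == [
        "packaging", "temperature_c", "actual_weeks", "actual_bound",
        "predicted_weeks", "t_s_raw", "k", "k_source", "order",
    ]


def test_missing_printed_rate_reports_absent_not_fatal():
    ds = sk.StudyDataset()
    ds.add(
        make_series([3, 6, 9], [6.0, 5.5, 4.0], packaging="vacuum_pouch")
    )
    table = sk.compare_actual_predicted(ds, sk.AnalysisConfig(k_source="printed"))
    assert len(table) == 1
    assert math.isnan(table["predicted_weeks"].iloc[0])
    assert table["actual_weeks"].iloc[0] == 6  # experimental side still works


def test_arrhenius_rate_source_interpolates_per_packaging(sensory):
    table = sk.compare_actual_predicted(
        sensory, sk.AnalysisConfig(k_source="arrhenius")
    )
    sub = table[table["packaging"] == "clear_plastic"].sort_values("temperature_c")
    ks = sub["k"].to_numpy()
    assert (np.diff(ks) > 0).all()  # extrapolated k increases with temperature
    assert sub["t_s_raw"].is_monotonic_decreasing


def test_format_comparison_renders_bounds(sensory):
    text = sk.format_comparison(
        sk.compare_actual_predicted(sensory, sk.AnalysisConfig(k_source="printed"))
    )
    assert ">24" in text and "<3" in text
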