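"""Shelf-life prediction and experimental shelf-life determination.

Two routes to a shelf life:

* **Predicted** — invert the fitted kinetic model for the time t_s at which
  quality falls from its initial value Q0 to the rejection value Qe:

      zero order:   t_s = (Q0 − Qe) / k
      first order:  t_s = ln(Q0 / Qe) / k

  and report completed weeks (floor by default — a product is not "good for
  9 weeks" if it fails during the ninth).

* **Experimental** — scan the censored consumer-panel series: the product is
  rejected at the first session whose mean score drops *strictly below* the
  threshold (a mean of exactly 5.0 still passes, matching the convention
  that rejection means "less than 5"), and the experimental shelf life is
  the last passing session before that.  A series whose first session
  already fails yields only an upper bound ("<3 weeks"); one that never
  fails yields a lower bound (">24 weeks").

:func:`compare_actual_predicted` joins the two routes into the
actual-vs-predicted comparison table, with the rate constant taken per
condition from fresh kinetic fits, from a printed rate table, or from an
Arrhenius fit across temperatures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arrhenius import ArrheniusFit, RatePoint, fit_arrhenius, k_at
from .config import AnalysisConfig
from .dataset import QualitySeries, StorageCondition, StudyDataset
from .errors import DomainError, InsufficientDataError
from .kinetics import KineticFit, fit_both_orders, select_order

__all__ = [
    "ShelfLifeEstimate",
    "ExperimentalShelfLife",
    "predict_shelf_life",
    "experimental_shelf_life",
    "compare_actual_predicted",
    "format_comparison",
]

COMPARISON_COLUMNS = [
    "packaging",
    "temperature_c",
    "actual_weeks",
    "actual_bound",
    "predicted_weeks",
    "t_s_raw",
    "k",
    "k_source",
    "order",
]


@dataclass(frozen=True)
class ShelfLifeEstimate:
    """Model-predicted time to reach the rejection value."""

    t_s_weeks: float
    reported_weeks: int
    q0: float
    qe: float
    k: float
    k_source: str  # "fitted" | "printed" | "arrhenius"
    order: str  # "zero" | "first"
    already_rejected: bool = False


@dataclass(frozen=True)
class ExperimentalShelfLife:
    """Shelf life read off a censored sensory series.

    ``bound`` is ``exact`` when rejection was observed after at least one
    passing session, ``less_than`` when the very first session failed, and
    ``greater_than`` when no session failed before the series ended.
    """

    weeks: float
    bound: str  # "exact" | "greater_than" | "less_than"
    attribute_used: str


def _report(t_s: float, rounding: str) -> int:
    if rounding == "floor":
        return int(math.floor(t_s))
    if rounding == "nearest":
        return int(round(t_s))
    raise DomainError(f"unknown rounding policy {rounding!r}")


def predict_shelf_life(
    order: str,
    q0: float,
    qe: float,
    k: float,
    *,
    k_source: str = "fitted",
    rounding: str = "floor",
) -> ShelfLifeEstimate:
    """Invert the kinetic model for the time at which Q0 decays to Qe.

    ``qe >= q0`` means the product is already at or past rejection at time
    zero: the estimate is t_s = 0 with ``already_rejected=True`` rather than
    an error, so batch comparisons keep going.
    """
    if not (np.isfinite(k) and k > 0):
        raise DomainError(f"rate constant must be positive, got {k}")
    if order == "first" and (q0 <= 0 or qe <= 0):
        raise DomainError("first-order shelf life needs positive Q0 and Qe")
    if qe >= q0:
        return ShelfLifeEstimate(0.0, 0, q0, qe, k, k_source, order, True)
    if order == "zero":
        t_s = (q0 - qe) / k
    elif order == "first":
        t_s = math.log(q0 / qe) / k
    else:
        raise DomainError(f"unknown reaction order {order!r}")
    return ShelfLifeEstimate(t_s, _report(t_s, rounding), q0, qe, k, k_source, order)


def experimental_shelf_life(
    series: QualitySeries, threshold: float = 5.0
) -> ExperimentalShelfLife:
    """Shelf life observed in a sensory series under a strict threshold.

    Rejection happens at the first observation with value < threshold;
    shelf life is the time of the last observation before it.
    """
    obs = series.measured
    if not obs:
        raise InsufficientDataError(
            f"no observations in ({series.attribute}, {series.condition})"
        )
    for i, o in enumerate(obs):
        if o.value < threshold:
            if i == 0:
                return ExperimentalShelfLife(o.time_weeks, "less_than", series.attribute)
            return ExperimentalShelfLife(obs[i - 1].time_weeks, "exact", series.attribute)
    return ExperimentalShelfLife(obs[-1].time_weeks, "greater_than", series.attribute)


# --------------------------------------------------------------------------
# Actual-vs-predicted comparison

def _fitted_rate(
    dataset: StudyDataset, series: QualitySeries, config: AnalysisConfig
) -> KineticFit | None:
    s = series
    if config.include_baseline and s.attribute in dataset.baseline:
        s = s.with_baseline(dataset.baseline[s.attribute])
    try:
        fit = select_order(*fit_both_orders(s))
    except (InsufficientDataError, DomainError):
        return None
    return fit if fit.k > 0 else None


def _printed_rates(config: AnalysisConfig) -> pd.DataFrame:
    from .fixtures import builtin_fixture

    name = "table3_lstar_k" if config.attribute == "L_star" else "table4_color_k"
    return builtin_fixture(name)


def _rate_for(
    dataset: StudyDataset,
    condition: StorageCondition,
    config: AnalysisConfig,
    printed: pd.DataFrame | None,
    arrhenius_fits: dict[str, ArrheniusFit],
) -> tuple[float, str] | None:
    """(k, order) for one condition under the configured k source."""
    if config.k_source == "fitted":
        series = dataset.series.get((config.attribute, condition))
        if series is None:
            return None
        fit = _fitted_rate(dataset, series, config)
        return None if fit is None else (fit.k, fit.order)
    if config.k_source == "printed":
        rows = printed[
            (printed["order"] == "first")
            & (printed["packaging"] == condition.packaging)
            & (printed["temperature_c"] == condition.temperature_c)
        ]
        if rows.empty:
            return None
        return float(rows["k"].iloc[0]), "first"
    # arrhenius: extrapolate the printed first-order rates of this packaging
    fit = arrhenius_fits.get(condition.packaging)
    if fit is None:
        sub = printed[
            (printed["order"] == "first")
            & (printed["packaging"] == condition.packaging)
        ]
        if len(sub) < 3:
            return None
        fit = fit_arrhenius(
            RatePoint(t, k)
            for t, k in zip(sub["temperature_c"].astype(float), sub["k"].astype(float))
        )
        arrhenius_fits[condition.packaging] = fit
    return k_at(fit, condition.temperature_c), "first"


def compare_actual_predicted(
    dataset: StudyDataset, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """One row per condition: experimental vs predicted shelf life.

    A condition whose rate constant cannot be obtained (too few points for a
    fit, no printed entry) keeps its experimental columns and reports the
    prediction as absent rather than failing the whole table.
    """
    config = config or AnalysisConfig()
    printed = (
        _printed_rates(config) if config.k_source in ("printed", "arrhenius") else None
    )
    arrhenius_fits: dict[str, ArrheniusFit] = {}

    rows = []
    for condition in dataset.conditions(config.attribute):
        series = dataset.get(config.attribute, condition)
        try:
            actual = experimental_shelf_life(series, config.threshold)
            actual_weeks, actual_bound = actual.weeks, actual.bound
        except InsufficientDataError:
            actual_weeks, actual_bound = math.nan, "absent"

        rate = _rate_for(dataset, condition, config, printed, arrhenius_fits)
        if rate is None:
            predicted = t_s_raw = math.nan
            k_used, order = math.nan, ""
        else:
            k_used, order = rate
            est = predict_shelf_life(
                order,
                config.q0,
                config.qe,
                k_used,
                k_source=config.k_source,
                rounding=config.rounding,
            )
            predicted, t_s_raw = est.reported_weeks, est.t_s_weeks
        rows.append(
            {
                "packaging": condition.packaging,
                "temperature_c": condition.temperature_c,
                "actual_weeks": actual_weeks,
                "actual_bound": actual_bound,
                "predicted_weeks": predicted,
                "t_s_raw": t_s_raw,
                "k": k_used,
                "k_source": config.k_source,
                "order": order,
            }
        )
    return pd.DataFrame(rows, columns=COMPARISON_COLUMNS)


_BOUND_SYMBOL = {"exact": "", "greater_than": ">", "less_than": "<", "absent": "?"}


def format_comparison(table: pd.DataFrame) -> str:
    """Aligned plain-text report of a comparison table."""
    lines = [
        f"{'packaging':<14} {'temp °C':>7} {'actual':>8} {'predicted':>9} "
        f"{'t_s':>7} {'k':>9} {'order':>6}"
    ]
    for _, r in table.iterrows():
        actual = (
            "absent"
            if r["actual_bound"] == "absent"
            else f"{_BOUND_SYMBOL[r['actual_bound']]}{r['actual_weeks']:g}"
        )
        predicted = "absent" if pd.isna(r["predicted_weeks"]) else f"{int(r['predicted_weeks'])}"
        t_s = "" if pd.isna(r["t_s_raw"]) else f"{r['t_s_raw']:.2f}"
        k = "" if pd.isna(r["k"]) else f"{r['k']:.4g}"
        lines.append(
            f"{r['packaging']:<14} {r['temperature_c']:>7g} {actual:>8} "
            f"{predicted:>9} {t_s:>7} {k:>9} {r['order']:>6}"
        )
    return "\n".join(lines)
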