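"""Zero- and first-order degradation kinetics.

A quality attribute Q(t) that declines during storage is modelled either as

* zero order:  Q = Q0 − k·t          (linear loss, k in attribute-units/week)
* first order: ln(Q/Q0) = −k·t       (exponential loss, k in 1/week)

Both are fitted by ordinary least squares with a free intercept — value on
time for zero order, log-value on time for first order — so Q0 is estimated
rather than pinned to the measured baseline.  R² is the coefficient of
determination on the fitting scale (the log scale for first order).  The
better-fitting order, judged by R², is used for shelf-life prediction; ties
go to first order, the conventional model for browning-driven quality loss.

Below-detection observations never enter a fit.  Fits are unweighted: the
panel sd and replicate count are descriptive here, not weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import QualitySeries, StorageCondition
from .errors import (
    ConsistencyError,
    DegenerateDesignError,
    DomainError,
    InsufficientDataError,
)

__all__ = [
    "KineticFit",
    "fit_zero_order",
    "fit_first_order",
    "fit_both_orders",
    "select_order",
    "predict_quality",
]

MIN_POINTS = 3


@dataclass(frozen=True)
class KineticFit:
    """A fitted reaction order for one quality series.

    ``k`` is positive for a decaying series (k = −slope of the fitted line).
    ``q0_hat`` is the fitted initial value (exp(intercept) for first order).
    Provenance fields (``attribute``, ``condition``) identify the series the
    fit came from so mismatched fits cannot be compared by accident.
    """

    order: str  # "zero" | "first"
    k: float
    q0_hat: float
    r_squared: float
    n_points: int
    attribute: str | None = None
    condition: StorageCondition | None = None

    def __post_init__(self) -> None:
        if self.order not in ("zero", "first"):
            raise DomainError(f"unknown reaction order {self.order!r}")
        if not np.isfinite(self.k):
            raise DomainError("rate constant must be finite")
        if not 0.0 <= self.r_squared <= 1.0:
            raise DomainError(f"R² {self.r_squared} outside [0, 1]")
        if self.n_points < MIN_POINTS:
            raise DomainError(f"fit claims only {self.n_points} points")


def _prepare(series: QualitySeries) -> tuple[np.ndarray, np.ndarray]:
    t, q = series.arrays()
    if len(t) < MIN_POINTS:
        raise InsufficientDataError(
            f"kinetic fit needs ≥ {MIN_POINTS} uncensored observations, "
            f"got {len(t)} for ({series.attribute}, {series.condition})"
        )
    if np.ptp(t) == 0:
        raise DegenerateDesignError("all observations share one time point")
    return t, q


def _ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and R² of y on t; R² = 0 for a flat response."""
    if np.allclose(y, y[0]):
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(t, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def fit_zero_order(series: QualitySeries) -> KineticFit:
    """OLS of value on time: Q = q0_hat − k·t."""
    t, q = _prepare(series)
    slope, intercept, r2 = _ols(t, q)
    return KineticFit(
        order="zero",
        k=-slope,
        q0_hat=intercept,
        r_squared=r2,
        n_points=len(t),
        attribute=series.attribute,
        condition=series.condition,
    )


def fit_first_order(series: QualitySeries) -> KineticFit:
    """OLS of ln(value) on time: ln Q = ln q0_hat − k·t.

    Requires strictly positive values; R² is computed on the log scale,
    which is the scale actually fitted.
    """
    t, q = _prepare(series)
    bad = q <= 0
    if bad.any():
        week = t[bad][0]
        raise DomainError(
            f"first-order fit needs positive values; week {week:g} has "
            f"value {q[bad][0]:g}"
        )
    slope, intercept, r2 = _ols(t, np.log(q))
    return KineticFit(
        order="first",
        k=-slope,
        q0_hat=float(np.exp(intercept)),
        r_squared=r2,
        n_points=len(t),
        attribute=series.attribute,
        condition=series.condition,
    )


def fit_both_orders(series: QualitySeries) -> tuple[KineticFit, KineticFit]:
    """Convenience: (zero-order fit, first-order fit) of the same series."""
    return fit_zero_order(series), fit_first_order(series)


def select_order(zero: KineticFit, first: KineticFit) -> KineticFit:
    """Pick the order with the larger R²; an exact tie goes to first order."""
    if zero.order == first.order:
        raise ConsistencyError("select_order expects one fit of each order")
    if (zero.attribute, zero.condition, zero.n_points) != (
        first.attribute,
        first.condition,
        first.n_points,
    ):
        raise ConsistencyError(
            "fits come from different series: "
            f"({zero.attribute}, {zero.condition}, n={zero.n_points}) vs "
            f"({first.attribute}, {first.condition}, n={first.n_points})"
        )
    return zero if zero.r_squared > first.r_squared else first


def predict_quality(order: str, k: float, q0: float, t: float) -> float:
    """Model value at time t: q0 − k·t (zero) or q0·exp(−k·t) (first)."""
    if t < 0:
        raise DomainError("time must be non-negative")
    if order == "zero":
        return q0 - k * t
    if order == "first":
        if q0 <= 0:
            raise DomainError("first-order prediction needs q0 > 0")
        return q0 * float(np.exp(-k * t))
    raise DomainError(f"unknown reaction order {order!r}")
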