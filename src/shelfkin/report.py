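"""Tabular summaries over a whole study: fits per condition, Arrhenius per
packaging, and the combined reproduction report."""

from __future__ import annotations

import math

import pandas as pd

from .arrhenius import RatePoint, fit_arrhenius
from .config import AnalysisConfig
from .dataset import StudyDataset
from .errors import (
    DegenerateDesignError,
    DomainError,
    InsufficientDataError,
)
from .kinetics import fit_first_order, fit_zero_order
from .shelf_life import compare_actual_predicted, format_comparison

__all__ = ["fits_table", "arrhenius_table", "study_report"]

FIT_COLUMNS = [
    "order",
    "attribute",
    "packaging",
    "temperature_c",
    "k",
    "q0_hat",
    "r_squared",
    "n_points",
    "status",
]


def fits_table(
    dataset: StudyDataset,
    attribute: str,
    include_baseline: bool = True,
) -> pd.DataFrame:
    """Both kinetic orders fitted to every condition of one attribute.

    Conditions with too few points (or non-positive values on the log
    scale) appear with ``status`` ``insufficient``/``domain`` instead of
    aborting the table.
    """
    rows = []
    for condition in dataset.conditions(attribute):
        series = dataset.get(attribute, condition)
        if include_baseline and attribute in dataset.baseline:
            series = series.with_baseline(dataset.baseline[attribute])
        for order, fitter in (("zero", fit_zero_order), ("first", fit_first_order)):
            row = {
                "order": order,
                "attribute": attribute,
                "packaging": condition.packaging,
                "temperature_c": condition.temperature_c,
                "k": math.nan,
                "q0_hat": math.nan,
                "r_squared": math.nan,
                "n_points": len(series.measured),
                "status": "ok",
            }
            try:
                fit = fitter(series)
                row.update(
                    k=fit.k, q0_hat=fit.q0_hat, r_squared=fit.r_squared,
                    n_points=fit.n_points,
                )
            except InsufficientDataError:
                row["status"] = "insufficient"
            except (DomainError, DegenerateDesignError) as exc:
                row["status"] = "domain"
            rows.append(row)
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


def arrhenius_table(fits: pd.DataFrame, order: str = "first") -> pd.DataFrame:
    """Activation energy per packaging from a fits (or printed-rate) table.

    Accepts any frame with ``order``, ``packaging``, ``temperature_c`` and
    ``k`` columns; rows with missing or non-positive k are skipped, and a
    packaging with fewer than three usable temperatures is reported with
    ``status='insufficient'``.
    """
    rows = []
    sub = fits[(fits["order"] == order)]
    for packaging, grp in sub.groupby("packaging", sort=True):
        usable = grp[pd.to_numeric(grp["k"], errors="coerce") > 0]
        row = {
            "packaging": packaging,
            "order": order,
            "ea_kj_mol": math.nan,
            "ln_a": math.nan,
            "r_squared": math.nan,
            "n_temps": len(usable),
            "status": "ok",
        }
        try:
            fit = fit_arrhenius(
                RatePoint(float(t), float(k))
                for t, k in zip(usable["temperature_c"], usable["k"])
            )
            row.update(
                ea_kj_mol=fit.ea_kj_mol, ln_a=fit.ln_a,
                r_squared=fit.r_squared, n_temps=fit.n_temps,
            )
        except DegenerateDesignError:
            row["status"] = "insufficient"
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["packaging", "order", "ea_kj_mol", "ln_a", "r_squared", "n_temps", "status"],
    )


def study_report(dataset: StudyDataset, config: AnalysisConfig | None = None) -> str:
    """Plain-text reproduction report: fits, activation energies, and the
    actual-vs-predicted shelf-life comparison."""
    config = config or AnalysisConfig()
    fits = fits_table(dataset, config.attribute, config.include_baseline)
    arr = arrhenius_table(fits)
    comparison = compare_actual_predicted(dataset, config)

    parts = [
        f"Attribute: {config.attribute}   Q0 = {config.q0:g}   "
        f"Qe = {config.qe:g}   k source: {config.k_source}",
        "",
        "Kinetic fits (per condition)",
        fits.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        "",
        "Arrhenius fits (per packaging, first order)",
        arr.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        "",
        "Shelf life: actual vs predicted (weeks)",
        format_comparison(comparison),
    ]
    return "\n".join(parts)
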