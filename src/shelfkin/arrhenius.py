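"""Arrhenius temperature dependence of degradation rate constants.

The Arrhenius equation k = A·exp(−Ea / (R·T)) linearises as

    ln k = ln A − (Ea / R) · (1/T)

with T in kelvin, so the activation energy Ea follows from an ordinary
least-squares fit of ln k on 1/T across storage temperatures: Ea = −slope·R.
A larger Ea means the degradation reaction accelerates more strongly with
heat — the quantity that makes accelerated storage trials extrapolable back
to ambient and chill temperatures.

Temperatures enter and leave this module in degrees Celsius; the Kelvin
conversion (T + 273.15) happens here and nowhere else in the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, DomainError

__all__ = ["R_GAS", "KELVIN_OFFSET", "RatePoint", "ArrheniusFit", "fit_arrhenius", "k_at"]

#: Molar gas constant, J/(mol·K).
R_GAS = 8.314

KELVIN_OFFSET = 273.15

MIN_TEMPS = 3


@dataclass(frozen=True)
class RatePoint:
    """A rate constant observed (or fitted) at one storage temperature."""

    temperature_c: float
    k: float

    def __post_init__(self) -> None:
        if not self.temperature_c > -KELVIN_OFFSET:
            raise DomainError("temperature at or below absolute zero")
        if not (np.isfinite(self.k) and self.k > 0):
            raise DomainError(f"rate constant must be positive, got {self.k}")


@dataclass(frozen=True)
class ArrheniusFit:
    """ln k vs 1/T regression: activation energy and pre-exponential term."""

    ea_kj_mol: float
    ln_a: float
    r_squared: float
    n_temps: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.ea_kj_mol):
            raise DomainError("activation energy must be finite")
        if self.n_temps < MIN_TEMPS:
            raise DomainError(f"fit claims only {self.n_temps} temperatures")


def fit_arrhenius(points: Sequence[RatePoint] | Iterable[RatePoint]) -> ArrheniusFit:
    """OLS of ln k on 1/T (kelvin) over ≥ 3 distinct temperatures.

    Ea (kJ/mol) = −slope · R / 1000; ln A is the intercept, in the same
    (log-)units as the supplied rate constants.
    """
    points = list(points)
    temps_k = np.array([p.temperature_c + KELVIN_OFFSET for p in points])
    if len(np.unique(temps_k)) < MIN_TEMPS:
        raise DegenerateDesignError(
            f"Arrhenius fit needs ≥ {MIN_TEMPS} distinct temperatures, "
            f"got {len(np.unique(temps_k))}"
        )
    ln_k = np.log([p.k for p in points])
    res = stats.linregress(1.0 / temps_k, ln_k)
    return ArrheniusFit(
        ea_kj_mol=float(-res.slope * R_GAS / 1000.0),
        ln_a=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_temps=len(np.unique(temps_k)),
    )


def k_at(fit: ArrheniusFit, temperature_c: float) -> float:
    """Rate constant the fitted Arrhenius law implies at a temperature.

    k(T) = exp(ln A − Ea·1000 / (R·T_kelvin)); strictly increasing in
    temperature whenever Ea > 0.
    """
    if not temperature_c > -KELVIN_OFFSET:
        raise DomainError("temperature at or below absolute zero")
    t_kelvin = temperature_c + KELVIN_OFFSET
    return float(np.exp(fit.ln_a - fit.ea_kj_mol * 1000.0 / (R_GAS * t_kelvin)))
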