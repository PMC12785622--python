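"""Synthetic storage studies with the structure the analysis assumes.

Generators for three layers of the pipeline:

* :func:`generate_decay_series` — an instrumental-style quality series:
  zero- or first-order decay from a known Q0 with additive Gaussian
  measurement noise, per storage temperature.
* :func:`generate_panel_study` — a consumer-panel study: at each session a
  panel of ``n_consumers`` scores the product on the 9-point hedonic scale
  (individual scores ~ Normal(model mean, consumer_sd), clipped to [1, 9]
  and rounded to whole points, as real ballots are), and the session mean ±
  sd is recorded; once a session mean falls strictly below the rejection
  threshold, later sessions are censored exactly as the analysis side
  censors them.
* :func:`generate_arrhenius_study` — an exact Arrhenius family of rate
  constants k(T) = k_ref · exp(−Ea/R · (1/T − 1/T_ref)).

All randomness flows from ``numpy.random.default_rng`` seeded by the
scenario seed (spawned per temperature), so identical scenarios produce
byte-identical CSV output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .arrhenius import KELVIN_OFFSET, R_GAS, RatePoint
from .dataset import (
    QualityObservation,
    QualitySeries,
    StorageCondition,
    StudyDataset,
)
from .errors import DomainError, FixtureLookupError
from .kinetics import predict_quality

__all__ = [
    "DecayScenario",
    "PanelScenario",
    "generate_decay_series",
    "generate_panel_study",
    "generate_arrhenius_study",
    "rates_from_activation_energy",
    "scenario_from_yaml",
]


def rates_from_activation_energy(
    ea_kj_mol: float,
    k_ref: float,
    t_ref_c: float,
    temperatures_c: Sequence[float],
) -> dict[float, float]:
    """Map temperature → k on the exact Arrhenius curve through (T_ref, k_ref)."""
    if ea_kj_mol < 0 or k_ref <= 0:
        raise DomainError("need ea_kj_mol >= 0 and k_ref > 0")
    t_ref = t_ref_c + KELVIN_OFFSET
    out = {}
    for t_c in temperatures_c:
        t = t_c + KELVIN_OFFSET
        out[float(t_c)] = float(
            k_ref * np.exp(-ea_kj_mol * 1000.0 / R_GAS * (1.0 / t - 1.0 / t_ref))
        )
    return out


@dataclass(frozen=True)
class DecayScenario:
    """Ground truth for an instrumental decay series at several temperatures."""

    order: str = "first"
    q0: float = 6.3
    k_by_temperature: Mapping[float, float] = field(
        default_factory=lambda: {4.0: 0.005, 25.0: 0.016, 35.0: 0.032, 45.0: 0.047}
    )
    noise_sd: float = 0.05
    times: tuple[float, ...] = tuple(range(0, 25, 3))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.order not in ("zero", "first"):
            raise DomainError(f"unknown order {self.order!r}")
        if any(k <= 0 for k in self.k_by_temperature.values()):
            raise DomainError("all rate constants must be positive")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")
        t = self.times
        if any(b <= a for a, b in zip(t, t[1:])):
            raise DomainError("times must be strictly increasing")


@dataclass(frozen=True)
class PanelScenario:
    """Ground truth for a consumer-panel acceptance study.

    Defaults mirror the accelerated-storage design this package analyses:
    50 consumers on the 9-point hedonic scale every 3 weeks for 24 weeks,
    between-consumer sd 1.5 points, rejection below a mean of 5.0, with
    censoring after the first rejected session.
    """

    decay: DecayScenario = field(default_factory=DecayScenario)
    n_consumers: int = 50
    consumer_sd: float = 1.5
    threshold: float = 5.0
    censor_after_rejection: bool = True
    attribute: str = "color_acceptance"
    packaging: str = "synthetic_bag"

    def __post_init__(self) -> None:
        if self.n_consumers < 1:
            raise DomainError("need at least one consumer")
        if self.consumer_sd < 0:
            raise DomainError("consumer_sd must be non-negative")


def _rng_for(seed: int, temperature_c: float) -> np.random.Generator:
    # independent, reproducible stream per (seed, temperature)
    return np.random.default_rng([int(seed), int(round(temperature_c * 100))])


def _mean_at(scenario: DecayScenario, temperature_c: float, t: float) -> float:
    k = dict(scenario.k_by_temperature).get(float(temperature_c))
    if k is None:
        raise FixtureLookupError(
            f"temperature {temperature_c} °C not in scenario map "
            f"{sorted(scenario.k_by_temperature)}"
        )
    return predict_quality(scenario.order, k, scenario.q0, t)


def generate_decay_series(
    scenario: DecayScenario, temperature_c: float, attribute: str = "L_star",
    packaging: str = "synthetic_bag",
) -> QualitySeries:
    """Model curve plus Gaussian noise at one of the scenario's temperatures."""
    rng = _rng_for(scenario.seed, temperature_c)
    obs = []
    for t in scenario.times:
        mean = _mean_at(scenario, temperature_c, t)
        value = mean + rng.normal(0.0, scenario.noise_sd) if scenario.noise_sd else mean
        obs.append(QualityObservation(float(t), float(value)))
    return QualitySeries(
        attribute=attribute,
        condition=StorageCondition(packaging, float(temperature_c)),
        observations=tuple(obs),
    )


def generate_panel_study(scenario: PanelScenario) -> StudyDataset:
    """Simulated hedonic panel at every scenario temperature.

    Per session, ``n_consumers`` integer ballots are drawn around the decay
    model's mean, so recorded session means show the same ≈0.02 granularity
    as real panel tables.  The week-0 session seeds the dataset's baseline
    map; sessions strictly after the first rejected one are censored when
    ``censor_after_rejection`` is set.
    """
    dataset = StudyDataset()
    decay = scenario.decay
    for temperature_c in sorted(decay.k_by_temperature):
        rng = _rng_for(decay.seed, temperature_c)
        obs: list[QualityObservation] = []
        terminated = False
        for t in decay.times:
            mean = _mean_at(decay, temperature_c, t)
            if scenario.consumer_sd == 0:
                scores = np.full(scenario.n_consumers, round(mean))
            else:
                scores = np.clip(
                    np.round(rng.normal(mean, scenario.consumer_sd, scenario.n_consumers)),
                    1,
                    9,
                )
            session_mean = float(scores.mean())
            session_sd = float(scores.std(ddof=1)) if scenario.n_consumers > 1 else 0.0
            obs.append(
                QualityObservation(
                    float(t), session_mean, sd=session_sd, n=scenario.n_consumers
                )
            )
            if scenario.censor_after_rejection and session_mean < scenario.threshold:
                terminated = True
                break
        dataset.add(
            QualitySeries(
                attribute=scenario.attribute,
                condition=StorageCondition(scenario.packaging, float(temperature_c)),
                observations=tuple(obs),
                terminated_early=terminated,
            )
        )
    dataset.baseline[scenario.attribute] = decay.q0
    return dataset


def generate_arrhenius_study(
    ea_kj_mol: float,
    k_ref: float,
    t_ref_c: float,
    temperatures_c: Sequence[float],
) -> list[RatePoint]:
    """Exact Arrhenius rate family — no noise, for round-trip checks."""
    rates = rates_from_activation_energy(ea_kj_mol, k_ref, t_ref_c, temperatures_c)
    return [RatePoint(t_c, rates[float(t_c)]) for t_c in temperatures_c]


# --------------------------------------------------------------------------
# Scenario configuration files (key-value YAML)

_PANEL_KEYS = {
    "order",
    "q0",
    "k_by_temperature",
    "noise_sd",
    "times",
    "seed",
    "n_consumers",
    "consumer_sd",
    "threshold",
    "censor_after_rejection",
    "attribute",
    "packaging",
}


def scenario_from_yaml(path: str | Path, seed: int | None = None) -> PanelScenario:
    """Build a :class:`PanelScenario` from a flat key-value YAML file.

    Recognised keys are the fields of :class:`DecayScenario` and
    :class:`PanelScenario`; ``k_by_temperature`` is a °C → k mapping.  An
    explicit ``seed`` argument overrides the file.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise DomainError(f"{path}: scenario file must be a key-value mapping")
    unknown = set(raw) - _PANEL_KEYS
    if unknown:
        raise DomainError(f"{path}: unknown scenario keys {sorted(unknown)}")
    if seed is not None:
        raw["seed"] = seed
    decay_kwargs = {}
    for key in ("order", "q0", "noise_sd", "seed"):
        if key in raw:
            decay_kwargs[key] = raw.pop(key)
    if "k_by_temperature" in raw:
        decay_kwargs["k_by_temperature"] = {
            float(t): float(k) for t, k in raw.pop("k_by_temperature").items()
        }
    if "times" in raw:
        decay_kwargs["times"] = tuple(float(t) for t in raw.pop("times"))
    return PanelScenario(decay=DecayScenario(**decay_kwargs), **raw)
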