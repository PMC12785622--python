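"""Storage-study data model and CSV input/output.

The central object is a :class:`StudyDataset`: a collection of
:class:`QualitySeries`, each an ordered time series of one quality attribute
(a hedonic acceptance score, an instrumental colour coordinate, water
activity, moisture, hardness, or a microbial count) measured under one
:class:`StorageCondition` (packaging type × storage temperature).

Series may be *censored*: in an accelerated storage study, measurement stops
once the product is rejected by the consumer panel, so a series that ends
early with ``terminated_early=True`` carries only a lower bound on shelf
life.  Microbial counts may additionally be *below detection* ("<limit"
records), which are kept as qualified records and excluded from maxima and
kinetic fits.

The on-disk form is a tidy UTF-8 CSV with columns::

    attribute, packaging, temperature_c, time_weeks, value, sd, n, qualifier, terminated

``qualifier`` is empty for measured values and ``lt`` for below-detection
records (whose ``value`` is then the detection limit).  An empty ``value``
marks a missing measurement; such rows are dropped on load, but a truthy
``terminated`` flag anywhere in a series marks it as ended by rejection.
Temperatures are stored in degrees Celsius throughout the data layer; the
Kelvin conversion happens only in :mod:`shelfkin.arrhenius`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    DuplicationError,
    FixtureLookupError,
    ParseError,
)

__all__ = [
    "ABSOLUTE_ZERO_C",
    "SENSORY_ATTRIBUTES",
    "MICROBIAL_ATTRIBUTES",
    "StorageCondition",
    "QualityObservation",
    "QualitySeries",
    "MicrobialCount",
    "StudyDataset",
    "load_quality_csv",
    "write_quality_csv",
    "parse_count",
    "format_count",
    "max_measured_count",
    "delta_e",
]

ABSOLUTE_ZERO_C = -273.15

#: Hedonic attributes scored on the 9-point scale (1 = dislike extremely,
#: 9 = like extremely); a panel mean below the rejection threshold ends the
#: product's shelf life.
SENSORY_ATTRIBUTES = frozenset(
    {"color_acceptance", "overall_acceptance", "flavor_acceptance"}
)

#: Plate-count attributes (cfu/g) that may carry "<limit" qualifiers.
MICROBIAL_ATTRIBUTES = frozenset({"tbc", "ymc"})

#: Canonical packaging labels used by the packaged study fixtures.  Free-text
#: labels are accepted for new studies.
KNOWN_PACKAGING = ("al_bag_n2", "al_bag_air", "clear_plastic")

CSV_COLUMNS = [
    "attribute",
    "packaging",
    "temperature_c",
    "time_weeks",
    "value",
    "sd",
    "n",
    "qualifier",
    "terminated",
]


@dataclass(frozen=True, order=True)
class StorageCondition:
    """One experimental arm: a packaging type stored at one temperature."""

    packaging: str
    temperature_c: float

    def __post_init__(self) -> None:
        if not self.packaging:
            raise DomainError("packaging label must be non-empty")
        if not self.temperature_c > ABSOLUTE_ZERO_C:
            raise DomainError(
                f"temperature {self.temperature_c} °C is at or below absolute zero"
            )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.packaging} @ {self.temperature_c:g} °C"


@dataclass(frozen=True)
class QualityObservation:
    """One measurement: value (mean over replicates) at a storage time.

    ``below_detection=True`` marks a qualified record whose ``value`` is the
    detection limit, not a measurement.
    """

    time_weeks: float
    value: float
    sd: float | None = None
    n: int | None = None
    below_detection: bool = False

    def __post_init__(self) -> None:
        if self.time_weeks < 0:
            raise DomainError(f"negative storage time {self.time_weeks}")
        if self.sd is not None and self.sd < 0:
            raise DomainError(f"negative sd {self.sd}")
        if self.n is not None and self.n < 1:
            raise DomainError(f"replicate count {self.n} < 1")


@dataclass(frozen=True)
class QualitySeries:
    """Ordered, possibly censored series of one attribute under one condition."""

    attribute: str
    condition: StorageCondition
    observations: tuple[QualityObservation, ...]
    terminated_early: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))
        times = [o.time_weeks for o in self.observations]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise DomainError(
                f"observation times must be strictly increasing, got {times}"
            )

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def measured(self) -> tuple[QualityObservation, ...]:
        """Observations excluding below-detection records."""
        return tuple(o for o in self.observations if not o.below_detection)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and values of the measured observations, as float arrays."""
        obs = self.measured
        t = np.array([o.time_weeks for o in obs], dtype=float)
        q = np.array([o.value for o in obs], dtype=float)
        return t, q

    def with_baseline(
        self, value: float, sd: float | None = None, n: int | None = None
    ) -> "QualitySeries":
        """Return a copy with a week-0 observation prepended.

        No-op if the series already starts at week 0.
        """
        if self.observations and self.observations[0].time_weeks == 0:
            return self
        obs = (QualityObservation(0.0, value, sd, n),) + self.observations
        return replace(self, observations=obs)


@dataclass(frozen=True)
class MicrobialCount:
    """A plate count in cfu/g, either measured or below a detection limit."""

    value: float | None
    qualifier: str  # "measured" | "below_detection"
    limit: float | None = None

    def __post_init__(self) -> None:
        if self.qualifier == "measured":
            if self.value is None or self.value <= 0:
                raise DomainError("measured count must be positive")
        elif self.qualifier == "below_detection":
            if self.limit is None or self.limit <= 0:
                raise DomainError("detection limit must be positive")
        else:
            raise DomainError(f"unknown qualifier {self.qualifier!r}")


@dataclass
class StudyDataset:
    """All series of one storage study, keyed by (attribute, condition)."""

    series: dict[tuple[str, StorageCondition], QualitySeries] = field(
        default_factory=dict
    )
    baseline: dict[str, float] = field(default_factory=dict)

    def add(self, s: QualitySeries) -> None:
        key = (s.attribute, s.condition)
        if key in self.series:
            raise DuplicationError(f"duplicate series for {key}")
        self.series[key] = s

    def get(self, attribute: str, condition: StorageCondition) -> QualitySeries:
        try:
            return self.series[(attribute, condition)]
        except KeyError:
            raise FixtureLookupError(
                f"no series for ({attribute}, {condition})"
            ) from None

    def select(
        self, attribute: str | None = None, packaging: str | None = None
    ) -> list[QualitySeries]:
        """All series matching the given attribute and/or packaging label."""
        out = []
        for (attr, cond), s in sorted(self.series.items()):
            if attribute is not None and attr != attribute:
                continue
            if packaging is not None and cond.packaging != packaging:
                continue
            out.append(s)
        return out

    def conditions(self, attribute: str) -> list[StorageCondition]:
        return sorted(
            cond for (attr, cond) in self.series if attr == attribute
        )

    def __len__(self) -> int:
        return len(self.series)


# --------------------------------------------------------------------------
# Detection-limit parsing

_COUNT_RE = re.compile(r"^\s*(<)?\s*([^<\s].*?)\s*$")


def parse_count(text: str) -> MicrobialCount:
    """Parse a plate-count cell such as ``"65"`` or ``"<2.5e-1"``.

    A leading ``<`` marks a below-detection record whose payload is the
    detection limit.  Scientific notation is accepted.  Unqualified
    non-positive counts are rejected: a plate either grew colonies (count
    > 0) or the count is below the detection limit.
    """
    m = _COUNT_RE.match(text)
    if not m:
        raise ParseError(f"cannot parse count {text!r}")
    censored, payload = m.group(1) is not None, m.group(2)
    try:
        number = float(payload)
    except ValueError:
        raise ParseError(f"non-numeric count payload {payload!r}") from None
    if not math.isfinite(number) or number <= 0:
        raise ParseError(
            f"count must be positive or qualified with '<', got {text!r}"
        )
    if censored:
        return MicrobialCount(None, "below_detection", limit=number)
    return MicrobialCount(number, "measured")


def format_count(count: MicrobialCount) -> str:
    """Inverse of :func:`parse_count`."""
    if count.qualifier == "below_detection":
        return f"<{count.limit:g}"
    return f"{count.value:g}"


def max_measured_count(
    dataset: StudyDataset, attribute: str, packaging: str
) -> MicrobialCount:
    """Largest measured count of one attribute/packaging across all
    temperatures and weeks.

    Below-detection records do not compete with measured values; only if
    every record is censored does the result carry the largest detection
    limit (still qualified).
    """
    series = dataset.select(attribute=attribute, packaging=packaging)
    if not series:
        raise FixtureLookupError(
            f"no {attribute} series for packaging {packaging!r}"
        )
    best_value = -math.inf
    best_limit = -math.inf
    for s in series:
        for o in s.observations:
            if o.below_detection:
                best_limit = max(best_limit, o.value)
            else:
                best_value = max(best_value, o.value)
    if best_value > -math.inf:
        return MicrobialCount(best_value, "measured")
    return MicrobialCount(None, "below_detection", limit=best_limit)


# --------------------------------------------------------------------------
# Colour difference

def delta_e(lab: Sequence[float], ref: Sequence[float]) -> float:
    """Total colour difference ΔE*ab between two CIELAB triples (CIE76).

    Euclidean distance sqrt(ΔL*² + Δa*² + Δb*²); symmetric, non-negative,
    zero iff the triples coincide.  The conventional reference is the week-0
    measurement of the same storage condition.
    """
    lab = np.asarray(lab, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if lab.shape != (3,) or ref.shape != (3,):
        raise DomainError("delta_e expects two L*/a*/b* triples")
    if not (np.isfinite(lab).all() and np.isfinite(ref).all()):
        raise DomainError("non-finite colour coordinates")
    return float(np.linalg.norm(lab - ref))


# --------------------------------------------------------------------------
# CSV input/output

def _parse_cell(raw, line_no: int, what: str, caster=float):
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return None
    try:
        return caster(raw)
    except (TypeError, ValueError):
        raise ParseError(f"line {line_no}: bad {what} value {raw!r}") from None


def load_quality_csv(path: str | Path) -> StudyDataset:
    """Read a tidy storage-study CSV into a :class:`StudyDataset`.

    Rows are grouped by (attribute, packaging, temperature) into series and
    sorted by week.  Rows with an empty ``value`` are dropped; a truthy
    ``terminated`` flag on any row of a group marks the series as ended by
    consumer rejection.  ``qualifier == 'lt'`` rows become below-detection
    observations whose value is the detection limit.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file (header required)") from None
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")

    groups: dict[tuple[str, StorageCondition], list[QualityObservation]] = {}
    terminated: set[tuple[str, StorageCondition]] = set()
    seen: set[tuple[str, StorageCondition, float]] = set()

    for idx, row in frame.iterrows():
        line_no = idx + 2  # 1-based, after header
        attribute = row["attribute"].strip()
        packaging = row["packaging"].strip()
        if not attribute or not packaging:
            raise ParseError(f"line {line_no}: attribute/packaging must be non-empty")
        temp = _parse_cell(row["temperature_c"], line_no, "temperature_c")
        week = _parse_cell(row["time_weeks"], line_no, "time_weeks")
        if temp is None or week is None:
            raise ParseError(f"line {line_no}: temperature_c and time_weeks required")
        condition = StorageCondition(packaging, temp)
        key = (attribute, condition)

        flag = row["terminated"].strip().lower()
        if flag not in {"", "0", "1", "true", "false"}:
            raise ParseError(f"line {line_no}: bad terminated flag {flag!r}")
        if flag in {"1", "true"}:
            terminated.add(key)

        value = _parse_cell(row["value"], line_no, "value")
        if value is None:
            # missing measurement: dropped, but flag above is retained
            groups.setdefault(key, [])
            continue

        dup_key = (attribute, condition, week)
        if dup_key in seen:
            raise DuplicationError(
                f"line {line_no}: duplicate observation for "
                f"({attribute}, {condition}, week {week:g})"
            )
        seen.add(dup_key)

        qualifier = row["qualifier"].strip().lower()
        if qualifier not in {"", "lt"}:
            raise ParseError(f"line {line_no}: unknown qualifier {qualifier!r}")
        obs = QualityObservation(
            time_weeks=week,
            value=value,
            sd=_parse_cell(row["sd"], line_no, "sd"),
            n=_parse_cell(row["n"], line_no, "n", caster=lambda v: int(float(v))),
            below_detection=qualifier == "lt",
        )
        groups.setdefault(key, []).append(obs)

    dataset = StudyDataset()
    for key, obs in groups.items():
        attribute, condition = key
        obs.sort(key=lambda o: o.time_weeks)
        dataset.add(
            QualitySeries(
                attribute=attribute,
                condition=condition,
                observations=tuple(obs),
                terminated_early=key in terminated,
            )
        )
    return dataset


def write_quality_csv(dataset: StudyDataset, path: str | Path) -> None:
    """Write a dataset in the tidy CSV dialect read by :func:`load_quality_csv`.

    The ``terminated`` flag of a censored series is carried on its last
    observation row, so a load/write cycle preserves every series, flag and
    qualifier.
    """
    rows = []
    for (attribute, condition), s in sorted(dataset.series.items()):
        for i, o in enumerate(s.observations):
            last = i == len(s.observations) - 1
            rows.append(
                {
                    "attribute": attribute,
                    "packaging": condition.packaging,
                    "temperature_c": f"{condition.temperature_c:g}",
                    "time_weeks": f"{o.time_weeks:g}",
                    "value": f"{o.value:g}",
                    "sd": "" if o.sd is None else f"{o.sd:g}",
                    "n": "" if o.n is None else str(o.n),
                    "qualifier": "lt" if o.below_detection else "",
                    "terminated": "1" if (last and s.terminated_early) else "",
                }
            )
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    frame.to_csv(path, index=False)
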