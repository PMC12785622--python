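"""Analysis settings shared by the shelf-life pipeline and the CLI.

Defaults are the study's own values: an initial colour-acceptance score
Q0 = 6.3, a consumer rejection point Qe = 5.0 (a mean hedonic score below
5 — "neither like nor dislike" — ends shelf life), shelf-life decisions
driven by colour acceptance, and shelf lives reported as completed weeks
(floor), the conservative convention.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .errors import DomainError

__all__ = ["AnalysisConfig"]

K_SOURCES = ("fitted", "printed", "arrhenius")
ROUNDINGS = ("floor", "nearest")


@dataclass
class AnalysisConfig:
    q0: float = 6.3
    qe: float = 5.0
    threshold: float = 5.0
    k_source: str = "fitted"
    include_baseline: bool = True
    rounding: str = "floor"
    attribute: str = "color_acceptance"

    def __post_init__(self) -> None:
        if not self.qe < self.q0:
            raise DomainError(f"qe ({self.qe}) must be below q0 ({self.q0})")
        if self.k_source not in K_SOURCES:
            raise DomainError(
                f"k_source must be one of {K_SOURCES}, got {self.k_source!r}"
            )
        if self.rounding not in ROUNDINGS:
            raise DomainError(
                f"rounding must be one of {ROUNDINGS}, got {self.rounding!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load settings from a YAML mapping; keyword overrides win.

        Unknown keys are rejected by name so a typo in a config file fails
        loudly instead of silently using a default.
        """
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise DomainError(f"{path}: config must be a key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DomainError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)
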