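"""Symptomatic intracerebral haemorrhage (SICH) risk for treated patients.

SICH — an NIHSS worsening of >= 4 within 24 h with a PH2 haematoma — is
too rare in single-country registries to model by regression, so risk is
assigned by a configurable point score derived from the wider monitoring
registry: points accumulate over antiplatelet use, NIHSS band, glucose,
age, SBP, weight, onset-to-treatment time and hypertension history, and a
risk table maps the total to a probability.

Post-SICH outcomes follow a fixed split (6 % independent, 33 % dependent,
61 % dead).  The split is presentational only: the three-state model's
death probability already absorbs haemorrhage deaths in treated patients,
so the overlay is never added to the totals.

Haemorrhage risk in *untreated* patients is deliberately not modelled
(insufficient data); report it as not applicable, never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional, Sequence

from .errors import ConfigurationError
from .model_core import PatientProfile, load_bundled_json

__all__ = [
    "SichScoreConfig",
    "SichOutcomeSplit",
    "SichOverlay",
    "default_sich_config",
    "sich_score",
    "sich_probability",
    "sich_outcome_overlay",
]


@dataclass(frozen=True)
class SichOutcomeSplit:
    """Outcome distribution conditional on suffering a SICH."""

    p_independent_given_sich: float = 0.06
    p_dependent_given_sich: float = 0.33
    p_dead_given_sich: float = 0.61

    def __post_init__(self):
        total = (
            self.p_independent_given_sich
            + self.p_dependent_given_sich
            + self.p_dead_given_sich
        )
        if abs(total - 1.0) > 1e-12:
            raise ConfigurationError(f"SICH outcome split sums to {total}, not 1")


@dataclass(frozen=True)
class SichOverlay:
    """Within-SICH decomposition; components sum to p_sich, not to 1."""

    independent: float
    dependent: float
    dead: float

    def as_tuple(self):
        return (self.independent, self.dependent, self.dead)


def _condition_met(profile: PatientProfile, cond: Mapping) -> bool:
    value = profile.require(cond["field"])
    op = cond["op"]
    if op == "ge":
        return value >= cond["value"]
    if op == "eq":
        return value == cond["value"]
    if op == "band":
        lo = cond.get("lo")
        hi = cond.get("hi")
        lo = -math.inf if lo is None else lo
        hi = math.inf if hi is None else hi
        return lo <= value <= hi
    raise ConfigurationError(f"unknown score condition operator {op!r}")


@dataclass(frozen=True)
class SichScoreConfig:
    """Point-score items plus the points -> probability risk table."""

    items: Sequence[Mapping]
    risk_table: Mapping[int, float]
    outcome_split: SichOutcomeSplit = field(default_factory=SichOutcomeSplit)
    name: str = "sich_score"

    def __post_init__(self):
        self._check_bands()
        classes = sorted(self.risk_table)
        risks = [self.risk_table[c] for c in classes]
        if any(not (0.0 <= r <= 1.0) for r in risks):
            raise ConfigurationError("risk table probabilities must lie in [0,1]")
        if any(b < a for a, b in zip(risks, risks[1:])):
            raise ConfigurationError("risk table must be non-decreasing in points")

    def _check_bands(self):
        by_field: dict = {}
        for item in self.items:
            for cond in item["conditions"]:
                if cond["op"] == "band":
                    lo = cond.get("lo")
                    hi = cond.get("hi")
                    by_field.setdefault(cond["field"], []).append(
                        (-math.inf if lo is None else lo, math.inf if hi is None else hi)
                    )
        for field_name, bands in by_field.items():
            bands.sort()
            for (lo1, hi1), (lo2, hi2) in zip(bands, bands[1:]):
                if lo2 <= hi1:
                    raise ConfigurationError(
                        f"overlapping {field_name} bands: [{lo1},{hi1}] and [{lo2},{hi2}]"
                    )

    @classmethod
    def from_dict(cls, d: Mapping) -> "SichScoreConfig":
        split = d.get("outcome_split")
        return cls(
            items=tuple(d["items"]),
            risk_table={int(k): float(v) for k, v in d["risk_table"].items()},
            outcome_split=SichOutcomeSplit(**split) if split else SichOutcomeSplit(),
            name=d.get("name", "sich_score"),
        )


@lru_cache(maxsize=None)
def default_sich_config() -> SichScoreConfig:
    return SichScoreConfig.from_dict(load_bundled_json("sich_score_v1.json"))


def sich_score(profile: PatientProfile, config: Optional[SichScoreConfig] = None) -> int:
    """Total points for one (validated, imputed) patient."""
    if config is None:
        config = default_sich_config()
    return sum(
        item["points"]
        for item in config.items
        if all(_condition_met(profile, c) for c in item["conditions"])
    )


def sich_probability(
    profile: PatientProfile, config: Optional[SichScoreConfig] = None
) -> float:
    """Risk-table lookup on the patient's point total (treated arm only)."""
    if config is None:
        config = default_sich_config()
    points = sich_score(profile, config)
    if points not in config.risk_table:
        raise ConfigurationError(
            f"points class {points} outside risk table "
            f"(classes {min(config.risk_table)}-{max(config.risk_table)})"
        )
    return config.risk_table[points]


def sich_outcome_overlay(
    p_sich: float, split: Optional[SichOutcomeSplit] = None
) -> SichOverlay:
    """Decompose a SICH risk into its expected outcome shares.

    For display only: these shares are already contained in the treated
    arm's three-state probabilities and must not be added to them.
    """
    if not (0.0 <= p_sich <= 1.0):
        raise ValueError(f"p_sich={p_sich} outside [0,1]")
    if split is None:
        split = SichOutcomeSplit()
    return SichOverlay(
        independent=p_sich * split.p_independent_given_sich,
        dependent=p_sich * split.p_dependent_given_sich,
        dead=p_sich * split.p_dead_given_sich,
    )
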