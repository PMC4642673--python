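"""One-way sensitivity sweeps and natural-frequency risk communication."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dam import predict_pair
from .errors import RangeViolationError
from .model_core import PatientProfile, PredictionPair, prepare_profile

__all__ = ["SweepResult", "one_way_sweep", "natural_frequencies", "SWEEPABLE_VARIABLES"]

#: Numeric fields a one-way sensitivity analysis may vary, with the
#: supported range of each (the model's validated ranges).
SWEEPABLE_VARIABLES = {
    "age": (18.0, 110.0),
    "sbp": (60.0, 200.0),
    "glucose": (1.0, 25.0),
    "nihss": (0.0, 42.0),
    "ott": (0.0, 270.0),
}


@dataclass(frozen=True)
class SweepResult:
    """Grid of decision forecasts as one input varies, all else held fixed."""

    variable: str
    grid: Sequence[float]
    pairs: Sequence[PredictionPair]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for value, pair in zip(self.grid, self.pairs):
            rows.append(
                {
                    self.variable: value,
                    "p_independent_untreated": pair.untreated.p_independent,
                    "p_independent_treated": pair.treated.p_independent,
                    "p_dead": pair.untreated.p_dead,
                    "p_sich": pair.p_sich,
                    "net_benefit": pair.net_benefit,
                }
            )
        return pd.DataFrame(rows)


def one_way_sweep(
    profile: PatientProfile, variable: str, grid: Sequence[float]
) -> SweepResult:
    """Evaluate the full decision forecast along a grid of one input.

    The grey-area reading of the result: the gap between the treated and
    untreated independence curves is the potential gain from treatment.
    """
    if variable not in SWEEPABLE_VARIABLES:
        raise ValueError(
            f"{variable!r} is not sweepable; choose one of "
            f"{sorted(SWEEPABLE_VARIABLES)}"
        )
    lo, hi = SWEEPABLE_VARIABLES[variable]
    grid = [float(v) for v in grid]
    for value in grid:
        if not (lo <= value <= hi):
            raise RangeViolationError(
                variable, value, f"sweep grid must stay within [{lo}, {hi}]"
            )
    pairs = [
        predict_pair(prepare_profile(profile.replace(**{variable: value})))
        for value in grid
    ]
    return SweepResult(variable=variable, grid=tuple(grid), pairs=tuple(pairs))


def _largest_remainder(probs: Sequence[float], denominator: int) -> list:
    """Round probabilities to integer counts summing exactly to the denominator.

    Hamilton apportionment: floor each share, then hand the remaining
    units to the largest fractional parts (ties broken by position, so
    the result is deterministic).
    """
    shares = np.asarray(probs, dtype=float) * denominator
    counts = np.floor(shares).astype(int)
    short = denominator - counts.sum()
    order = np.lexsort((np.arange(len(shares)), -(shares - np.floor(shares))))
    for i in order[:short]:
        counts[i] += 1
    return counts.tolist()


def natural_frequencies(pair: PredictionPair, denominator: int = 100) -> dict:
    """Express a forecast as counts per ``denominator`` patients.

    Each arm's three states are rounded by largest remainder so they sum
    exactly to the denominator; the treated arm additionally reports an
    expected SICH count (rounded to the nearest unit).
    """
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    out = {}
    for arm_name, dist in (("untreated", pair.untreated), ("treated", pair.treated)):
        ind, dep, dead = _largest_remainder(dist.as_tuple(), denominator)
        out[arm_name] = {"independent": ind, "dependent": dep, "dead": dead}
    out["treated"]["sich"] = int(np.floor(pair.p_sich * denominator + 0.5))
    out["denominator"] = denominator
    return out
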