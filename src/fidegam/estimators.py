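"""Comparator completeness measures: NPE and STE.

NPE is the observed richness divided by the first-order Jackknife
prediction (values in (0, 1]; high = well sampled).  STE is the terminal
secant slope of the accumulation curve (low = well sampled): with unit
record spacing it reduces to S(H) - S(H-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occurrence import UnitIncidence
from .sac import AccumulationCurve

__all__ = ["CompletenessScore", "jackknife1", "npe", "ste_slope", "MIN_RECORDS"]

#: completeness is only quantified for units with at least this many records
MIN_RECORDS = 3


class InsufficientDataError(ValueError):
    pass


@dataclass
class CompletenessScore:
    """One unit's completeness value under one method.

    ``method`` fixes the orientation: NPE is high for well-sampled
    units, STE and FIDEGAM are low for well-sampled units.
    """

    unit_id: str
    method: str  # "NPE" | "STE" | "FIDEGAM"
    value: float
    H: int
    S_obs: int
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("NPE", "STE", "FIDEGAM"):
            raise ValueError(f"unknown method {self.method!r}")


def jackknife1(inc: UnitIncidence) -> float:
    """First-order Jackknife richness estimate.

    S_obs + Q1 * (H-1)/H, with Q1 the number of species found in exactly
    one record (the classic incidence-based form).
    """
    if inc.H < 2:
        raise InsufficientDataError(f"unit {inc.unit_id}: H={inc.H} < 2")
    q1 = int((inc.species_record_counts == 1).sum())
    return inc.S_obs + q1 * (inc.H - 1) / inc.H


def npe(inc: UnitIncidence) -> CompletenessScore:
    """Observed / Jackknife-1 predicted richness."""
    if inc.H < MIN_RECORDS:
        raise InsufficientDataError(f"unit {inc.unit_id}: H={inc.H} < {MIN_RECORDS}")
    return CompletenessScore(
        unit_id=inc.unit_id,
        method="NPE",
        value=inc.S_obs / jackknife1(inc),
        H=inc.H,
        S_obs=inc.S_obs,
    )


def ste_slope(curve: AccumulationCurve) -> CompletenessScore:
    """Terminal secant slope (y_i - y_{i-1}) / (x_i - x_{i-1}) of a SAC."""
    if len(curve.n) < 2:
        raise InsufficientDataError(f"unit {curve.unit_id}: curve has < 2 points")
    if curve.H < MIN_RECORDS:
        raise InsufficientDataError(f"unit {curve.unit_id}: H={curve.H} < {MIN_RECORDS}")
    dy = float(curve.S_mean[-1] - curve.S_mean[-2])
    dx = float(curve.n[-1] - curve.n[-2])
    return CompletenessScore(
        unit_id=curve.unit_id,
        method="STE",
        value=dy / dx,
        H=curve.H,
        S_obs=int(round(curve.S_obs)),
    )


def scores_to_frame(scores: list[CompletenessScore]) -> pd.DataFrame:
    """Tidy export: unit_id, method, value, ci_low, ci_high, H, S_obs."""
    return pd.DataFrame(
        {
            "unit_id": [s.unit_id for s in scores],
            "method": [s.method for s in scores],
            "value": [s.value for s in scores],
            "ci_low": [np.nan if s.ci_low is None else s.ci_low for s in scores],
            "ci_high": [np.nan if s.ci_high is None else s.ci_high for s in scores],
            "H": [s.H for s in scores],
            "S_obs": [s.S_obs for s in scores],
        }
    )
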