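"""Species accumulation curves (sample-based rarefaction).

Two constructions are provided per sampling unit:

* :func:`sac_permutation` — the randomized curve: mean (and SD) of the
  cumulative number of distinct species over many uniformly random
  orderings of the unit's sampling records.
* :func:`mao_tau` / :func:`mao_tau_curve` — the analytic expectation of
  the same quantity (the Mao Tau sample-based rarefaction estimator),
  obtained from hypergeometric absence probabilities.

The permutation mean converges to the Mao Tau curve as the number of
permutations grows; the analytic curve is exact and deterministic, so it
is the default input for slope-based completeness measures.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .occurrence import UnitIncidence

__all__ = [
    "AccumulationCurve",
    "sac_permutation",
    "mao_tau",
    "mao_tau_curve",
    "unit_seed",
]


@dataclass
class AccumulationCurve:
    """Expected richness S(n) for n = 1..H accumulated records."""

    unit_id: str
    n: np.ndarray  # 1..H
    S_mean: np.ndarray
    S_sd: np.ndarray
    n_perm: int
    kind: str  # "permutation" | "mao_tau"

    @property
    def H(self) -> int:
        return int(self.n[-1])

    @property
    def S_obs(self) -> float:
        return float(self.S_mean[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit_id": self.unit_id,
                "n": self.n,
                "S_mean": self.S_mean,
                "S_sd": self.S_sd,
            }
        )


def unit_seed(root_seed: int, unit_id: str) -> np.random.SeedSequence:
    """Deterministic per-unit seed, independent of unit iteration order."""
    return np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, zlib.crc32(unit_id.encode())])


def sac_permutation(
    inc: UnitIncidence, n_perm: int = 1000, seed: int | np.random.SeedSequence = 0
) -> AccumulationCurve:
    """Randomized species accumulation curve.

    Draws ``n_perm`` uniformly random orderings of the H records and
    accumulates distinct species.  Returns the across-permutation mean
    and standard deviation at every n = 1..H.
    """
    H, S = inc.matrix.shape
    if H < 1:
        raise ValueError("unit has no records")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    # position of each record under each permutation
    pos = np.argsort(rng.random((n_perm, H)), axis=1).argsort(axis=1)
    # first position at which each species appears, per permutation
    first = np.empty((S, n_perm), dtype=np.int64)
    cols = inc.matrix.astype(bool)
    for s in range(S):
        first[s] = pos[:, cols[:, s]].min(axis=1)
    # per-permutation curve via histogram of first positions, then cumsum
    offsets = first + (np.arange(n_perm, dtype=np.int64) * H)[None, :]
    hist = np.bincount(offsets.ravel(), minlength=n_perm * H).reshape(n_perm, H)
    curves = hist.cumsum(axis=1)
    return AccumulationCurve(
        unit_id=inc.unit_id,
        n=np.arange(1, H + 1),
        S_mean=curves.mean(axis=0),
        S_sd=curves.std(axis=0, ddof=0),
        n_perm=n_perm,
        kind="permutation",
    )


def _log_choose(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def mao_tau(inc: UnitIncidence, h: int) -> float:
    """Expected richness after ``h`` of the unit's H records.

    tau(h) = S_obs - sum_j s_j * C(H-j, h) / C(H, h), where s_j is the
    number of species occurring in exactly j records: each species is
    absent from a random h-subset with hypergeometric probability.
    Binomials are evaluated in log space (H can reach ~100).
    """
    H, S_obs = inc.H, inc.S_obs
    if not 0 <= h <= H:
        raise ValueError(f"h={h} outside [0, {H}]")
    if h == 0:
        return 0.0
    counts = inc.species_record_counts  # j per species
    j = counts[counts <= H - h].astype(float)
    if len(j) == 0:
        return float(S_obs)
    logp = _log_choose(H - j, float(h)) - _log_choose(float(H), float(h))
    return float(S_obs - np.exp(logp).sum())


def mao_tau_curve(inc: UnitIncidence) -> AccumulationCurve:
    """Analytic expected accumulation curve at n = 1..H."""
    H = inc.H
    vals = np.array([mao_tau(inc, h) for h in range(1, H + 1)])
    return AccumulationCurve(
        unit_id=inc.unit_id,
        n=np.arange(1, H + 1),
        S_mean=vals,
        S_sd=np.zeros(H),
        n_perm=0,
        kind="mao_tau",
    )


def curves_to_frame(curves: list[AccumulationCurve]) -> pd.DataFrame:
    """Tidy export (unit_id, n, S_mean, S_sd) for a set of curves."""
    return pd.concat([c.to_frame() for c in curves], ignore_index=True)
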