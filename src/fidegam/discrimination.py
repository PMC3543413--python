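"""ROC-based evaluation of completeness measures.

A completeness measure is useful only if it separates well-sampled (S1)
from poorly sampled (S2) units.  Units are labeled either by a sampling
effort surrogate (record count above the median) or, when the simulator
provides true richness, by true completeness exceeding 70%.  Each
measure is then treated as a classifier: a binary-regression (logistic)
model gives P[S1 | Y], the ROC curve is traced, and discrimination is
summarized by the nonparametric AUC (the Mann-Whitney pair statistic)
with a stratified case-resampling bootstrap CI.  The Youden index
J = max(TPR - FPR) gives an objective cut-point, mapped back to a
threshold on the measure's own scale.

Orientation: scores are flipped where needed so that larger always
means "more completely sampled" (NPE as-is; STE and FIDEGAM negated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from sklearn.metrics import roc_curve as _sk_roc_curve

from .occurrence import OccurrenceTable
from .simulate import SimulatedDatabase, true_completeness

__all__ = [
    "LabeledUnits",
    "RocResult",
    "YoudenResult",
    "label_by_median_records",
    "label_by_true_completeness",
    "empirical_auc",
    "roc_glm",
    "density_diagnostic",
    "youden_threshold",
    "orient_scores",
]

#: true-completeness percentage above which a unit counts as well sampled
COMPLETENESS_CUTOFF = 70.0
#: methods whose raw value decreases with completeness (flip before ROC)
NEGATED_METHODS = frozenset({"STE", "FIDEGAM"})


class DegenerateLabelingError(ValueError):
    """Labels place every unit in a single class."""


@dataclass
class LabeledUnits:
    """Binary S1 (well sampled) / S2 (poorly sampled) unit labels."""

    unit_ids: list[str]
    labels: np.ndarray  # 1 = S1, 0 = S2
    rule: str  # "median_records" | "true_completeness_70"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.unit_ids):
            raise ValueError("labels and unit ids differ in length")

    def require_both_classes(self) -> None:
        if self.labels.min() == self.labels.max():
            raise DegenerateLabelingError(
                f"rule {self.rule!r} produced a single class"
            )

    def aligned(self, unit_ids: list[str]) -> np.ndarray:
        idx = {u: i for i, u in enumerate(self.unit_ids)}
        return self.labels[[idx[u] for u in unit_ids]]


@dataclass
class RocResult:
    method: str
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray
    glm_intercept: float
    glm_slope: float
    glm_converged: bool
    probabilities: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)
    oriented_scores: np.ndarray = field(repr=False, default=None)


@dataclass
class YoudenResult:
    J: float
    c0: float  # optimal probability cut-point
    threshold_on_measure: float  # on the measure's own (raw) scale


def label_by_median_records(db: OccurrenceTable) -> LabeledUnits:
    """S1 = record count strictly above the median; ties go to S2."""
    units = db.unit_ids
    if len(units) < 2:
        raise ValueError("need at least 2 units to label")
    counts = np.array([db.n_records(u) for u in units], dtype=float)
    med = float(np.median(counts))
    labels = (counts > med).astype(int)
    out = LabeledUnits(units, labels, "median_records")
    out.require_both_classes()
    return out


def label_by_true_completeness(sim_sub: SimulatedDatabase) -> LabeledUnits:
    """S1 = true completeness strictly above 70%."""
    comp = true_completeness(sim_sub)
    labels = (comp.to_numpy() > COMPLETENESS_CUTOFF).astype(int)
    out = LabeledUnits(list(comp.index), labels, "true_completeness_70")
    out.require_both_classes()
    return out


def orient_scores(method: str, values: np.ndarray) -> np.ndarray:
    """Return scores oriented so that larger means more likely S1."""
    values = np.asarray(values, dtype=float)
    return -values if method in NEGATED_METHODS else values


def empirical_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Nonparametric AUC: fraction of (S1, S2) pairs correctly ordered.

    Ties count one half.  ``scores`` must already be oriented (larger =
    more likely S1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    s1 = scores[labels == 1]
    s2 = scores[labels == 0]
    if len(s1) == 0 or len(s2) == 0:
        raise DegenerateLabelingError("both classes required for AUC")
    diff = s1[:, None] - s2[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def roc_glm(
    scores: np.ndarray,
    labels: LabeledUnits | np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    method: str = "",
) -> RocResult:
    """Logistic-regression ROC with bootstrap AUC confidence interval.

    ``scores`` must be oriented.  The logistic model supplies P[S1 | Y]
    (the Fig-2-style densities and the Youden back-mapping); the AUC
    point estimate is the nonparametric pair statistic, which the
    monotone probability transform leaves unchanged.  The CI is a
    percentile interval over class-stratified case resamples.
    """
    y = labels.labels if isinstance(labels, LabeledUnits) else np.asarray(labels, int)
    scores = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise DegenerateLabelingError("both classes required for ROC")

    X = sm.add_constant(scores)
    converged = True
    try:
        with np.errstate(all="ignore"):
            glm = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        coef = np.asarray(glm.params, dtype=float)
        probs = np.asarray(glm.predict(X), dtype=float)
        if not np.all(np.isfinite(coef)) or abs(coef[1]) > 1e3:
            converged = False
    except Exception:
        converged = False
        coef = np.array([np.nan, np.nan])
    if not converged:
        # complete separation: keep the empirical ROC on the raw scores
        probs = (scores - scores.min()) / max(np.ptp(scores), 1e-12)

    fpr, tpr, _ = _sk_roc_curve(y, probs)
    auc = empirical_auc(scores, y)

    rng = np.random.default_rng(seed)
    i1 = np.flatnonzero(y == 1)
    i0 = np.flatnonzero(y == 0)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(i1, size=len(i1)), rng.choice(i0, size=len(i0))]
        )
        boot[b] = empirical_auc(scores[idx], y[idx])
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return RocResult(
        method=method,
        auc=auc,
        ci_low=float(min(lo, auc)),
        ci_high=float(max(hi, auc)),
        fpr=fpr,
        tpr=tpr,
        glm_intercept=float(coef[0]),
        glm_slope=float(coef[1]),
        glm_converged=converged,
        probabilities=probs,
        labels=y,
        oriented_scores=scores,
    )


def density_diagnostic(
    probabilities: np.ndarray, labels: np.ndarray, grid_size: int = 201
) -> pd.DataFrame:
    """Gaussian-kernel densities of P[S1|Y] per class on a [0,1] grid.

    Degenerate classes (a single observation, or zero spread) fall back
    to a fixed-bandwidth Gaussian bump so the diagnostic stays defined.
    """
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    grid = np.linspace(0.0, 1.0, grid_size)
    out = {"p": grid}
    for cls, name in ((1, "S1"), (0, "S2")):
        vals = probs[y == cls]
        if len(vals) >= 2 and np.std(vals) > 1e-12:
            from scipy.stats import gaussian_kde

            dens = gaussian_kde(vals)(grid)
        else:
            bw = 0.05
            dens = norm.pdf(grid[:, None], loc=vals[None, :], scale=bw).mean(axis=1)
        out[f"density_{name}"] = dens
    return pd.DataFrame(out)


def youden_threshold(roc: RocResult, scores: np.ndarray | None = None) -> YoudenResult:
    """Youden index J = max(TPR - FPR) and the associated cut-point.

    ``c0`` is the optimal probability cut; the threshold is mapped back
    to the measure's raw scale through the logistic coefficients (and
    through the orientation flip for slope-type measures, so that e.g.
    FIDEGAM values *above* the returned threshold mean poorly sampled).
    """
    y = roc.labels
    probs = roc.probabilities
    order = np.argsort(probs)[::-1]
    p_sorted = probs[order]
    y_sorted = y[order]
    n1 = max(int(y.sum()), 1)
    n0 = max(int((1 - y).sum()), 1)
    tpr = np.cumsum(y_sorted) / n1
    fpr = np.cumsum(1 - y_sorted) / n0
    j_all = tpr - fpr
    k = int(np.argmax(j_all))
    J = float(j_all[k])
    # cut midway between the last included and the next excluded prob
    p_in = p_sorted[k]
    p_out = p_sorted[k + 1] if k + 1 < len(p_sorted) else p_in - 1e-9
    c0 = float((p_in + p_out) / 2.0)

    if roc.glm_converged and abs(roc.glm_slope) > 1e-12:
        c0c = min(max(c0, 1e-9), 1 - 1e-9)
        y_star = (np.log(c0c / (1 - c0c)) - roc.glm_intercept) / roc.glm_slope
    else:
        # fall back to the oriented-score scale directly
        s = roc.oriented_scores
        s_sorted = s[np.argsort(s)[::-1]]
        y_star = float(s_sorted[k])
    # undo orientation: for negated measures the raw threshold flips sign
    threshold = -y_star if roc.method in NEGATED_METHODS else y_star
    return YoudenResult(J=J, c0=c0, threshold_on_measure=float(threshold))
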