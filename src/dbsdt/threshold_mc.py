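"""Fixed CMCT -> baseline-severity tree, Monte Carlo threshold sweep and ROC.

The two-node prognostic tree reads: if CMCT is abnormal, prognosis is
unfavorable; otherwise prognosis is favorable iff the baseline BFMDRS-m
exceeds a severity cut-off (equality routes to unfavorable — the rule is a
strict ``>``).  Because the cut-off is a free clinical choice, the sweep
resamples the cohort with replacement many times and reports, for every
cut-off on a 0.5-step grid, the mean and standard error of sensitivity and
specificity across resamples, together with the node-1 bounds: whatever the
cut-off, sensitivity can never exceed the fraction of true positives with
normal CMCT, and specificity can never fall below the fraction of true
negatives with abnormal CMCT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from dbsdt.cohort_model import Cohort, CohortError, NeurophysStatus

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "MCSweepResult",
    "fixed_tree_predict",
    "confusion",
    "compute_metrics",
    "mc_threshold_sweep",
    "node1_bounds",
    "roc_points",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies; positive means favorable prognosis."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise CohortError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    """Accuracy, sensitivity and specificity; ``None`` marks an undefined
    ratio (zero denominator), never silently 0."""

    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]


def fixed_tree_predict(cmct, baseline: float, cutoff: float) -> int:
    """Prognosis from the fixed two-node tree.

    Unfavorable (0) whenever CMCT is abnormal; otherwise favorable (1) iff
    ``baseline > cutoff``.  CMCT must be normal or abnormal — NA cases are
    excluded upstream by :func:`dbsdt.cohort_model.filter_feature_available`.
    """
    status = NeurophysStatus(cmct)
    if status is NeurophysStatus.NA:
        raise CohortError("fixed tree is undefined for CMCT = NA; filter the cohort first")
    if status is NeurophysStatus.ABNORMAL:
        return 0
    return int(baseline > cutoff)


def confusion(predictions: Sequence[int], truths: Sequence[int]) -> ConfusionCounts:
    """Tally the four confusion cells from aligned prediction/truth lists."""
    preds = np.asarray(predictions, dtype=int)
    y = np.asarray(truths, dtype=int)
    if preds.shape != y.shape:
        raise CohortError(f"length mismatch: {preds.shape} predictions vs {y.shape} truths")
    return ConfusionCounts(
        tp=int(((preds == 1) & (y == 1)).sum()),
        tn=int(((preds == 0) & (y == 0)).sum()),
        fp=int(((preds == 1) & (y == 0)).sum()),
        fn=int(((preds == 0) & (y == 1)).sum()),
    )


def compute_metrics(cc: ConfusionCounts) -> Metrics:
    """Accuracy = (TP+TN)/all, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP)."""
    total = cc.total
    pos = cc.tp + cc.fn
    neg = cc.tn + cc.fp
    return Metrics(
        accuracy=(cc.tp + cc.tn) / total if total > 0 else None,
        sensitivity=cc.tp / pos if pos > 0 else None,
        specificity=cc.tn / neg if neg > 0 else None,
    )


def _cohort_arrays(cohort: Cohort):
    if cohort.labels is None:
        raise CohortError("cohort must be labelled")
    abn = []
    base = []
    for r in cohort.records:
        if r.cmct is NeurophysStatus.NA:
            raise CohortError(
                "cohort contains CMCT = NA records; apply filter_feature_available first"
            )
        abn.append(r.cmct is NeurophysStatus.ABNORMAL)
        base.append(r.baseline_bfm)
    return np.asarray(abn), np.asarray(base, dtype=float), np.asarray(cohort.labels, dtype=int)


def node1_bounds(cohort: Cohort) -> tuple[float, float]:
    """Sensitivity ceiling and specificity floor induced by the CMCT node.

    ``sens_upper_bound = 1 - P(abnormal CMCT | positive outcome)`` — positives
    with abnormal CMCT are lost at node 1 regardless of the severity cut-off;
    ``spec_lower_bound = P(abnormal CMCT | negative outcome)`` — those
    negatives are correctly rejected at node 1 for free.
    """
    abn, _, y = _cohort_arrays(cohort)
    n_pos = int(y.sum())
    n_neg = int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise CohortError("node-1 bounds need both outcome classes present")
    sens_ub = 1.0 - int((abn & (y == 1)).sum()) / n_pos
    spec_lb = int((abn & (y == 0)).sum()) / n_neg
    return sens_ub, spec_lb


@dataclass
class MCSweepResult:
    """Per-cutoff sensitivity/specificity summaries over resamples."""

    thresholds: np.ndarray
    sens_mean: np.ndarray
    sens_se: np.ndarray
    spec_mean: np.ndarray
    spec_se: np.ndarray
    n_sample: int
    reps: int
    sens_upper_bound: float
    spec_lower_bound: float
    n_undefined_sens: int = 0
    n_undefined_spec: int = 0


def cutoff_grid(baselines: Sequence[float], step: float = 0.5) -> np.ndarray:
    """Every candidate threshold from floor(min) to ceil(max) in 0.5 steps."""
    lo = math.floor(float(np.min(baselines)))
    hi = math.ceil(float(np.max(baselines)))
    n_steps = int(round((hi - lo) / step))
    return lo + step * np.arange(n_steps + 1)


def mc_threshold_sweep(
    cohort: Cohort,
    cutoff_step: float = 0.5,
    n_sample: int = 100,
    reps: int = 1000,
    seed: int = 0,
    grid: Optional[np.ndarray] = None,
) -> MCSweepResult:
    """Monte Carlo sensitivity/specificity sweep over severity cut-offs.

    Each of ``reps`` resamples draws ``n_sample`` records uniformly with
    replacement; the fixed tree is applied at every cut-off and the per-rep
    sensitivity and specificity recorded.  Resamples that drew no positives
    (or no negatives) have that metric undefined and are excluded from its
    mean/SE; their count is reported.  The standard error is the across-rep
    sample standard deviation divided by sqrt(#defined reps).  By
    construction, every rep's sensitivity stays at or below that rep's own
    node-1 upper bound (and specificity at or above its lower bound); this is
    asserted for every rep.
    """
    abn, base, y = _cohort_arrays(cohort)
    if y.sum() == 0 or (1 - y).sum() == 0:
        raise CohortError("Monte Carlo sweep needs both outcome classes present")
    grid = cutoff_grid(base, cutoff_step) if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)
    n_cut = len(grid)
    sens = np.full((reps, n_cut), np.nan)
    spec = np.full((reps, n_cut), np.nan)
    for r in range(reps):
        idx = rng.integers(0, n, size=n_sample)
        y_s, abn_s, base_s = y[idx], abn[idx], base[idx]
        pos = int(y_s.sum())
        neg = n_sample - pos
        # predicted favorable: normal CMCT and baseline > cutoff
        pred = (~abn_s)[:, None] & (base_s[:, None] > grid[None, :])
        tp = (pred & (y_s == 1)[:, None]).sum(axis=0)
        tn = ((~pred) & (y_s == 0)[:, None]).sum(axis=0)
        if pos > 0:
            sens[r] = tp / pos
            rep_sens_ub = 1.0 - int((abn_s & (y_s == 1)).sum()) / pos
            assert np.all(sens[r] <= rep_sens_ub + 1e-12)
        if neg > 0:
            spec[r] = tn / neg
            rep_spec_lb = int((abn_s & (y_s == 0)).sum()) / neg
            assert np.all(spec[r] >= rep_spec_lb - 1e-12)
    sens_ub, spec_lb = node1_bounds(cohort)

    def _summ(mat):
        defined = ~np.isnan(mat[:, 0])
        m = mat[defined]
        mean = m.mean(axis=0)
        se = (
            m.std(axis=0, ddof=1) / np.sqrt(len(m))
            if len(m) > 1
            else np.zeros(mat.shape[1])
        )
        return mean, se, int((~defined).sum())

    sens_mean, sens_se, und_s = _summ(sens)
    spec_mean, spec_se, und_p = _summ(spec)
    return MCSweepResult(
        thresholds=grid,
        sens_mean=sens_mean,
        sens_se=sens_se,
        spec_mean=spec_mean,
        spec_se=spec_se,
        n_sample=n_sample,
        reps=reps,
        sens_upper_bound=sens_ub,
        spec_lower_bound=spec_lb,
        n_undefined_sens=und_s,
        n_undefined_spec=und_p,
    )


def roc_points(sweep: MCSweepResult) -> list[tuple[float, float]]:
    """ROC locus: one (1 - specificity, sensitivity) point per cut-off,
    ordered by cut-off."""
    return [
        (1.0 - sp, se)
        for sp, se in zip(sweep.spec_mean.tolist(), sweep.sens_mean.tolist())
    ]
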