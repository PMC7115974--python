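"""Exhaustive feature-subset search with repeated k-fold cross-validation.

Every non-empty subset of the candidate features (2^k - 1 of them; 63 for the
six clinical features, 31 when CMCT is dropped) is evaluated by repeated
k-fold cross-validation of a decision tree, and ranked by mean out-of-sample
accuracy against the majority-class baseline.  Because fold allocation is
random, accuracy is averaged over many independent random partitions and
reported with its standard error.

The outcome-threshold sweep re-binarizes the cohort at each % change
threshold (0-5 by default) and reruns the search, reporting class counts and
the features that appear in more than half of the top-10 subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from dbsdt.cart_learner import (
    TreeParams,
    _fit_encoded,
    _predict_encoded,
    encode_records,
)
from dbsdt.cohort_model import Cohort, CohortError

__all__ = [
    "CVResult",
    "SearchReport",
    "ThresholdSweepEntry",
    "enumerate_feature_subsets",
    "majority_class_accuracy",
    "repeated_kfold_cv",
    "run_search",
    "outcome_threshold_sweep",
    "subset_seed",
]


@dataclass(frozen=True)
class CVResult:
    """Mean out-of-sample accuracy of one feature subset over repeated CV."""

    feature_subset: tuple[str, ...]
    mean_accuracy: float
    stderr: float
    iterations: int
    k: int


@dataclass
class SearchReport:
    """Outcome of an exhaustive subset search."""

    results: list[CVResult]
    baseline: float
    top_n: list[CVResult]
    feature_frequency: dict[str, int]
    features: tuple[str, ...]

    def subset_mask(self, subset: Sequence[str]) -> tuple[int, ...]:
        """Binary-coded subset mask in schema feature order (1 = included)."""
        included = set(subset)
        return tuple(int(f in included) for f in self.features)


def enumerate_feature_subsets(features: Sequence[str]) -> list[tuple[str, ...]]:
    """All non-empty subsets in binary-counter order over the feature list.

    Feature ``i`` corresponds to bit ``i``, so for k features the result has
    2^k - 1 entries and entry ``m - 1`` is the subset encoded by mask ``m``.
    """
    features = tuple(features)
    k = len(features)
    if k == 0:
        raise CohortError("cannot enumerate subsets of an empty feature list")
    if k > 16:
        raise CohortError(f"{k} features is beyond the exhaustive-search range")
    return [
        tuple(f for i, f in enumerate(features) if (mask >> i) & 1)
        for mask in range(1, 1 << k)
    ]


def majority_class_accuracy(labels: Sequence[int]) -> float:
    """Accuracy of the constant majority-class predictor: max class share."""
    y = np.asarray(labels, dtype=int)
    if y.size == 0:
        raise CohortError("majority_class_accuracy of empty labels")
    pos = int(y.sum())
    return max(pos, y.size - pos) / y.size


def _fold_assignment(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random allocation into k near-equal folds (unstratified)."""
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f
    return folds


def _stratified_assignment(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    folds = np.empty(len(y), dtype=int)
    offset = 0
    for cls in (0, 1):
        idx = np.nonzero(y == cls)[0]
        perm = rng.permutation(idx)
        for j, i in enumerate(perm):
            folds[i] = (j + offset) % k
        offset += len(idx)
    return folds


def repeated_kfold_cv(
    cohort: Cohort,
    subset: Sequence[str],
    params: TreeParams = TreeParams(),
    k: int = 10,
    iterations: int = 100,
    seed: int = 0,
    aggregation: str = "pooled",
    stratified: bool = False,
) -> CVResult:
    """Repeated k-fold CV accuracy of a tree on one feature subset.

    Each iteration draws a fresh random partition into k near-equal folds;
    each fold is held out once, a tree is fit on the rest, and the iteration's
    accuracy pools correct out-of-sample predictions over all folds
    (``aggregation="fold_mean"`` averages per-fold accuracies instead).  A
    training partition with a single class, or one on which no admissible
    split exists, yields a single-leaf tree predicting the training majority.
    Mean and standard error are taken over iterations; deterministic given
    the seed.
    """
    if cohort.labels is None:
        raise CohortError("cohort must be labelled for cross-validation")
    n = len(cohort)
    if n < k:
        raise CohortError(f"n = {n} < k = {k}")
    if aggregation not in ("pooled", "fold_mean"):
        raise CohortError(f"unknown aggregation {aggregation!r}")
    subset = tuple(subset)
    y = np.asarray(cohort.labels, dtype=int)
    X = encode_records(cohort.records, cohort.feature_schema, subset)
    ss = np.random.SeedSequence(seed)
    accs = np.empty(iterations)
    for it, child in enumerate(ss.spawn(iterations)):
        rng = np.random.default_rng(child)
        folds = (
            _stratified_assignment(y, k, rng) if stratified else _fold_assignment(n, k, rng)
        )
        correct = 0
        fold_accs = []
        for f in range(k):
            test = folds == f
            train = ~test
            tree = _fit_encoded(X[train], y[train], subset, cohort.feature_schema, params)
            preds = _predict_encoded(tree, X[test], subset)
            correct += int((preds == y[test]).sum())
            fold_accs.append(float((preds == y[test]).mean()))
        accs[it] = correct / n if aggregation == "pooled" else float(np.mean(fold_accs))
    mean = float(accs.mean())
    stderr = float(accs.std(ddof=1) / np.sqrt(iterations)) if iterations > 1 else 0.0
    return CVResult(subset, mean, stderr, iterations, k)


def subset_seed(master_seed: int, subset_index: int) -> int:
    """Deterministic per-subset seed derived from (master seed, subset index)."""
    state = np.random.SeedSequence([int(master_seed), int(subset_index)]).generate_state(1)
    return int(state[0] % (2**31))


def run_search(
    cohort: Cohort,
    features: Optional[Sequence[str]] = None,
    params: TreeParams = TreeParams(),
    k: int = 10,
    iterations: int = 100,
    seed: int = 0,
    top_n: int = 10,
    aggregation: str = "pooled",
    stratified: bool = False,
    progress: Optional[callable] = None,
) -> SearchReport:
    """Evaluate every non-empty feature subset and rank by mean accuracy.

    Ranking ties are broken toward fewer features, then subset enumeration
    order.  ``feature_frequency`` counts, per feature, its appearances among
    the top-``top_n`` subsets.
    """
    if cohort.labels is None:
        raise CohortError("cohort must be labelled for the search")
    features = (
        tuple(features) if features is not None else cohort.feature_names()
    )
    subsets = enumerate_feature_subsets(features)
    results = []
    for idx, subset in enumerate(subsets):
        res = repeated_kfold_cv(
            cohort,
            subset,
            params=params,
            k=k,
            iterations=iterations,
            seed=subset_seed(seed, idx),
            aggregation=aggregation,
            stratified=stratified,
        )
        results.append(res)
        if progress is not None:
            progress(idx + 1, len(subsets), res)
    order = sorted(
        range(len(results)),
        key=lambda i: (-results[i].mean_accuracy, len(results[i].feature_subset), i),
    )
    top = [results[i] for i in order[: min(top_n, len(results))]]
    freq = {f: sum(f in r.feature_subset for r in top) for f in features}
    return SearchReport(
        results=results,
        baseline=majority_class_accuracy(cohort.labels),
        top_n=top,
        feature_frequency=freq,
        features=features,
    )


@dataclass
class ThresholdSweepEntry:
    """Per-threshold outcome of the robustness sweep."""

    threshold: float
    n_improved: int
    n_not_improved: int
    degraded: bool
    best_features: tuple[str, ...] = ()
    report: Optional[SearchReport] = None


def outcome_threshold_sweep(
    cohort: Cohort,
    thresholds: Sequence[float] = (0, 1, 2, 3, 4, 5),
    mode: str = "strict_gt",
    features: Optional[Sequence[str]] = None,
    params: TreeParams = TreeParams(),
    k: int = 10,
    iterations: int = 100,
    seed: int = 0,
    top_n: int = 10,
) -> list[ThresholdSweepEntry]:
    """Re-binarize the outcome at each threshold and rerun the search.

    ``best_features`` are those appearing in more than half of the top-10
    subsets.  A threshold leaving fewer than ``2 * min_leaf`` members in
    either class is flagged as performance degradation and its search is
    skipped.
    """
    entries = []
    for thr in thresholds:
        labelled = cohort.with_labels(thr, mode)
        y = np.asarray(labelled.labels)
        n_pos, n_neg = int(y.sum()), int((1 - y).sum())
        if min(n_pos, n_neg) < 2 * params.min_leaf:
            entries.append(ThresholdSweepEntry(thr, n_pos, n_neg, degraded=True))
            continue
        report = run_search(
            labelled,
            features=features,
            params=params,
            k=k,
            iterations=iterations,
            seed=seed,
            top_n=top_n,
        )
        cut = len(report.top_n) / 2
        best = tuple(
            f for f in report.features if report.feature_frequency[f] > cut
        )
        entries.append(
            ThresholdSweepEntry(thr, n_pos, n_neg, False, best, report)
        )
    return entries
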