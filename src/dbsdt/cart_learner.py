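"""Binary classification trees (CART) with native categorical splits.

Decision trees are the classifier of choice here because they combine
features non-linearly, handle categorical features without one-hot
re-encoding, and yield directly interpretable clinical rules.  This is a
plain greedy CART: each node takes the admissible split with the largest
weighted impurity decrease (Gini by default), and growth stops on purity,
the minimum-leaf-size constraint, the depth limit, or when no admissible
split has positive gain.

Determinism contract
--------------------
Among equal-gain splits the learner prefers the lowest schema feature index,
then the lowest threshold (continuous), then the lexicographically smallest
left-level set (categorical).  Continuous splits send ``value <= threshold``
left; categorical splits send ``value in left_levels`` left.  Leaf-label ties
default to the negative (unfavorable-prognosis) class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from dbsdt.cohort_model import Cohort, CohortError, FeatureSpec, PatientRecord

__all__ = [
    "Split",
    "TreeNode",
    "TreeParams",
    "DecisionTree",
    "Rule",
    "best_split",
    "fit",
    "predict",
    "predict_many",
    "tree_to_rules",
    "rules_predict",
    "tree_to_json",
    "tree_from_json",
]

_EPS = 1e-12


@dataclass(frozen=True)
class Split:
    """A single decision: continuous threshold or binary categorical partition."""

    feature: str
    kind: str  # "continuous_threshold" | "categorical_partition"
    threshold: Optional[float] = None
    left_levels: Optional[frozenset[str]] = None

    def goes_left(self, value) -> bool:
        if self.kind == "continuous_threshold":
            return float(value) <= self.threshold
        return value in self.left_levels


@dataclass
class TreeNode:
    """Internal node (has a split and two children) or leaf (has neither)."""

    label: int
    n_samples: int
    class_counts: tuple[int, int]  # (negative, positive)
    split: Optional[Split] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None


@dataclass(frozen=True)
class TreeParams:
    """Induction settings; the default minimum leaf size of 10 matches the
    end-node constraint used throughout the feature-subset search."""

    min_leaf: int = 10
    max_depth: Optional[int] = None
    impurity: str = "gini"
    tie_label: int = 0

    def __post_init__(self) -> None:
        if self.min_leaf < 1:
            raise CohortError("min_leaf must be >= 1")
        if self.impurity not in ("gini", "entropy"):
            raise CohortError(f"impurity must be gini/entropy, got {self.impurity!r}")


@dataclass
class DecisionTree:
    root: TreeNode
    features: tuple[str, ...]
    schema: tuple[FeatureSpec, ...]
    params: TreeParams = field(default_factory=TreeParams)


# ---------------------------------------------------------------------------
# Encoding: categorical levels -> integer codes per the schema, so split
# search runs on a float matrix.
# ---------------------------------------------------------------------------


def encode_records(
    records: Sequence, schema: Sequence[FeatureSpec], features: Sequence[str]
) -> np.ndarray:
    """Encode records (PatientRecord or mapping) as an (n, p) float matrix."""
    if isinstance(records, Cohort):
        records = records.records
    spec_by_name = {s.name: s for s in schema}
    cols = []
    for name in features:
        spec = spec_by_name[name]
        raw = [
            r.feature_value(name) if isinstance(r, PatientRecord) else r[name]
            for r in records
        ]
        if spec.kind == "continuous":
            cols.append(np.asarray(raw, dtype=float))
        else:
            lookup = {lv: i for i, lv in enumerate(spec.levels)}
            try:
                cols.append(np.asarray([lookup[v] for v in raw], dtype=float))
            except KeyError as exc:
                raise CohortError(f"unknown level {exc.args[0]!r} for feature {name!r}")
    return np.column_stack(cols) if cols else np.empty((len(records), 0))


def _impurity_arrays(pos: np.ndarray, n: np.ndarray, kind: str) -> np.ndarray:
    """Impurity of binary nodes given positive counts and sizes (vectorized)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, pos / np.maximum(n, 1), 0.0)
        if kind == "gini":
            return 2.0 * p * (1.0 - p)
        q = 1.0 - p
        ent = -(np.where(p > 0, p * np.log2(np.maximum(p, _EPS)), 0.0)) - np.where(
            q > 0, q * np.log2(np.maximum(q, _EPS)), 0.0
        )
        return ent


def _node_impurity(pos: int, n: int, kind: str) -> float:
    return float(_impurity_arrays(np.array([pos], float), np.array([n], float), kind)[0])


def _best_continuous(x, y, min_leaf, parent_imp, kind):
    """Best threshold for one continuous column; returns (gain, threshold)."""
    n = len(y)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    boundaries = np.nonzero(xs[:-1] < xs[1:])[0]  # split after position i
    if boundaries.size == 0:
        return None
    left_n = boundaries + 1
    cum_pos = np.cumsum(ys)
    left_pos = cum_pos[boundaries]
    right_n = n - left_n
    ok = (left_n >= min_leaf) & (right_n >= min_leaf)
    if not ok.any():
        return None
    left_n, right_n = left_n[ok], right_n[ok]
    left_pos = left_pos[ok]
    right_pos = cum_pos[-1] - left_pos
    child = (
        left_n * _impurity_arrays(left_pos, left_n, kind)
        + right_n * _impurity_arrays(right_pos, right_n, kind)
    ) / n
    gains = parent_imp - child
    i = int(np.argmax(gains))  # first max -> lowest threshold
    thresholds = (xs[boundaries] + xs[boundaries + 1]) / 2.0
    return float(gains[i]), float(thresholds[ok][i])


def _best_categorical(x, y, levels, min_leaf, parent_imp, kind):
    """Best binary partition of the levels present at this node.

    Returns (gain, left_level_names) with the lexicographically smaller
    orientation of the winning partition.
    """
    n = len(y)
    codes = x.astype(int)
    present = np.unique(codes)
    m = len(present)
    if m < 2:
        return None
    pos_c = np.array([int(y[codes == c].sum()) for c in present])
    n_c = np.array([int((codes == c).sum()) for c in present])
    total_pos = int(pos_c.sum())
    best = None  # (gain, left_names_tuple)
    # Fix the last present level on the right: each partition enumerated once.
    for mask in range(1, 1 << (m - 1)):
        sel = np.array([(mask >> j) & 1 == 1 for j in range(m - 1)] + [False])
        ln, lp = int(n_c[sel].sum()), int(pos_c[sel].sum())
        rn, rp = n - ln, total_pos - lp
        if ln < min_leaf or rn < min_leaf:
            continue
        child = (
            ln * _node_impurity(lp, ln, kind) + rn * _node_impurity(rp, rn, kind)
        ) / n
        gain = parent_imp - child
        side_a = tuple(sorted(levels[c] for c in present[sel]))
        side_b = tuple(sorted(levels[c] for c in present[~sel]))
        left_names = min(side_a, side_b)
        if best is None or gain > best[0] + _EPS or (
            abs(gain - best[0]) <= _EPS and left_names < best[1]
        ):
            best = (gain, left_names)
    if best is None:
        return None
    return best


def _best_split_encoded(
    X: np.ndarray,
    y: np.ndarray,
    features: Sequence[str],
    schema_by_name: dict,
    params: TreeParams,
) -> Optional[tuple[float, Split]]:
    n = len(y)
    pos = int(y.sum())
    if pos == 0 or pos == n or n < 2 * params.min_leaf:
        return None
    parent_imp = _node_impurity(pos, n, params.impurity)
    best_gain, best_split_ = -np.inf, None
    for j, name in enumerate(features):  # schema subset order = feature index order
        spec = schema_by_name[name]
        if spec.kind == "continuous":
            res = _best_continuous(X[:, j], y, params.min_leaf, parent_imp, params.impurity)
            if res is None:
                continue
            gain, thr = res
            cand = Split(name, "continuous_threshold", threshold=thr)
        else:
            res = _best_categorical(
                X[:, j], y, spec.levels, params.min_leaf, parent_imp, params.impurity
            )
            if res is None:
                continue
            gain, left_names = res
            cand = Split(name, "categorical_partition", left_levels=frozenset(left_names))
        if gain > best_gain + _EPS:
            best_gain, best_split_ = gain, cand
    if best_split_ is None or best_gain <= _EPS:
        return None
    return best_gain, best_split_


def best_split(
    records: Sequence,
    labels: Sequence[int],
    schema: Sequence[FeatureSpec],
    features: Optional[Sequence[str]] = None,
    params: TreeParams = TreeParams(),
) -> Optional[Split]:
    """The impurity-decrease-maximizing admissible split, or ``None``.

    An admissible split leaves at least ``min_leaf`` rows in each child; a
    winning split must have strictly positive gain.
    """
    if len(records) == 0:
        raise CohortError("best_split on empty input")
    features = tuple(features) if features is not None else tuple(s.name for s in schema)
    X = encode_records(records, schema, features)
    y = np.asarray(labels, dtype=int)
    res = _best_split_encoded(X, y, features, {s.name: s for s in schema}, params)
    return None if res is None else res[1]


def _route_left(split: Split, value: float, spec: FeatureSpec) -> bool:
    if split.kind == "continuous_threshold":
        return value <= split.threshold
    return spec.levels[int(value)] in split.left_levels


def _grow(X, y, idx, depth, features, schema_by_name, params) -> TreeNode:
    sub_y = y[idx]
    n = len(idx)
    pos = int(sub_y.sum())
    neg = n - pos
    if pos > neg:
        label = 1
    elif neg > pos:
        label = 0
    else:
        label = params.tie_label
    node = TreeNode(label=label, n_samples=n, class_counts=(neg, pos))
    if pos in (0, n) or n < 2 * params.min_leaf:
        return node
    if params.max_depth is not None and depth >= params.max_depth:
        return node
    res = _best_split_encoded(X[idx], sub_y, features, schema_by_name, params)
    if res is None:
        return node
    _, split = res
    j = features.index(split.feature)
    spec = schema_by_name[split.feature]
    col = X[idx, j]
    if split.kind == "continuous_threshold":
        go_left = col <= split.threshold
    else:
        left_codes = {i for i, lv in enumerate(spec.levels) if lv in split.left_levels}
        go_left = np.isin(col.astype(int), list(left_codes))
    node.split = split
    node.left = _grow(X, y, idx[go_left], depth + 1, features, schema_by_name, params)
    node.right = _grow(X, y, idx[~go_left], depth + 1, features, schema_by_name, params)
    return node


def fit(
    cohort: Union[Cohort, Sequence],
    features: Optional[Sequence[str]] = None,
    labels: Optional[Sequence[int]] = None,
    params: TreeParams = TreeParams(),
    schema: Optional[Sequence[FeatureSpec]] = None,
) -> DecisionTree:
    """Greedy recursive induction of a binary decision tree.

    ``cohort`` may be a :class:`Cohort` (whose schema and labels are used by
    default) or a plain sequence of records with an explicit ``schema``.
    """
    if isinstance(cohort, Cohort):
        records = cohort.records
        schema = cohort.feature_schema
        if labels is None:
            labels = cohort.labels
    else:
        records = list(cohort)
        if schema is None:
            raise CohortError("schema required when fitting raw records")
    if labels is None:
        raise CohortError("labels are required to fit a tree")
    if len(records) == 0:
        raise CohortError("cannot fit a tree on an empty cohort")
    if len(labels) != len(records):
        raise CohortError("labels and records length mismatch")
    features = tuple(features) if features is not None else tuple(s.name for s in schema)
    X = encode_records(records, schema, features)
    y = np.asarray(labels, dtype=int)
    return _fit_encoded(X, y, features, tuple(schema), params)


def _fit_encoded(
    X: np.ndarray,
    y: np.ndarray,
    features: tuple[str, ...],
    schema: tuple[FeatureSpec, ...],
    params: TreeParams,
) -> DecisionTree:
    """Fit from a pre-encoded matrix (categorical columns as level codes)."""
    schema_by_name = {s.name: s for s in schema}
    root = _grow(X, y, np.arange(len(y)), 0, features, schema_by_name, params)
    return DecisionTree(root=root, features=features, schema=schema, params=params)


def _feature_value(record, name: str):
    if isinstance(record, PatientRecord):
        return record.feature_value(name)
    return record[name]


def predict(tree: DecisionTree, record) -> int:
    """Route one record root-to-leaf and return the leaf's label.

    A categorical level the training data never routed (absent from the
    split's stored levels *and* the schema) falls back to the majority child,
    with a warning, so prediction is total over schema-valid inputs.
    """
    node = tree.root
    spec_by_name = {s.name: s for s in tree.schema}
    while not node.is_leaf:
        split = node.split
        value = _feature_value(record, split.feature)
        if split.kind == "continuous_threshold":
            go_left = float(value) <= split.threshold
        else:
            spec = spec_by_name[split.feature]
            if value not in spec.levels:
                warnings.warn(
                    f"unseen level {value!r} for feature {split.feature!r}; "
                    "routing with majority child",
                    stacklevel=2,
                )
                go_left = node.left.n_samples >= node.right.n_samples
            else:
                go_left = value in split.left_levels
        node = node.left if go_left else node.right
    return node.label


def predict_many(tree: DecisionTree, records: Sequence) -> np.ndarray:
    return np.array([predict(tree, r) for r in records], dtype=int)


def _predict_encoded(tree: DecisionTree, X: np.ndarray, features: Sequence[str]) -> np.ndarray:
    """Prediction over a pre-encoded matrix (used by cross-validation)."""
    spec_by_name = {s.name: s for s in tree.schema}
    col_of = {name: j for j, name in enumerate(features)}
    out = np.empty(len(X), dtype=int)
    for i in range(len(X)):
        node = tree.root
        while not node.is_leaf:
            s = node.split
            v = X[i, col_of[s.feature]]
            node = (
                node.left
                if _route_left(s, v, spec_by_name[s.feature])
                else node.right
            )
        out[i] = node.label
    return out


# ---------------------------------------------------------------------------
# Rule extraction: one conjunctive rule per leaf; re-applying the rules
# reproduces predict exactly.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Rule:
    """Conjunction of conditions leading to one leaf."""

    conditions: tuple[tuple[str, str, object], ...]  # (feature, op, operand)
    label: int
    n_samples: int

    def matches(self, record) -> bool:
        for feature, op, operand in self.conditions:
            v = _feature_value(record, feature)
            if op == "<=" and not float(v) <= operand:
                return False
            if op == ">" and not float(v) > operand:
                return False
            if op == "in" and v not in operand:
                return False
            if op == "not_in" and v in operand:
                return False
        return True

    def __str__(self) -> str:
        verdict = "favorable" if self.label == 1 else "unfavorable"
        if not self.conditions:
            return f"ALWAYS -> {verdict} (n={self.n_samples})"
        parts = []
        for feature, op, operand in self.conditions:
            if op in ("in", "not_in"):
                lv = "{" + ", ".join(sorted(operand)) + "}"
                parts.append(f"{feature} {'in' if op == 'in' else 'not in'} {lv}")
            else:
                parts.append(f"{feature} {op} {operand:g}")
        return "IF " + " AND ".join(parts) + f" -> {verdict} (n={self.n_samples})"


def tree_to_rules(tree: DecisionTree) -> list[Rule]:
    """One conjunctive rule per leaf, in left-to-right leaf order."""
    rules: list[Rule] = []

    def walk(node: TreeNode, conds: tuple) -> None:
        if node.is_leaf:
            rules.append(Rule(conds, node.label, node.n_samples))
            return
        s = node.split
        if s.kind == "continuous_threshold":
            walk(node.left, conds + ((s.feature, "<=", s.threshold),))
            walk(node.right, conds + ((s.feature, ">", s.threshold),))
        else:
            walk(node.left, conds + ((s.feature, "in", frozenset(s.left_levels)),))
            walk(node.right, conds + ((s.feature, "not_in", frozenset(s.left_levels)),))

    walk(tree.root, ())
    return rules


def rules_predict(rules: Sequence[Rule], record) -> int:
    """Apply an extracted rule list; rules are exhaustive and exclusive."""
    for rule in rules:
        if rule.matches(record):
            return rule.label
    raise CohortError("no rule matched; rule list is not exhaustive for this record")


# ---------------------------------------------------------------------------
# Serialization: documented JSON text form, round-trippable.
# ---------------------------------------------------------------------------


def _node_to_dict(node: TreeNode) -> dict:
    d = {
        "label": node.label,
        "n_samples": node.n_samples,
        "class_counts": list(node.class_counts),
    }
    if not node.is_leaf:
        s = node.split
        d["split"] = {
            "feature": s.feature,
            "kind": s.kind,
            "threshold": s.threshold,
            "left_levels": sorted(s.left_levels) if s.left_levels is not None else None,
        }
        d["left"] = _node_to_dict(node.left)
        d["right"] = _node_to_dict(node.right)
    return d


def _node_from_dict(d: dict) -> TreeNode:
    node = TreeNode(
        label=int(d["label"]),
        n_samples=int(d["n_samples"]),
        class_counts=tuple(d["class_counts"]),
    )
    if "split" in d:
        s = d["split"]
        node.split = Split(
            feature=s["feature"],
            kind=s["kind"],
            threshold=s["threshold"],
            left_levels=frozenset(s["left_levels"]) if s["left_levels"] is not None else None,
        )
        node.left = _node_from_dict(d["left"])
        node.right = _node_from_dict(d["right"])
    return node


def tree_to_json(tree: DecisionTree) -> str:
    payload = {
        "features": list(tree.features),
        "schema": [
            {"name": s.name, "kind": s.kind, "levels": list(s.levels)} for s in tree.schema
        ],
        "params": {
            "min_leaf": tree.params.min_leaf,
            "max_depth": tree.params.max_depth,
            "impurity": tree.params.impurity,
            "tie_label": tree.params.tie_label,
        },
        "root": _node_to_dict(tree.root),
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def tree_from_json(text: str) -> DecisionTree:
    payload = json.loads(text)
    schema = tuple(
        FeatureSpec(s["name"], s["kind"], tuple(s["levels"])) for s in payload["schema"]
    )
    params = TreeParams(**payload["params"])
    return DecisionTree(
        root=_node_from_dict(payload["root"]),
        features=tuple(payload["features"]),
        schema=schema,
        params=params,
    )
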