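"""CART learner: split search vs brute-force oracle, induction, rules, I/O."""

import itertools

import numpy as np
import pytest

from dbsdt.cart_learner import (
    DecisionTree,
    Split,
    TreeParams,
    best_split,
    fit,
    predict,
    predict_many,
    rules_predict,
    tree_from_json,
    tree_to_json,
    tree_to_rules,
)
from dbsdt.cohort_model import CohortError, FeatureSpec
from dbsdt.model_search import majority_class_accuracy
from tests.conftest import make_cohort, make_record

# ---------------------------------------------------------------------------
# Independent oracle: exhaustive enumeration of every admissible split with
# plain-python Gini arithmetic and the documented tie-break order.
# ---------------------------------------------------------------------------


def _gini(labels):
    n = len(labels)
    if n == 0:
        return 0.0
    p = sum(labels) / n
    return 1.0 - p * p - (1.0 - p) ** 2


def oracle_best_split(rows, labels, schema, min_leaf):
    """Enumerate all admissible splits; return the gain-maximizing one under
    the (feature index, threshold, lexicographic left levels) tie-break."""
    n = len(labels)
    parent = _gini(labels)
    best = None  # (gain, order_key, Split)
    for fi, spec in enumerate(schema):
        vals = [row[spec.name] for row in rows]
        candidates = []
        if spec.kind == "continuous":
            uniq = sorted(set(vals))
            for a, b in zip(uniq, uniq[1:]):
                thr = (a + b) / 2.0
                left = [l for v, l in zip(vals, labels) if v <= thr]
                candidates.append(
                    ((fi, thr, ()), Split(spec.name, "continuous_threshold", threshold=thr), left)
                )
        else:
            present = sorted(set(vals))
            for r in range(1, len(present)):
                for combo in itertools.combinations(present, r):
                    left_set = frozenset(combo)
                    right_set = frozenset(present) - left_set
                    canon = min(tuple(sorted(left_set)), tuple(sorted(right_set)))
                    if tuple(sorted(left_set)) != canon:
                        continue  # each partition once, smaller side as left
                    left = [l for v, l in zip(vals, labels) if v in left_set]
                    candidates.append(
                        (
                            (fi, float("inf"), canon),
                            Split(spec.name, "categorical_partition", left_levels=left_set),
                            left,
                        )
                    )
        for key, split, left in candidates:
            n_left = len(left)
            n_right = n - n_left
            if n_left < min_leaf or n_right < min_leaf:
                continue
            right = [l for v, l in zip(vals, labels) if not split.goes_left(v)]
            gain = parent - (n_left * _gini(left) + n_right * _gini(right)) / n
            if best is None or gain > best[0] + 1e-12 or (
                abs(gain - best[0]) <= 1e-12 and key < best[1]
            ):
                best = (gain, key, split)
    if best is None or best[0] <= 1e-12:
        return None
    return best[2]


_MIXED_SCHEMA = (
    FeatureSpec("score", "continuous"),
    FeatureSpec("grade", "categorical", ("lo", "mid", "hi")),
)


def _random_table(rng, n=30):
    rows = [
        {"score": float(rng.integers(0, 10)), "grade": ("lo", "mid", "hi")[rng.integers(0, 3)]}
        for _ in range(n)
    ]
    labels = rng.integers(0, 2, size=n).tolist()
    return rows, labels


class TestBestSplit:
    def test_perfect_binary_separator(self):
        """A binary feature splitting labels 10/10 is chosen with full gain."""
        schema = (FeatureSpec("flag", "categorical", ("no", "yes")),)
        rows = [{"flag": "yes"}] * 10 + [{"flag": "no"}] * 10
        labels = [1] * 10 + [0] * 10
        split = best_split(rows, labels, schema, params=TreeParams(min_leaf=5))
        assert split.feature == "flag"
        assert split.left_levels == frozenset({"no"})

    def test_pure_labels_give_no_split(self):
        schema = (FeatureSpec("x", "continuous"),)
        rows = [{"x": float(i)} for i in range(20)]
        assert best_split(rows, [1] * 20, schema, params=TreeParams(min_leaf=2)) is None

    def test_empty_input_is_an_error(self):
        with pytest.raises(CohortError):
            best_split([], [], _MIXED_SCHEMA)

    @pytest.mark.parametrize("table_seed", range(50))
    def test_matches_exhaustive_enumeration(self, table_seed):
        """On random mixed tables the learner's split equals the brute-force
        enumeration of every admissible split's weighted Gini decrease."""
        rng = np.random.default_rng(1000 + table_seed)
        rows, labels = _random_table(rng)
        min_leaf = int(rng.choice([1, 3, 5]))
        params = TreeParams(min_leaf=min_leaf)
        got = best_split(rows, labels, _MIXED_SCHEMA, params=params)
        expected = oracle_best_split(rows, labels, _MIXED_SCHEMA, min_leaf)
        assert got == expected

    @pytest.mark.parametrize("table_seed", range(20))
    def test_depth1_fit_equals_stump_oracle(self, table_seed):
        """A depth-limited fit's root split is the brute-force best stump."""
        rng = np.random.default_rng(2000 + table_seed)
        rows, labels = _random_table(rng)
        params = TreeParams(min_leaf=3, max_depth=1)
        tree = fit(rows, labels=labels, params=params, schema=_MIXED_SCHEMA)
        assert tree.root.split == oracle_best_split(rows, labels, _MIXED_SCHEMA, 3)


def _cmct_cohort(n=200, seed=5):
    """Cohort whose label is exactly 1[cmct = normal]."""
    rng = np.random.default_rng(seed)
    recs, labels = [], []
    for i in range(n):
        status = "normal" if rng.random() < 0.5 else "abnormal"
        recs.append(
            make_record(
                id=f"R{i}",
                cmct=status,
                baseline_bfm=float(rng.uniform(10, 110)),
                pct_change=1.0,
            )
        )
        labels.append(int(status == "normal"))
    return make_cohort(recs, labels)


class TestFit:
    def test_min_leaf_at_n_forces_root_leaf(self):
        cohort = _cmct_cohort(40)
        tree = fit(cohort, params=TreeParams(min_leaf=40))
        assert tree.root.is_leaf
        majority = int(sum(cohort.labels) * 2 > len(cohort.labels))
        assert tree.root.label == majority

    def test_planted_single_feature_recovery(self):
        """Outcome = 1[cmct normal] with no noise yields a depth-1 CMCT tree
        with perfect training accuracy."""
        cohort = _cmct_cohort(200)
        tree = fit(cohort, params=TreeParams(min_leaf=10))
        assert tree.root.split.feature == "cmct"
        assert tree.root.left.is_leaf and tree.root.right.is_leaf
        preds = predict_many(tree, cohort.records)
        assert (preds == np.array(cohort.labels)).all()

    def test_xor_interaction_needs_depth_two(self):
        """A (slightly unbalanced) XOR of two binary features is captured
        perfectly at depth 2, while no single split can beat chance by much —
        the non-linear-combination property decision trees are chosen for."""
        schema = (
            FeatureSpec("f1", "categorical", ("a", "b")),
            FeatureSpec("f2", "categorical", ("a", "b")),
        )
        counts = {("a", "a"): 12, ("a", "b"): 9, ("b", "a"): 9, ("b", "b"): 10}
        rows, labels = [], []
        for (v1, v2), count in counts.items():
            rows += [{"f1": v1, "f2": v2}] * count
            labels += [int(v1 != v2)] * count
        tree = fit(rows, labels=labels, params=TreeParams(min_leaf=2), schema=schema)
        preds = [predict(tree, r) for r in rows]
        assert preds == labels
        depth = 0
        node = tree.root
        while not node.is_leaf:
            depth += 1
            node = node.left
        assert depth >= 2
        # brute force: every stump leaves at least 18 of 40 misclassified
        stump = oracle_best_split(rows, labels, schema, 2)
        for split in [stump]:
            left_lab = [l for r, l in zip(rows, labels) if split.goes_left(r[split.feature])]
            right_lab = [l for r, l in zip(rows, labels) if not split.goes_left(r[split.feature])]
            best_acc = (
                max(sum(left_lab), len(left_lab) - sum(left_lab))
                + max(sum(right_lab), len(right_lab) - sum(right_lab))
            ) / len(labels)
            assert best_acc <= 0.55

    def test_balanced_xor_stops_at_root(self):
        """With perfectly balanced XOR cells every split has zero Gini gain,
        so positive-gain stopping yields a single leaf."""
        schema = (
            FeatureSpec("f1", "categorical", ("a", "b")),
            FeatureSpec("f2", "categorical", ("a", "b")),
        )
        rows, labels = [], []
        for v1, v2 in itertools.product("ab", "ab"):
            rows += [{"f1": v1, "f2": v2}] * 10
            labels += [int(v1 != v2)] * 10
        tree = fit(rows, labels=labels, params=TreeParams(min_leaf=2), schema=schema)
        assert tree.root.is_leaf

    def test_training_accuracy_at_least_majority(self, default_cohort):
        tree = fit(default_cohort)
        preds = predict_many(tree, default_cohort.records)
        acc = (preds == np.array(default_cohort.labels)).mean()
        assert acc >= majority_class_accuracy(default_cohort.labels)

    def test_deterministic(self, default_cohort):
        t1 = fit(default_cohort)
        t2 = fit(default_cohort)
        assert tree_to_json(t1) == tree_to_json(t2)

    def test_structural_invariants(self, default_cohort):
        """Every leaf respects min_leaf; internal counts sum over children."""
        params = TreeParams(min_leaf=10)
        tree = fit(default_cohort, params=params)

        def walk(node):
            assert node.n_samples == sum(node.class_counts)
            if node.is_leaf:
                assert node.n_samples >= params.min_leaf
                return
            assert node.n_samples == node.left.n_samples + node.right.n_samples
            assert tuple(
                l + r for l, r in zip(node.left.class_counts, node.right.class_counts)
            ) == node.class_counts
            walk(node.left)
            walk(node.right)

        walk(tree.root)

    def test_leaf_tie_goes_to_unfavorable(self):
        schema = (FeatureSpec("x", "continuous"),)
        rows = [{"x": float(i)} for i in range(4)]
        tree = fit(rows, labels=[0, 1, 0, 1], params=TreeParams(min_leaf=4), schema=schema)
        assert tree.root.is_leaf and tree.root.label == 0


class TestPredict:
    def test_single_leaf_constant(self):
        schema = (FeatureSpec("x", "continuous"),)
        tree = fit([{"x": 1.0}] * 5, labels=[1] * 5, params=TreeParams(), schema=schema)
        assert predict(tree, {"x": -100.0}) == 1

    def test_etiology_gate_semantics(self):
        """A tree splitting genetic/idiopathic vs acquired sends an isolated
        genetic record to the favorable leaf."""
        recs, labels = [], []
        rng = np.random.default_rng(9)
        for i in range(60):
            et = ("isolated_genetic", "complex_genetic", "acquired_cp")[i % 3]
            recs.append(make_record(id=f"E{i}", etiology=et, pct_change=1.0))
            labels.append(int(et.endswith("genetic")))
        tree = fit(make_cohort(recs, labels), params=TreeParams(min_leaf=10))
        assert tree.root.split.feature == "etiology"
        assert predict(tree, make_record(etiology="isolated_genetic")) == 1
        assert predict(tree, make_record(etiology="acquired_cp")) == 0

    def test_boundary_value_routes_left(self):
        schema = (FeatureSpec("x", "continuous"),)
        rows = [{"x": float(v)} for v in [1, 1, 1, 3, 3, 3]]
        tree = fit(rows, labels=[0, 0, 0, 1, 1, 1], params=TreeParams(min_leaf=3), schema=schema)
        thr = tree.root.split.threshold
        assert predict(tree, {"x": thr}) == tree.root.left.label

    def test_unseen_level_warns_and_uses_majority_child(self):
        schema = (FeatureSpec("g", "categorical", ("a", "b")),)
        rows = [{"g": "a"}] * 12 + [{"g": "b"}] * 4
        tree = fit(rows, labels=[1] * 12 + [0] * 4, params=TreeParams(min_leaf=2), schema=schema)
        with pytest.warns(UserWarning, match="unseen level"):
            out = predict(tree, {"g": "zz"})
        assert out == 1  # majority child is the 12-sample 'a' leaf


class TestRulesAndSerialization:
    def test_single_leaf_single_rule(self):
        schema = (FeatureSpec("x", "continuous"),)
        tree = fit([{"x": 0.0}] * 3, labels=[0, 0, 0], params=TreeParams(), schema=schema)
        rules = tree_to_rules(tree)
        assert len(rules) == 1 and rules[0].conditions == ()

    def test_depth1_cmct_tree_rules(self):
        cohort = _cmct_cohort(100)
        tree = fit(cohort, params=TreeParams(min_leaf=10))
        rules = tree_to_rules(tree)
        assert len(rules) == 2
        assert all(
            feature == "cmct" for rule in rules for feature, _, _ in rule.conditions
        )

    def test_rules_reproduce_predict(self, default_cohort):
        tree = fit(default_cohort)
        rules = tree_to_rules(tree)
        for rec in default_cohort.records:
            assert rules_predict(rules, rec) == predict(tree, rec)

    def test_json_round_trip(self, default_cohort):
        tree = fit(default_cohort)
        text = tree_to_json(tree)
        back = tree_from_json(text)
        assert tree_to_json(back) == text
        assert (
            predict_many(back, default_cohort.records)
            == predict_many(tree, default_cohort.records)
        ).all()


class TestSklearnCrossCheck:
    def test_depth1_stump_matches_sklearn(self):
        """On continuous data with a unique optimal cut our stump agrees with
        an independent CART implementation (threshold and predictions)."""
        sklearn_tree = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(33)
        x = rng.uniform(0, 100, size=200)
        y = (x > 57.3).astype(int)
        flip = rng.random(200) < 0.05
        y[flip] = 1 - y[flip]
        schema = (FeatureSpec("x", "continuous"),)
        rows = [{"x": float(v)} for v in x]
        ours = fit(rows, labels=y, params=TreeParams(min_leaf=10, max_depth=1), schema=schema)
        clf = sklearn_tree.DecisionTreeClassifier(
            criterion="gini", max_depth=1, min_samples_leaf=10
        ).fit(x.reshape(-1, 1), y)
        # sklearn stores thresholds as float32; compare at that precision
        assert ours.root.split.threshold == pytest.approx(
            float(clf.tree_.threshold[0]), rel=1e-6
        )
        grid = [{"x": float(v)} for v in np.linspace(0, 100, 101)]
        assert (
            predict_many(ours, grid)
            == clf.predict(np.linspace(0, 100, 101).reshape(-1, 1))
        ).all()
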