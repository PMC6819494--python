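import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thyromir as tm
from thyromir.tree import C45Params, TreeNode, UnclassifiableError, _pessimistic_errors


def panel(hmga2=-8.0, mir375=-16.0, mir221=-9.0, mir146b=-6.0, mtdna=300.0):
    """Marker panel in storage scale: log2 levels, linear mtDNA ratio."""
    return {
        "level_hmga2": hmga2, "level_mir375": mir375, "level_mir221": mir221,
        "level_mir146b": mir146b, "mtdna_ratio": mtdna,
    }


LOG2 = math.log2


class TestFixedMalignancyTree:
    @pytest.mark.parametrize(
        "p, expected",
        [
            # HMGA2 at/above the 0.0918 root cutoff -> Malignant outright
            (panel(hmga2=LOG2(0.1)), "Malignant"),
            (panel(hmga2=LOG2(0.0918)), "Malignant"),          # boundary goes right
            # low HMGA2, miR-375 above -12.1213 (log2) -> Malignant
            (panel(hmga2=LOG2(0.05), mir375=-10.0), "Malignant"),
            # low HMGA2/miR-375, miR-221 above 0.0105 -> Malignant
            (panel(mir221=LOG2(0.02)), "Malignant"),
            # only miR-146b elevated -> Malignant via the deepest split
            (panel(mir146b=LOG2(2.0)), "Malignant"),
            # everything below every cutoff -> Benign
            (panel(hmga2=LOG2(0.05), mir375=-13.0, mir221=LOG2(0.001),
                   mir146b=LOG2(1.0)), "Benign"),
        ],
    )
    def test_branches(self, p, expected):
        klass, trace = tm.apply_malignancy_tree(p)
        assert klass == expected
        assert trace[-1] == f"Diagnosis = {expected}"

    def test_early_exit_skips_deeper_markers(self):
        p = panel(hmga2=LOG2(0.05), mir375=-10.0)
        p["level_mir221"] = float("nan")
        p["level_mir146b"] = float("nan")
        klass, trace = tm.apply_malignancy_tree(p)
        assert klass == "Malignant"
        assert not any("miR-221" in s for s in trace)

    def test_missing_marker_on_path_raises(self):
        p = panel()
        p["level_mir221"] = float("nan")
        with pytest.raises(UnclassifiableError, match="miR-221"):
            tm.apply_malignancy_tree(p)

    def test_pure_function(self, benign_panel):
        assert tm.apply_malignancy_tree(benign_panel) == tm.apply_malignancy_tree(benign_panel)


class TestFixedTypingTree:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (panel(mir375=LOG2(5.2514)), "MTC"),               # boundary right
            (panel(mir375=LOG2(6.0)), "MTC"),
            (panel(mir146b=LOG2(0.5)), "PTC"),
            (panel(mir146b=LOG2(0.1), mtdna=6000.0), "HCC"),
            (panel(mir146b=LOG2(0.1), mtdna=5000.0), "FNMM"),
        ],
    )
    def test_branches(self, p, expected):
        assert tm.apply_typing_tree(p)[0] == expected


class TestRender:
    def test_fixed_tree_leaf_strings_match_published_listing(self):
        text = tm.render_tree(tm.fixed_malignancy_tree())
        assert "then Diagnosis = Benign (98.6% of 214 examples)" in text
        assert "then Diagnosis = Malignant (88.9% of 9 examples)" in text
        assert "then Diagnosis = Malignant (100.0% of 37 examples)" in text
        typing = tm.render_tree(tm.fixed_typing_tree())
        assert "then Diagnosis = MTC (100.0% of 18 examples)" in typing
        assert "then Diagnosis = PTC (98.8% of 164 examples)" in typing
        assert "then Diagnosis = FNMM (96.0% of 76 examples)" in typing

    def test_render_leaf(self):
        assert tm.render_leaf("Malignant", 8, 9) == \
            "Diagnosis = Malignant (88.9% of 9 examples)"
        assert tm.render_leaf("Benign", 211, 214) == \
            "Diagnosis = Benign (98.6% of 214 examples)"
        assert "100.0% of 5" in tm.render_leaf("PTC", 5, 5)


class TestEntropy:
    @pytest.mark.parametrize(
        "counts, expected",
        [({"A": 5, "B": 5}, 1.0), ({"A": 7, "B": 0}, 0.0),
         ({"A": 1, "B": 1, "C": 2}, 1.5)],
    )
    def test_examples(self, counts, expected):
        assert tm.entropy(counts) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            tm.entropy({"A": 0})

    @given(st.lists(st.integers(0, 50), min_size=2, max_size=6).filter(lambda c: sum(c) > 0))
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_permutation_invariance(self, counts):
        h = tm.entropy(counts)
        k = len(counts)
        assert 0.0 <= h <= math.log2(k) + 1e-12
        assert tm.entropy(list(reversed(counts))) == pytest.approx(h)

    def test_maximal_iff_equal(self):
        assert tm.entropy([7, 7, 7]) == pytest.approx(math.log2(3))
        assert tm.entropy([8, 7, 6]) < math.log2(3)


def brute_force_best_split(values, labels):
    """Exhaustive gain-ratio maximization over every midpoint threshold."""
    v = np.asarray(values, float)
    y = np.asarray(labels)
    uniq = np.unique(v)
    h_total = tm.entropy(pd.Series(y).value_counts().tolist())
    best = None
    for a, b in zip(uniq[:-1], uniq[1:]):
        thr = (a + b) / 2
        left, right = y[v < thr], y[v >= thr]
        h = (len(left) * tm.entropy(pd.Series(left).value_counts().tolist())
             + len(right) * tm.entropy(pd.Series(right).value_counts().tolist())) / len(y)
        gain = h_total - h
        if gain <= 1e-12:
            continue
        ratio = gain / tm.entropy([len(left), len(right)])
        if best is None or ratio > best[1] + 1e-12:
            best = (thr, ratio)
    return best


class TestBestSplit:
    def test_perfect_balanced_separation(self):
        thr, ratio, gain = tm.best_split([1, 2, 3, 4], ["A", "A", "B", "B"])
        assert thr == 2.5 and ratio == pytest.approx(1.0) and gain == pytest.approx(1.0)

    def test_pure_labels_no_split(self):
        assert tm.best_split([1, 2, 3], ["A", "A", "A"]) is None

    def test_constant_values_no_split(self):
        assert tm.best_split([2, 2, 2, 2], ["A", "B", "A", "B"]) is None

    @given(
        values=st.lists(st.integers(0, 12), min_size=2, max_size=25),
        data=st.data(),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_oracle(self, values, data):
        labels = data.draw(st.lists(st.sampled_from("AB"), min_size=len(values),
                                    max_size=len(values)))
        got = tm.best_split(values, labels)
        expected = brute_force_best_split(values, labels)
        if expected is None:
            assert got is None
        else:
            assert got is not None
            assert got[0] == pytest.approx(expected[0])
            assert got[1] == pytest.approx(expected[1])


class TestC45Train:
    def test_single_class_single_leaf(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": ["A", "A", "A"]})
        t = tm.c45_train(df, "y", ["x"], C45Params(min_leaf=1, pruning_cf=None))
        assert t.root.is_leaf and t.root.purity == 1.0 and t.root.support == 3

    def test_four_row_depth_one(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": ["A", "A", "B", "B"]})
        t = tm.c45_train(df, "y", ["x"], C45Params(min_leaf=1, pruning_cf=None))
        assert not t.root.is_leaf
        assert t.root.threshold == 2.5
        assert t.root.left.klass == "A" and t.root.right.klass == "B"

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            tm.c45_train(pd.DataFrame({"x": [], "y": []}), "y", ["x"])

    def test_training_error_not_worse_than_majority_leaf(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = 60
            df = pd.DataFrame({
                "x": rng.normal(size=n), "z": rng.normal(size=n),
                "y": rng.choice(["A", "B"], size=n, p=[0.7, 0.3]),
            })
            t = tm.c45_train(df, "y", ["x", "z"], C45Params(min_leaf=2))
            err_tree = (t.predict(df) != df["y"]).mean()
            err_major = min((df["y"] == "A").mean(), (df["y"] == "B").mean())
            assert err_tree <= err_major + 1e-12

    def test_min_leaf_respected(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.normal(size=100),
                           "y": rng.choice(["A", "B"], size=100)})
        t = tm.c45_train(df, "y", ["x"], C45Params(min_leaf=10, pruning_cf=None))

        def min_support(node):
            if node.is_leaf:
                return node.support
            return min(min_support(node.left), min_support(node.right))

        assert min_support(t.root) >= 10

    def test_sklearn_agrees_on_clean_separation(self):
        """Independent cross-check: on perfectly separable data an
        entropy-based sklearn tree finds the same root threshold."""
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(-3, 0.5, 50), rng.normal(3, 0.5, 50)])
        y = np.array(["lo"] * 50 + ["hi"] * 50)
        df = pd.DataFrame({"x": x, "y": y})
        ours = tm.c45_train(df, "y", ["x"], C45Params(min_leaf=1, pruning_cf=None))
        sk = DecisionTreeClassifier(criterion="entropy", max_depth=1).fit(
            x.reshape(-1, 1), y)
        assert ours.root.threshold == pytest.approx(sk.tree_.threshold[0], abs=0.3)


class TestPruning:
    def test_pessimistic_error_zero_error_case(self):
        # E=0: upper limit is 1 - cf^(1/n)
        n, cf = 14, 0.25
        assert _pessimistic_errors(n, 0, cf) == pytest.approx(n * (1 - cf ** (1 / n)))

    def test_pruning_collapses_noise_splits(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.normal(size=200),
                           "y": rng.choice(["A", "B"], size=200, p=[0.9, 0.1])})
        pruned = tm.c45_train(df, "y", ["x"], C45Params(min_leaf=2, pruning_cf=0.25))
        unpruned = tm.c45_train(df, "y", ["x"], C45Params(min_leaf=2, pruning_cf=None))

        def n_leaves(node):
            return 1 if node.is_leaf else n_leaves(node.left) + n_leaves(node.right)

        assert n_leaves(pruned.root) <= n_leaves(unpruned.root)


class TestSerialization:
    def test_json_round_trip_classifies_identically(self, analysis_cohort):
        sub = analysis_cohort.head(200)
        g = tm.molecular_grouping(sub)
        t = sub.assign(label=g.reindex(sub["sample_id"]).values)
        tree = tm.c45_train(t, "label", tm.DEFAULT_FEATURES,
                            C45Params(min_leaf=2))
        clone = tm.DecisionTree.from_json(tree.to_json())
        pd.testing.assert_series_equal(tree.predict(sub), clone.predict(sub))

    def test_fixed_tree_json_preserves_scale_tags(self, tmp_path):
        path = tmp_path / "tree.json"
        tm.fixed_malignancy_tree().to_json(path)
        clone = tm.DecisionTree.from_json(path)
        assert clone.root.scale == "linear" and clone.root.threshold == 0.0918
        assert clone.root.left.scale == "log2"
        assert clone.classify(panel(hmga2=LOG2(0.1)))[0] == "Malignant"
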