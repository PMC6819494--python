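"""Decision trees over continuous marker levels.

Two trees published for this marker panel are shipped verbatim as data (the
malignancy tree over HMGA2 / miR-375 / miR-221 / miR-146b and the typing tree
over miR-375 / miR-146b / mtDNA), and a from-scratch C4.5-style trainer
re-induces trees from labelled marker tables: binary splits on continuous
attributes at midpoints between consecutive sorted distinct values, chosen by
gain ratio (information gain / split information) among splits with positive
gain, with optional pessimistic-error pruning at a confidence factor.

Every node carries an explicit ``scale`` tag because the published thresholds
mix conventions: most are linear 2^-dCq quantities (0.0918, 0.0105, 1.5362,
0.1721, 5.2514) or a linear copy ratio (5716.3013), while the malignancy-tree
miR-375 cutoff (-12.1213) can only be a log2 value.  Panels store miRNA and
HMGA2 levels on log2 scale and the mtDNA ratio linearly; thresholds are
converted to the storage scale at comparison time, never the data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import markers as mk


class UnclassifiableError(ValueError):
    """A marker needed on the realized tree path is missing."""


# ---------------------------------------------------------------------------
# structure

@dataclass
class TreeNode:
    # internal node fields
    marker: str | None = None
    scale: str | None = None        # "linear" or "log2"; scale of `threshold`
    threshold: float | None = None  # value < threshold -> left, >= -> right
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    # leaf fields
    klass: str | None = None
    purity: float | None = None
    support: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.klass is not None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"class": self.klass, "purity": self.purity, "support": self.support}
        return {
            "marker": self.marker,
            "scale": self.scale,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "class" in d:
            return cls(klass=d["class"], purity=d.get("purity"), support=d.get("support"))
        return cls(
            marker=d["marker"], scale=d["scale"], threshold=d["threshold"],
            left=cls.from_dict(d["left"]), right=cls.from_dict(d["right"]),
        )


@dataclass
class DecisionTree:
    root: TreeNode
    classes: tuple[str, ...]
    provenance: str = "trained"

    def classify(self, panel: Mapping) -> tuple[str, list[str]]:
        """Class of one sample plus the trace of visited nodes.

        ``panel`` is any mapping (dict, pandas Series / row) with the panel's
        ``level_*`` / ``mtdna_ratio`` columns.  A value equal to a node's
        threshold goes right (the ">= then ..." branch).
        """
        node, trace = self.root, []
        while not node.is_leaf:
            col = (mk.level_column(node.marker)
                   if node.marker in mk.PANEL_MARKERS else node.marker)
            value = panel.get(col)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise UnclassifiableError(
                    f"marker {node.marker} missing on the decision path"
                )
            thr = _threshold_in_storage_scale(node)
            right = float(value) >= thr
            trace.append(
                f"{node.marker} {'>=' if right else '<'} {node.threshold:.10g} ({node.scale})"
            )
            node = node.right if right else node.left
        trace.append(f"Diagnosis = {node.klass}")
        return node.klass, trace

    def predict(self, panels: pd.DataFrame) -> pd.Series:
        """Vector of classes for a panel table (raises if any row is
        unclassifiable)."""
        out = [self.classify(row)[0] for _, row in panels.iterrows()]
        return pd.Series(out, index=panels.index, name="predicted")

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"classes": list(self.classes), "provenance": self.provenance,
             "root": self.root.to_dict()},
            indent=2,
        )
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, text_or_path) -> "DecisionTree":
        try:
            d = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path, encoding="utf-8") as fh:
                d = json.load(fh)
        return cls(root=TreeNode.from_dict(d["root"]), classes=tuple(d["classes"]),
                   provenance=d.get("provenance", "trained"))


def _threshold_in_storage_scale(node: TreeNode) -> float:
    """Convert a node threshold to the panel's storage scale for its marker."""
    if node.marker not in mk.PANEL_MARKERS:
        return node.threshold  # ad-hoc feature: stored as-is
    storage = mk.storage_scale(node.marker)
    if node.scale == storage:
        return node.threshold
    if node.scale == "linear" and storage == "log2":
        if node.threshold <= 0:
            raise ValueError("linear threshold must be positive to compare on log2 scale")
        return math.log2(node.threshold)
    return math.exp2(node.threshold)  # log2 threshold vs linear storage


# ---------------------------------------------------------------------------
# the two published trees, verbatim (thresholds and leaf statistics as printed)

def _leaf(klass, purity, support):
    return TreeNode(klass=klass, purity=purity, support=support)


def fixed_malignancy_tree() -> DecisionTree:
    """Benign/malignant discrimination tree (HMGA2, miR-375, miR-221, miR-146b)."""
    root = TreeNode(
        marker="HMGA2", scale="linear", threshold=0.0918,
        right=_leaf("Malignant", 1.0, 214),
        left=TreeNode(
            marker="miR-375", scale="log2", threshold=-12.1213,
            right=_leaf("Malignant", 1.0, 37),
            left=TreeNode(
                marker="miR-221", scale="linear", threshold=0.0105,
                right=_leaf("Malignant", 1.0, 19),
                left=TreeNode(
                    marker="miR-146b", scale="linear", threshold=1.5362,
                    right=_leaf("Malignant", 8 / 9, 9),
                    left=_leaf("Benign", 211 / 214, 214),
                ),
            ),
        ),
    )
    return DecisionTree(root=root, classes=("Benign", "Malignant"),
                        provenance="fixed_paper_malignancy")


def fixed_typing_tree() -> DecisionTree:
    """Tumor typing tree (miR-375, miR-146b, mtDNA/nDNA ratio)."""
    root = TreeNode(
        marker="miR-375", scale="linear", threshold=5.2514,
        right=_leaf("MTC", 1.0, 18),
        left=TreeNode(
            marker="miR-146b", scale="linear", threshold=0.1721,
            right=_leaf("PTC", 162 / 164, 164),
            left=TreeNode(
                marker="mtDNA", scale="linear", threshold=5716.3013,
                right=_leaf("HCC", 1.0, 23),
                left=_leaf("FNMM", 0.960, 76),
            ),
        ),
    )
    return DecisionTree(root=root, classes=("FNMM", "HCC", "MTC", "PTC"),
                        provenance="fixed_paper_typing")


def apply_malignancy_tree(panel: Mapping) -> tuple[str, list[str]]:
    return fixed_malignancy_tree().classify(panel)


def apply_typing_tree(panel: Mapping) -> tuple[str, list[str]]:
    return fixed_typing_tree().classify(panel)


# ---------------------------------------------------------------------------
# C4.5-style induction

def entropy(class_counts) -> float:
    """Shannon entropy in bits of a class-count multiset; 0*log0 = 0."""
    counts = np.asarray(
        list(class_counts.values()) if isinstance(class_counts, Mapping)
        else class_counts, dtype=float,
    )
    if (counts < 0).any():
        raise ValueError("negative class count")
    total = counts.sum()
    if total == 0:
        raise ValueError("entropy of an empty node is undefined")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def best_split(values: Sequence[float], labels: Sequence, min_leaf: int = 1):
    """Best binary threshold on one continuous attribute by gain ratio.

    Candidates are midpoints between consecutive sorted distinct values;
    only splits with strictly positive information gain qualify; ties are
    broken toward the smaller threshold.  Returns ``(threshold, gain_ratio,
    gain)`` or ``None`` when no qualifying split exists (all values equal or
    labels pure).
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    order = np.argsort(v, kind="mergesort")
    v, y = v[order], y[order]
    n = len(v)
    classes, y_idx = np.unique(y, return_inverse=True)
    total_counts = np.bincount(y_idx, minlength=len(classes))
    h_total = entropy(total_counts)

    best = None
    left_counts = np.zeros(len(classes), dtype=int)
    for i in range(n - 1):
        left_counts[y_idx[i]] += 1
        if v[i] == v[i + 1]:
            continue
        n_l = i + 1
        n_r = n - n_l
        if n_l < min_leaf or n_r < min_leaf:
            continue
        right_counts = total_counts - left_counts
        gain = h_total - (n_l * entropy(left_counts) + n_r * entropy(right_counts)) / n
        if gain <= 1e-12:
            continue
        split_info = entropy([n_l, n_r])
        ratio = gain / split_info
        if best is None or ratio > best[1] + 1e-12:
            best = ((v[i] + v[i + 1]) / 2.0, ratio, gain)
    return best


@dataclass(frozen=True)
class C45Params:
    min_leaf: int = 5
    pruning_cf: float = 0.25          # confidence factor; None disables pruning
    max_depth: int | None = None
    missing_policy: str = "exclude"   # or "majority_branch"

    def __post_init__(self):
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.pruning_cf is not None and not 0.0 < self.pruning_cf <= 1.0:
            raise ValueError("pruning_cf must be in (0, 1]")
        if self.missing_policy not in ("exclude", "majority_branch"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")


def _pessimistic_errors(n: int, errors: int, cf: float) -> float:
    """C4.5 predicted error count: n times the one-sided upper binomial
    confidence limit on the error rate at confidence factor ``cf``."""
    if n == 0:
        return 0.0
    if errors >= n:
        return float(n)
    # upper limit u with P(Bin(n, u) <= errors) = cf
    u = stats.beta.ppf(1.0 - cf, errors + 1, n - errors)
    return float(n * u)


def _majority(y: np.ndarray, class_order: Sequence[str]) -> tuple[str, int]:
    vals, counts = np.unique(y, return_counts=True)
    by = dict(zip(vals, counts))
    top = max(by.values())
    # deterministic tie-break: first class in class_order among maxima
    for c in class_order:
        if by.get(c, 0) == top:
            return c, int(top)
    raise AssertionError("unreachable")


def c45_train(table: pd.DataFrame, target: str, features: Sequence[str],
              params: C45Params = C45Params()) -> DecisionTree:
    """Induce a decision tree from a labelled marker table.

    ``features`` are marker names (e.g. ``"HMGA2"``); their values are read
    from the panel's storage columns and trained thresholds carry the storage
    scale, so trained and fixed trees classify panels identically.
    """
    if len(table) == 0:
        raise ValueError("empty training table")
    y_all = table[target].to_numpy()
    class_order = tuple(sorted(pd.unique(y_all)))
    cols = {f: mk.level_column(f) if f in mk.PANEL_MARKERS else f for f in features}
    missing_cols = [c for c in cols.values() if c not in table]
    if missing_cols:
        raise ValueError(f"training table lacks feature columns: {missing_cols}")
    X = table[[cols[f] for f in features]].to_numpy(dtype=float)
    feat_names = list(features)
    scales = [mk.storage_scale(f) if f in mk.PANEL_MARKERS else "linear"
              for f in features]

    def build(rows: np.ndarray, depth: int) -> TreeNode:
        y = y_all[rows]
        klass, top = _majority(y, class_order)
        n = len(rows)
        if top == n or n < 2 * params.min_leaf or (
            params.max_depth is not None and depth >= params.max_depth
        ):
            return TreeNode(klass=klass, purity=top / n, support=n)
        best = None  # (ratio, j, threshold)
        for j in range(len(feat_names)):
            vals = X[rows, j]
            ok = ~np.isnan(vals)
            if ok.sum() < 2 * params.min_leaf:
                continue
            cand = best_split(vals[ok], y[ok], min_leaf=params.min_leaf)
            if cand is None:
                continue
            thr, ratio, _ = cand
            if best is None or ratio > best[0] + 1e-12:
                best = (ratio, j, thr)
        if best is None:
            return TreeNode(klass=klass, purity=top / n, support=n)
        _, j, thr = best
        vals = X[rows, j]
        missing = np.isnan(vals)
        go_right = vals >= thr
        if params.missing_policy == "majority_branch":
            right_bigger = (go_right & ~missing).sum() >= ((~go_right) & ~missing).sum()
            go_right = np.where(missing, right_bigger, go_right)
            left_rows = rows[~go_right]
            right_rows = rows[go_right]
        else:  # exclude
            left_rows = rows[~go_right & ~missing]
            right_rows = rows[go_right & ~missing]
        node = TreeNode(
            marker=feat_names[j], scale=scales[j], threshold=float(thr),
            left=build(left_rows, depth + 1), right=build(right_rows, depth + 1),
        )
        return node

    root = build(np.arange(len(table)), 0)
    if params.pruning_cf is not None:
        root = _prune(root, params.pruning_cf, class_order)
    return DecisionTree(root=root, classes=class_order, provenance="trained")


def _prune(node: TreeNode, cf: float, class_order) -> TreeNode:
    """Bottom-up subtree replacement by pessimistic error estimates."""
    if node.is_leaf:
        return node
    node.left = _prune(node.left, cf, class_order)
    node.right = _prune(node.right, cf, class_order)

    def leaf_stats(nd):
        if nd.is_leaf:
            n = nd.support
            errs = round(n * (1.0 - nd.purity))
            yield n, errs, nd.klass
        else:
            yield from leaf_stats(nd.left)
            yield from leaf_stats(nd.right)

    stats_ = list(leaf_stats(node))
    subtree_err = sum(_pessimistic_errors(n, e, cf) for n, e, _ in stats_)
    n_total = sum(n for n, _, _ in stats_)
    # class counts if collapsed: majority-class tally over the leaves
    class_n = {}
    for n, e, k in stats_:
        class_n[k] = class_n.get(k, 0) + (n - e)
    if not class_n or n_total == 0:
        return node
    best_class = max(class_order, key=lambda c: class_n.get(c, 0))
    correct = class_n.get(best_class, 0)
    leaf_err = _pessimistic_errors(n_total, n_total - correct, cf)
    if leaf_err <= subtree_err + 0.1:
        return TreeNode(klass=best_class, purity=correct / n_total, support=n_total)
    return node


# ---------------------------------------------------------------------------

def render_tree(tree: DecisionTree) -> str:
    """Indented text rendering in the published listing style, e.g.
    ``then Diagnosis = Malignant (88.9% of 9 examples)``."""
    lines: list[str] = []

    def fmt_leaf(nd: TreeNode) -> str:
        pur = "" if nd.purity is None else f" ({nd.purity * 100:.1f}% of {nd.support} examples)"
        return f"then Diagnosis = {nd.klass}{pur}"

    def walk(nd: TreeNode, indent: int):
        pad = "    " * indent
        for child, op in ((nd.left, "<"), (nd.right, ">=")):
            head = f"{pad}{nd.marker} {op} {nd.threshold:.10g}"
            if child.is_leaf:
                lines.append(f"{head} {fmt_leaf(child)}")
            else:
                lines.append(head)
                walk(child, indent + 1)

    if tree.root.is_leaf:
        lines.append(fmt_leaf(tree.root))
    else:
        walk(tree.root, 0)
    return "\n".join(lines)


def render_leaf(klass: str, correct: int, support: int) -> str:
    """One leaf line, e.g. ``Diagnosis = Malignant (88.9% of 9 examples)``."""
    return f"Diagnosis = {klass} ({correct / support * 100:.1f}% of {support} examples)"
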