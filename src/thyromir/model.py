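"""Model/Results interface to the tree classifier.

`DecisionTreeModel` holds a labelled marker table and training settings; its
`fit()` returns a `DecisionTreeResults` carrying the induced tree, training
confusion matrix and per-class diagnostics, with `summary()` for a printable
report and `cross_validate()` for stratified k-fold accuracy estimates.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .metrics import (ConfusionMatrix, CVResult, kfold_cv, per_class_metrics,
                      total_error)
from .tree import C45Params, DecisionTree, c45_train, render_tree

DEFAULT_FEATURES = ("HMGA2", "miR-375", "miR-221", "miR-146b", "mtDNA")


class DecisionTreeModel:
    """C4.5-style decision-tree model over continuous marker levels."""

    def __init__(self, data: pd.DataFrame, target: str,
                 features: Sequence[str] = DEFAULT_FEATURES,
                 params: C45Params | None = None):
        if target not in data:
            raise ValueError(f"target column {target!r} not in table")
        self.data = data.reset_index(drop=True)
        self.target = target
        self.features = tuple(features)
        self.params = params or C45Params()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, target: str,
                       features: Sequence[str] = DEFAULT_FEATURES,
                       **params_kw) -> "DecisionTreeModel":
        params = C45Params(**params_kw) if params_kw else None
        return cls(data, target, features, params)

    def fit(self) -> "DecisionTreeResults":
        tree = c45_train(self.data, self.target, self.features, self.params)
        return DecisionTreeResults(self, tree)


class DecisionTreeResults:
    """Fitted tree plus training diagnostics."""

    def __init__(self, model: DecisionTreeModel, tree: DecisionTree):
        self.model = model
        self.tree = tree
        pred = tree.predict(model.data)
        self.training_confusion = ConfusionMatrix.from_labels(
            model.data[model.target], pred, tree.classes
        )
        self.total_error = total_error(self.training_confusion)
        self.per_class = per_class_metrics(self.training_confusion)

    def predict(self, panels: pd.DataFrame) -> pd.Series:
        return self.tree.predict(panels)

    def cross_validate(self, k: int = 5, seed: int = 0,
                       group_by: str = "sample") -> CVResult:
        return kfold_cv(self.model.data, self.model.target, self.model.features,
                        self.model.params, k=k, seed=seed, group_by=group_by)

    def summary(self) -> str:
        lines = [
            "Decision-tree classifier",
            f"  target:   {self.model.target}",
            f"  features: {', '.join(self.model.features)}",
            f"  n:        {len(self.model.data)}",
            f"  total training error: {self.total_error:.4f}",
            "",
            "Per-class training metrics (one-vs-rest):",
            self.per_class.to_string(float_format=lambda x: f"{x:.4f}"),
            "",
            "Tree:",
            render_tree(self.tree),
        ]
        return "\n".join(lines)
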