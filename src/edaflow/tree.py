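"""CART-style binary decision tree with Gini splitting.

The tree is grown by exhaustively scanning every feature and every
midpoint threshold, choosing the split with the largest weighted Gini
impurity decrease.  Growth stops at a node that is pure or that holds
fewer than 20% of all samples that entered ``grow`` (so a node below the
bound is never split), or when no split separates the values.  No pruning
is applied.

A fixed two-threshold tree over SDSC (cut 4.4830) and SKSC (cut 3.1102)
is provided as a ready-made lightweight classifier for the calm/distress
task; its branch orientation and leaf classes are configurable because
only the two thresholds are pinned down.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import (NEGATIVE, POSITIVE, confusion_metrics,
                         stratified_fold_indices)

__all__ = ["TreeNode", "TreeModel", "gini", "best_split", "grow",
           "reference_tree", "predict", "tree_cv"]


def gini(labels: Sequence[str], method: Literal["impurity", "lorenz"] = "impurity") -> float:
    """Gini index of a node's label multiset.

    ``impurity`` is the standard CART criterion ``1 - sum_c p_c^2``
    (range [0, 0.5] for two classes).  ``lorenz`` is an alternative
    two-class reading based on the Lorenz-curve Gini coefficient,
    rescaled to ``2 * min(p, 1-p)`` so a pure node is 0 and a 50/50 node
    is 1; it exists because the Lorenz formulation is sometimes quoted
    with the (0, 1] range for impure nodes, which the standard impurity
    cannot reach.  Both are 0 exactly on a pure node.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty node")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    if method == "impurity":
        return float(1.0 - np.sum(p ** 2))
    if method == "lorenz":
        if len(p) > 2:
            raise ValueError("lorenz variant is defined for two classes")
        pmin = 0.0 if len(p) == 1 else float(p.min())
        return 2.0 * pmin
    raise ValueError("method must be 'impurity' or 'lorenz'")


@dataclass
class TreeNode:
    """One node: either an internal split (feature, threshold) or a leaf."""

    n_samples: int
    gini: float
    feature: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    klass: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return self.klass is not None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf": self.klass, "n": self.n_samples, "gini": self.gini}
        return {"feature": self.feature, "threshold": self.threshold,
                "n": self.n_samples, "gini": self.gini,
                "left": self.left.to_dict(), "right": self.right.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "leaf" in d:
            return cls(n_samples=d.get("n", 0), gini=d.get("gini", 0.0), klass=d["leaf"])
        return cls(n_samples=d.get("n", 0), gini=d.get("gini", 0.0),
                   feature=d["feature"], threshold=d["threshold"],
                   left=cls.from_dict(d["left"]), right=cls.from_dict(d["right"]))


@dataclass
class TreeModel:
    root: TreeNode
    min_fraction: float = 0.20
    n_samples: int = 0
    seed: Optional[int] = None
    split_history: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({"min_fraction": self.min_fraction, "n_samples": self.n_samples,
                           "seed": self.seed, "root": self.root.to_dict()}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TreeModel":
        d = json.loads(text)
        return cls(root=TreeNode.from_dict(d["root"]), min_fraction=d.get("min_fraction", 0.2),
                   n_samples=d.get("n_samples", 0), seed=d.get("seed"))

    def features_used(self) -> set[str]:
        out: set[str] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.add(node.feature)
                stack.extend([node.left, node.right])
        return out


def best_split(
    X: pd.DataFrame,
    y: Sequence[str],
    features: Optional[Iterable[str]] = None,
) -> Optional[tuple[str, float, float]]:
    """Exhaustive best (feature, threshold, impurity decrease) for one node.

    Thresholds are the midpoints between consecutive sorted unique values;
    a row goes left when ``value <= threshold``.  The split maximising the
    weighted Gini impurity decrease wins; ties break on feature name order
    and then on the lower threshold.  Returns None when no feature admits a
    valid split.
    """
    y = np.asarray(y)
    n = len(y)
    if n < 2:
        return None
    parent = gini(y)
    feats = sorted(features) if features is not None else sorted(X.columns)
    best: Optional[tuple[str, float, float]] = None
    for feat in feats:
        v = X[feat].to_numpy(float)
        uniq = np.unique(v)
        if len(uniq) < 2:
            continue
        for thr in (uniq[:-1] + uniq[1:]) / 2.0:
            left = v <= thr
            decrease = parent - (left.sum() * gini(y[left]) + (~left).sum() * gini(y[~left])) / n
            if best is None or decrease > best[2] + 1e-12:
                best = (feat, float(thr), float(decrease))
    return best


def _majority(y: np.ndarray) -> str:
    n_pos = int(np.sum(y == POSITIVE))
    # ties go to distress: missing a distress case is the costlier error
    return POSITIVE if n_pos * 2 >= len(y) else NEGATIVE


def grow(
    table: pd.DataFrame,
    min_fraction: float = 0.20,
    features: Optional[Iterable[str]] = None,
    seed: Optional[int] = None,
) -> TreeModel:
    """Grow a tree on a labelled feature table (``condition`` column = labels).

    A node becomes a leaf when it is pure, when it holds fewer than
    ``min_fraction`` of all samples passed to this call, or when no valid
    split exists.  Leaf class is the majority label (ties to distress).
    """
    if table.empty:
        raise ValueError("empty training table")
    y_all = table["condition"].to_numpy()
    if len(set(y_all)) < 2:
        raise ValueError("need both classes at the root")
    feats = sorted(features) if features is not None else sorted(
        c for c in table.columns if c not in ("condition", "subject_id"))
    n_total = len(table)
    min_samples = min_fraction * n_total
    history: list[dict] = []

    def build(idx: np.ndarray) -> TreeNode:
        y = y_all[idx]
        node_gini = gini(y)
        if node_gini == 0.0 or len(idx) < min_samples:
            return TreeNode(n_samples=len(idx), gini=node_gini, klass=_majority(y))
        split = best_split(table.iloc[idx][feats], y, feats)
        if split is None or split[2] <= 0:
            return TreeNode(n_samples=len(idx), gini=node_gini, klass=_majority(y))
        feat, thr, dec = split
        history.append({"feature": feat, "threshold": thr, "decrease": dec, "n": len(idx)})
        mask = table.iloc[idx][feat].to_numpy(float) <= thr
        return TreeNode(n_samples=len(idx), gini=node_gini, feature=feat, threshold=thr,
                        left=build(idx[mask]), right=build(idx[~mask]))

    root = build(np.arange(n_total))
    return TreeModel(root=root, min_fraction=min_fraction, n_samples=n_total,
                     seed=seed, split_history=history)


def reference_tree(flip: bool = False) -> TreeModel:
    """The fixed two-threshold temporal/morphological tree.

    Root splits on SDSC at 4.4830; the low-SDSC subgroup is refined on
    SKSC at 3.1102.  Default orientation: high SDSC predicts distress, and
    within the low-SDSC subgroup high SKSC predicts distress.  ``flip``
    inverts every leaf class.  Comparisons are ``<=`` left / ``>`` right.
    """
    lo, hi = (POSITIVE, NEGATIVE) if flip else (NEGATIVE, POSITIVE)
    sksc = TreeNode(n_samples=0, gini=0.0, feature="SKSC", threshold=3.1102,
                    left=TreeNode(0, 0.0, klass=lo), right=TreeNode(0, 0.0, klass=hi))
    root = TreeNode(n_samples=0, gini=0.0, feature="SDSC", threshold=4.4830,
                    left=sksc, right=TreeNode(0, 0.0, klass=hi))
    return TreeModel(root=root, min_fraction=0.20)


def tree_cv(
    table: pd.DataFrame,
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
    min_fraction: float = 0.20,
    features: Optional[Iterable[str]] = None,
    group_by_subject: bool = False,
) -> dict[str, float]:
    """Repeated stratified k-fold CV of the grown tree.

    Uses the same fold machinery as the single-feature evaluation, so tree
    and threshold classifiers can be compared on identical partitions.
    Returns learning- and test-phase Se/Sp/Acc in percent.  A tree grown
    with only the pure/20% stopping rules fits its training folds far
    better than it generalises; both phases are reported so the gap is
    visible.
    """
    feats = list(features) if features is not None else [
        c for c in table.columns if c not in ("condition", "subject_id", "sex")]
    sums = np.zeros(6)
    n_eval = 0
    for rep in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(rep,)))
        folds = stratified_fold_indices(table, k, rng, group_by_subject)
        for fold in range(k):
            train = table.loc[folds != fold]
            test = table.loc[folds == fold]
            if test.empty:
                continue
            model = grow(train[feats + ["condition"]], min_fraction=min_fraction)
            learn = confusion_metrics(predict(model, train)[0], train["condition"].to_numpy())
            t = confusion_metrics(predict(model, test)[0], test["condition"].to_numpy())
            sums += [*learn, *(np.nan_to_num(x) for x in t)]
            n_eval += 1
    keys = ["learn_se", "learn_sp", "learn_acc", "test_se", "test_sp", "test_acc"]
    return dict(zip(keys, (sums / n_eval).tolist()))


def predict(model: TreeModel, rows: pd.DataFrame) -> tuple[np.ndarray, list[list[str]]]:
    """Route rows through the tree; returns labels and per-row leaf paths.

    A feature used by the model but absent from ``rows`` is a schema error,
    never silently imputed.
    """
    missing = model.features_used() - set(rows.columns)
    if missing:
        raise KeyError(f"rows are missing model features: {sorted(missing)}")
    labels = []
    paths = []
    for _, row in rows.iterrows():
        node = model.root
        path = []
        while not node.is_leaf:
            v = float(row[node.feature])
            side = "<=" if v <= node.threshold else ">"
            path.append(f"{node.feature}{side}{node.threshold:g}")
            node = node.left if v <= node.threshold else node.right
        path.append(node.klass)
        labels.append(node.klass)
        paths.append(path)
    return np.asarray(labels), paths
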