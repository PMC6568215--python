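"""From-scratch CART classifier and the feature-ablation harness used to
validate latency + errors as escape-strategy predictors.

The learner makes greedy binary splits minimizing weighted Gini impurity,
with candidate thresholds at midpoints of sorted unique feature values.
It is fully deterministic: ties are broken by lowest feature name, then
lowest threshold; leaf labels break count ties lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ValidationError

FEATURE_NAMES = (
    "latency_s",
    "n_errors",
    "rotations",
    "distance_cm",
    "heading_to_exit_deg",
    "meander_turns",
    "mean_speed_cm_s",
)


@dataclass
class TreeNode:
    """Either an internal split (feature, threshold, children) or a leaf
    (label + class counts).  Split rule: go left iff ``x[feature] <= threshold``."""

    feature: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    label: Optional[str] = None
    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def predict_one(self, x: Mapping[str, float]) -> str:
        node = self
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node.label

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def to_text(self, indent: int = 0) -> str:
        pad = "  " * indent
        if self.is_leaf:
            counts = ", ".join(f"{k}={v}" for k, v in sorted(self.counts.items()))
            return f"{pad}leaf: {self.label} ({counts})"
        return "\n".join(
            [
                f"{pad}{self.feature} <= {self.threshold:.6g}",
                self.left.to_text(indent + 1),
                self.right.to_text(indent + 1),
            ]
        )


def _as_matrix(
    data: Union[pd.DataFrame, Sequence[Mapping[str, float]]],
    features: Sequence[str],
) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        return data[list(features)].to_numpy(dtype=float)
    return np.array([[row[f] for f in features] for row in data], dtype=float)


def _labels_array(labels: Sequence) -> np.ndarray:
    return np.array([getattr(l, "value", l) for l in labels], dtype=object)


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p * p).sum())


def _majority(labels: np.ndarray) -> Tuple[str, Dict[str, int]]:
    values, counts = np.unique(labels, return_counts=True)
    order = np.lexsort((values, -counts))  # by count desc, then name asc
    return str(values[order[0]]), {str(v): int(c) for v, c in zip(values, counts)}


def fit_cart(
    data: Union[pd.DataFrame, Sequence[Mapping[str, float]]],
    labels: Sequence,
    feature_subset: Optional[Sequence[str]] = None,
    max_depth: int = 5,
    min_leaf: int = 5,
) -> TreeNode:
    """Fit a Gini-impurity decision tree on the given feature subset."""
    if feature_subset is None:
        if isinstance(data, pd.DataFrame):
            feature_subset = [c for c in FEATURE_NAMES if c in data.columns]
        else:
            feature_subset = list(FEATURE_NAMES)
    features = sorted(set(feature_subset))
    if not features:
        raise ValidationError("feature subset must be nonempty")
    y = _labels_array(labels)
    X = _as_matrix(data, features)
    if len(X) != len(y):
        raise ValidationError("data and labels length mismatch")
    if len(y) < max(1, min_leaf):
        raise ValidationError(f"need at least min_leaf={min_leaf} samples")
    if not np.all(np.isfinite(X)):
        raise ValidationError("features must be finite")
    return _grow(X, y, features, depth=0, max_depth=max_depth, min_leaf=min_leaf)


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    features: List[str],
    depth: int,
    max_depth: int,
    min_leaf: int,
) -> TreeNode:
    label, counts = _majority(y)
    classes = np.unique(y)
    if depth >= max_depth or len(classes) == 1 or len(y) < 2 * min_leaf:
        return TreeNode(label=label, counts=counts)

    best = None  # (impurity, feature_index, threshold)
    parent_impurity = _gini(np.unique(y, return_counts=True)[1])
    n = len(y)
    y_codes = np.searchsorted(classes, y)
    for fi, fname in enumerate(features):
        col = X[:, fi]
        order = np.argsort(col, kind="mergesort")
        cs = col[order]
        boundary = np.nonzero(cs[:-1] < cs[1:])[0]  # split between i and i+1
        if boundary.size == 0:
            continue
        onehot = np.zeros((n, len(classes)))
        onehot[np.arange(n), y_codes[order]] = 1.0
        cum = np.cumsum(onehot, axis=0)
        nl = boundary + 1.0
        nr = n - nl
        valid = (nl >= min_leaf) & (nr >= min_leaf)
        if not valid.any():
            continue
        left_counts = cum[boundary]
        right_counts = cum[-1] - left_counts
        gl = 1.0 - ((left_counts / nl[:, None]) ** 2).sum(axis=1)
        gr = 1.0 - ((right_counts / nr[:, None]) ** 2).sum(axis=1)
        w = (nl * gl + nr * gr) / n
        w = np.where(valid, w, np.inf)
        # argmin keeps the lowest threshold on ties; strict '<' across
        # features keeps the lowest feature name
        bi = int(np.argmin(w))
        if best is None or w[bi] < best[0] - 1e-12:
            thr = float((cs[boundary[bi]] + cs[boundary[bi] + 1]) / 2.0)
            best = (float(w[bi]), fi, thr)
    if best is None or best[0] >= parent_impurity - 1e-12:
        return TreeNode(label=label, counts=counts)

    _, fi, thr = best
    mask = X[:, fi] <= thr
    node = TreeNode(feature=features[fi], threshold=thr, counts=counts)
    node.left = _grow(X[mask], y[mask], features, depth + 1, max_depth, min_leaf)
    node.right = _grow(X[~mask], y[~mask], features, depth + 1, max_depth, min_leaf)
    return node


def predict(
    tree: TreeNode, data: Union[pd.DataFrame, Sequence[Mapping[str, float]]]
) -> List[str]:
    if isinstance(data, pd.DataFrame):
        rows = data.to_dict("records")
    else:
        rows = list(data)
    return [tree.predict_one(r) for r in rows]


def misclassification(
    tree: TreeNode,
    data: Union[pd.DataFrame, Sequence[Mapping[str, float]]],
    labels: Sequence,
) -> float:
    """Fraction of mismatched predictions, in [0, 1]."""
    y = _labels_array(labels)
    preds = np.array(predict(tree, data), dtype=object)
    if len(preds) != len(y):
        raise ValidationError("data and labels length mismatch")
    return float((preds != y).mean())


def kfold_misclassification(
    data: pd.DataFrame,
    labels: Sequence,
    feature_subset: Optional[Sequence[str]] = None,
    k: int = 10,
    seed: int = 0,
    max_depth: int = 5,
    min_leaf: int = 5,
) -> float:
    """Seeded k-fold estimate reported alongside the resubstitution rate."""
    y = _labels_array(labels)
    n = len(y)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    errors = 0
    for fold in folds:
        if len(fold) == 0:
            continue
        train = np.setdiff1d(order, fold)
        tree = fit_cart(
            data.iloc[train],
            y[train],
            feature_subset=feature_subset,
            max_depth=max_depth,
            min_leaf=min_leaf,
        )
        preds = np.array(predict(tree, data.iloc[fold]), dtype=object)
        errors += int((preds != y[fold]).sum())
    return errors / n


# --------------------------------------------------------------------------
# ablation


@dataclass(frozen=True)
class AblationRow:
    excluded: Tuple[str, ...]
    misclassification_rate: float
    predicted_classes: Tuple[str, ...]
    predicts_futile: bool


@dataclass
class AblationReport:
    rows: List[AblationRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "excluded": "+".join(r.excluded) if r.excluded else "none",
                    "misclassification_rate": r.misclassification_rate,
                    "predicted_classes": "+".join(r.predicted_classes),
                    "predicts_futile": r.predicts_futile,
                }
                for r in self.rows
            ]
        )

    def write(self, sink) -> None:
        self.to_frame().to_csv(sink, index=False)


DEFAULT_EXCLUSION_LADDER: Tuple[Tuple[str, ...], ...] = (
    (),
    ("n_errors",),
    ("latency_s",),
    ("latency_s", "n_errors"),
)


def ablation_study(
    data: Union[pd.DataFrame, Sequence[Mapping[str, float]]],
    labels: Sequence,
    exclusions: Optional[Sequence[Sequence[str]]] = None,
    max_depth: int = 5,
    min_leaf: int = 5,
) -> AblationReport:
    """Refit the tree with feature sets excluded and record the resulting
    resubstitution misclassification rate and whether the futile class is
    ever predicted."""
    if exclusions is None:
        exclusions = DEFAULT_EXCLUSION_LADDER
    if isinstance(data, pd.DataFrame):
        all_features = [c for c in FEATURE_NAMES if c in data.columns]
    else:
        all_features = list(FEATURE_NAMES)
    rows = []
    for excl in exclusions:
        excl = tuple(sorted(excl))
        subset = [f for f in all_features if f not in excl]
        if not subset:
            raise ValidationError(f"exclusion {excl} leaves no features")
        tree = fit_cart(
            data, labels, feature_subset=subset, max_depth=max_depth, min_leaf=min_leaf
        )
        rate = misclassification(tree, data, labels)
        preds = sorted(set(predict(tree, data)))
        rows.append(
            AblationRow(
                excluded=excl,
                misclassification_rate=rate,
                predicted_classes=tuple(preds),
                predicts_futile="futile" in preds,
            )
        )
    return AblationReport(rows=rows)
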