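"""Information-gain attribute ranking and random-forest classification.

Information gain of an attribute is the reduction in behaviour-label
entropy after conditioning on the discretised attribute,

    IG = H(labels) - H(labels | bin(attribute))   [bits],

with the attribute discretised by Fayyad-Irani supervised binary
splitting under the MDL stopping criterion (equal-frequency binning is
available as an alternative).  Gains over the 99 attributes are ranked
and banded by the quartile rule: low when gain <= lower quartile, high
when gain >= upper quartile, medium otherwise; where the two quartiles
coincide, ``high`` takes precedence.

Three ranking tasks are supported:

* A — sit vs stand vs walk (labels as-is);
* B — static vs walk (sit and stand merged into ``static``);
* C — sit vs stand (walk rows dropped).

Classification uses a bagged random forest of unpruned trees, by default
100 trees with floor(log2 M) + 1 candidate attributes per split (7 for
M = 99) — the classic WEKA-style defaults.  Tree count is tuned by
stratified 10-fold cross-validation over {100, 300, 500}, ties resolved
toward fewer trees (the computationally cheapest model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from . import errors
from .names import FEATURE_NAMES

DEFAULT_N_TREES = 100
DEFAULT_TREE_GRID = (100, 300, 500)
TASKS = ("A", "B", "C")


# --- entropy / MDL discretisation --------------------------------------


def _h(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a count vector."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def mdlp_thresholds(values: np.ndarray, labels: np.ndarray) -> list[float]:
    """Cut thresholds from Fayyad-Irani entropy-minimising binary splitting.

    Recursively picks the cut minimising class-entropy and keeps it only
    when its gain clears the MDL criterion; returns the sorted thresholds
    (possibly empty).  Cuts fall midway between adjacent distinct values,
    so the result is invariant under strictly increasing transforms of
    ``values`` up to the same bin memberships.
    """
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    _, y = np.unique(labels, return_inverse=True)
    y = y[order]
    n_classes = y.max() + 1
    onehot = np.zeros((len(y), n_classes), dtype=np.int64)
    onehot[np.arange(len(y)), y] = 1
    cum = np.vstack([np.zeros(n_classes, dtype=np.int64), np.cumsum(onehot, axis=0)])
    thresholds: list[float] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2:
            return
        total = cum[hi] - cum[lo]
        h_s = _h(total)
        if h_s == 0.0:
            return
        cand = lo + 1 + np.flatnonzero(v[lo + 1 : hi] != v[lo : hi - 1])
        if len(cand) == 0:
            return
        left = cum[cand] - cum[lo]
        right = total - left
        nl = left.sum(axis=1)
        nr = n - nl
        h_left = np.array([_h(c) for c in left])
        h_right = np.array([_h(c) for c in right])
        weighted = (nl * h_left + nr * h_right) / n
        best = int(np.argmin(weighted))
        gain = h_s - weighted[best]
        k = int((total > 0).sum())
        k1 = int((left[best] > 0).sum())
        k2 = int((right[best] > 0).sum())
        delta = math.log2(3**k - 2) - (k * h_s - k1 * h_left[best] - k2 * h_right[best])
        if gain <= (math.log2(n - 1) + delta) / n:
            return
        cut_idx = int(cand[best])
        thresholds.append(0.5 * (v[cut_idx - 1] + v[cut_idx]))
        recurse(lo, cut_idx)
        recurse(cut_idx, hi)

    recurse(0, len(v))
    return sorted(thresholds)


def info_gain(
    attribute: np.ndarray,
    labels: np.ndarray,
    method: str = "mdl",
    n_bins: int = 10,
) -> float:
    """Information gain (bits) of one attribute for the label column.

    ``method`` is ``"mdl"`` (supervised Fayyad-Irani discretisation; an
    attribute the MDL criterion cannot usefully split contributes 0) or
    ``"equal-frequency"`` (unsupervised ``n_bins`` quantile bins).
    """
    attribute = np.asarray(attribute, dtype=float)
    labels = np.asarray(labels)
    if len(attribute) != len(labels):
        raise errors.LengthMismatch("attribute and labels differ in length")
    classes, y = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise errors.ConstantLabels("need >= 2 distinct labels")
    if method == "mdl":
        cuts = mdlp_thresholds(attribute, labels)
        bins = np.searchsorted(cuts, attribute, side="right")
    elif method == "equal-frequency":
        edges = np.unique(np.quantile(attribute, np.linspace(0, 1, n_bins + 1)[1:-1]))
        bins = np.searchsorted(edges, attribute, side="right")
    else:
        raise ValueError(f"unknown method {method!r}")
    n = len(y)
    h_labels = _h(np.bincount(y))
    h_cond = 0.0
    for b in np.unique(bins):
        mask = bins == b
        h_cond += mask.sum() / n * _h(np.bincount(y[mask]))
    return max(0.0, h_labels - h_cond)


# --- ranking and banding -----------------------------------------------


def task_labels(behaviour: pd.Series, task: str) -> tuple[pd.Series, pd.Series]:
    """(labels, row mask) for a ranking task; B merges sit/stand into
    ``static``, C restricts to sit and stand rows."""
    if task == "A":
        return behaviour, pd.Series(True, index=behaviour.index)
    if task == "B":
        return behaviour.where(behaviour == "walk", "static"), pd.Series(
            True, index=behaviour.index
        )
    if task == "C":
        return behaviour, behaviour.isin(["sit", "stand"])
    raise ValueError(f"task must be one of {TASKS}")


def rank_and_band(gains: pd.Series, task: str = "A") -> pd.DataFrame:
    """Rank 99 attribute gains and band them by the quartile rule.

    Returns a frame indexed by attribute with columns gain, rank (1 =
    highest gain), band (low/medium/high) and task.
    """
    if len(gains) != 99:
        raise ValueError(f"expected 99 gains, got {len(gains)}")
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}")
    lq, uq = np.percentile(gains.to_numpy(), [25, 75])
    band = np.where(
        gains >= uq, "high", np.where(gains <= lq, "low", "medium")
    )
    rank = gains.rank(ascending=False, method="first").astype(int)
    return pd.DataFrame(
        {"gain": gains, "rank": rank, "band": band, "task": task}
    ).sort_values("rank")


def gain_ranking(
    table: pd.DataFrame, task: str = "A", method: str = "mdl"
) -> pd.DataFrame:
    """Compute per-attribute information gains for a ranking task and band
    them; ``table`` is a feature table with behaviour labels."""
    labels, mask = task_labels(table["behaviour"], task)
    labels = labels[mask].to_numpy()
    gains = pd.Series(
        {
            name: info_gain(table.loc[mask, name].to_numpy(), labels, method=method)
            for name in FEATURE_NAMES
        }
    )
    return rank_and_band(gains, task)


# --- random forest -----------------------------------------------------


def _features_per_split(n_attributes: int) -> int:
    return int(math.floor(math.log2(n_attributes))) + 1


@dataclass
class ForestModel:
    """A trained random forest plus its training metadata."""

    forest: RandomForestClassifier
    attributes: list[str]
    classes: list[str]
    n_trees: int
    seed: int
    cv_results: dict = field(default_factory=dict)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.forest.predict(table[self.attributes].to_numpy())

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ForestModel":
        return joblib.load(path)


def train_forest(
    train: pd.DataFrame,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    attributes: list[str] | None = None,
) -> ForestModel:
    """Fit a bagged forest of unpruned trees on a training feature table.

    ``attributes`` restricts the attribute set (default all 99); per-split
    candidates are floor(log2 M) + 1 and bootstrap samples are size n.
    """
    attributes = list(attributes or FEATURE_NAMES)
    if len(train) == 0:
        raise errors.TooFewRows("empty training table")
    y = train["behaviour"].to_numpy()
    classes = sorted(set(y))
    if len(classes) < 2:
        raise errors.SingleClassTraining(f"single class {classes}")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=_features_per_split(len(attributes)),
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(train[attributes].to_numpy(), y)
    return ForestModel(
        forest=forest, attributes=attributes, classes=classes, n_trees=n_trees, seed=seed
    )


def cross_validate(
    train: pd.DataFrame,
    k: int = 10,
    n_trees_grid: tuple[int, ...] = DEFAULT_TREE_GRID,
    seed: int = 0,
    attributes: list[str] | None = None,
) -> ForestModel:
    """Stratified k-fold CV over the tree-count grid; returns the selected
    model refit on all rows, with per-setting accuracies attached.

    The best mean accuracy wins; ties go to the smaller forest.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(train) < k:
        raise errors.TooFewRows(f"{len(train)} rows < {k} folds")
    attributes = list(attributes or FEATURE_NAMES)
    X = train[attributes].to_numpy()
    y = train["behaviour"].to_numpy()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    results: dict[int, float] = {}
    for n_trees in n_trees_grid:
        correct = 0
        for train_idx, test_idx in folds:
            forest = RandomForestClassifier(
                n_estimators=n_trees,
                max_features=_features_per_split(len(attributes)),
                bootstrap=True,
                random_state=seed,
                n_jobs=1,
            )
            forest.fit(X[train_idx], y[train_idx])
            correct += (forest.predict(X[test_idx]) == y[test_idx]).sum()
        results[n_trees] = correct / len(y)
    best = min(results, key=lambda nt: (-results[nt], nt))
    model = train_forest(train, n_trees=best, seed=seed, attributes=attributes)
    model.cv_results = {"accuracy": results, "selected_n_trees": best, "k": k}
    return model
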