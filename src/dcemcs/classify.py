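"""Base classifiers for the two channels.

Morphological channel: an axis-aligned binary decision tree grown by
information gain, unpruned by default (confidence factor 0.25 retained for
the optional pessimistic-pruning variant), with Laplace-smoothed leaf
probabilities (count + 1)/(n + 2).

Dynamic channel: a Gaussian naive-Bayes classifier over per-voxel dynamic
features; every suspicious voxel in a lesion is classified and the lesion's
dynamic-channel probabilities are the voxel-vote fractions
D_m = n_m/N, D_b = n_b/N.

Both emit a ProbPair (p_malignant, p_benign) summing to one; decision ties
resolve to malignant (favouring sensitivity).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.model_selection import StratifiedKFold

from .dce_io import VOI
from .features import DynFeatures

__all__ = [
    "TreeConfig",
    "NBConfig",
    "ProbPair",
    "DecisionTreeModel",
    "NaiveBayesModel",
    "train_tree",
    "train_nb",
    "predict_proba",
    "voxel_dynamic_probabilities",
    "cross_validate",
]

LABEL_COLUMN = "label"
CLASSES = ("benign", "malignant")
VAR_FLOOR = 1e-9


@dataclass(frozen=True)
class TreeConfig:
    confidence_factor: float = 0.25
    pruned: bool = False
    min_leaf: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.confidence_factor < 1:
            raise ValueError("confidence_factor must lie in (0, 1)")


@dataclass(frozen=True)
class NBConfig:
    kernel_estimator: bool = False


@dataclass(frozen=True)
class ProbPair:
    p_malignant: float
    p_benign: float

    def __post_init__(self) -> None:
        for p in (self.p_malignant, self.p_benign):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(self.p_malignant + self.p_benign - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @property
    def predicted(self) -> str:
        """Hard label; exact ties go to malignant."""
        return "malignant" if self.p_malignant >= self.p_benign else "benign"


def _check_table(table: pd.DataFrame, features: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    y = (table[LABEL_COLUMN] == "malignant").to_numpy()
    counts = table[LABEL_COLUMN].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("training table needs >= 2 instances of each class")
    X = table[list(features)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    return X, y


# ---------------------------------------------------------------------------
# decision tree
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    n: int
    n_mal: int
    feature: str | None = None
    threshold: float = np.nan
    left: "_Node | None" = None     # feature value <= threshold
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def p_malignant(self) -> float:
        return (self.n_mal + 1) / (self.n + 2)      # Laplace smoothing

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"n": self.n, "n_mal": self.n_mal}
        return {"n": self.n, "n_mal": self.n_mal, "feature": self.feature,
                "threshold": self.threshold,
                "left": self.left.to_dict(), "right": self.right.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "_Node":
        node = cls(n=d["n"], n_mal=d["n_mal"])
        if "feature" in d:
            node.feature = d["feature"]
            node.threshold = d["threshold"]
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


def _entropy(n_mal: int, n: int) -> float:
    if n == 0:
        return 0.0
    p = n_mal / n
    out = 0.0
    for q in (p, 1 - p):
        if q > 0:
            out -= q * np.log2(q)
    return out


def _best_split(X: np.ndarray, y: np.ndarray, features: Sequence[str]):
    """Highest information-gain (feature, threshold); candidate thresholds
    are midpoints between consecutive distinct sorted values. Ties break by
    lexicographic feature name then lowest threshold."""
    n = len(y)
    n_mal = int(y.sum())
    parent = _entropy(n_mal, n)
    best = None  # (gain, feature_name, threshold, j)
    for j in np.argsort(features):
        name = features[j]
        order = np.argsort(X[:, j], kind="stable")
        xs, ys = X[order, j], y[order]
        distinct = np.nonzero(np.diff(xs) > 0)[0]
        cum_mal = np.cumsum(ys)
        for idx in distinct:
            thr = 0.5 * (xs[idx] + xs[idx + 1])
            if not xs[idx] <= thr < xs[idx + 1]:   # float collapse: skip
                continue
            n_l = idx + 1
            mal_l = int(cum_mal[idx])
            gain = parent - (n_l / n) * _entropy(mal_l, n_l) \
                - ((n - n_l) / n) * _entropy(n_mal - mal_l, n - n_l)
            if best is None or gain > best[0] + 1e-12:
                best = (gain, name, thr, j)
    if best is None or best[0] <= 1e-12:
        return None
    return best[1], best[2], best[3]


def _grow(X: np.ndarray, y: np.ndarray, features: Sequence[str],
          min_leaf: int) -> _Node:
    node = _Node(n=len(y), n_mal=int(y.sum()))
    if len(y) <= min_leaf or node.n_mal in (0, node.n):
        return node
    split = _best_split(X, y, features)
    if split is None:
        return node
    name, thr, j = split
    mask = X[:, j] <= thr
    if not mask.any() or mask.all():
        return node
    node.feature, node.threshold = name, thr
    node.left = _grow(X[mask], y[mask], features, min_leaf)
    node.right = _grow(X[~mask], y[~mask], features, min_leaf)
    return node


def _pessimistic_error(errors: int, n: int, z: float, cf: float) -> float:
    """C4.5 upper confidence limit on the node error rate.

    Zero observed errors use the exact binomial inversion 1 - cf^(1/n);
    otherwise the normal approximation to the binomial upper limit.
    """
    if n == 0:
        return 0.0
    if errors == 0:
        return 1.0 - cf ** (1.0 / n)
    f = errors / n
    num = f + z * z / (2 * n) + z * np.sqrt(f / n - f * f / n + z * z / (4 * n * n))
    return num / (1 + z * z / n)


def _prune(node: _Node, cf: float) -> _Node:
    if node.is_leaf:
        return node
    z = float(norm.ppf(1 - cf))
    node.left = _prune(node.left, cf)
    node.right = _prune(node.right, cf)

    def subtree_error(nd: _Node) -> float:
        if nd.is_leaf:
            errors = min(nd.n_mal, nd.n - nd.n_mal)
            return _pessimistic_error(errors, nd.n, z, cf) * nd.n
        return subtree_error(nd.left) + subtree_error(nd.right)

    as_leaf = _pessimistic_error(min(node.n_mal, node.n - node.n_mal),
                                 node.n, z, cf) * node.n
    if as_leaf <= subtree_error(node) + 0.1:
        node.feature, node.left, node.right = None, None, None
    return node


@dataclass
class DecisionTreeModel:
    features: tuple[str, ...]
    root: _Node
    config: TreeConfig = field(default_factory=TreeConfig)

    def predict_proba(self, x: Mapping[str, float]) -> ProbPair:
        missing = [f for f in self.features if f not in x]
        if missing:
            raise ValueError(f"missing feature(s) {missing} in query")
        node = self.root
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        p = node.p_malignant
        return ProbPair(p_malignant=p, p_benign=1.0 - p)

    def to_json(self) -> str:
        return json.dumps({"kind": "tree", "features": list(self.features),
                           "config": vars(self.config), "root": self.root.to_dict()})

    @classmethod
    def from_json(cls, text: str) -> "DecisionTreeModel":
        d = json.loads(text)
        return cls(features=tuple(d["features"]), root=_Node.from_dict(d["root"]),
                   config=TreeConfig(**d["config"]))


def train_tree(table: pd.DataFrame, cfg: TreeConfig = TreeConfig(),
               features: Sequence[str] | None = None) -> DecisionTreeModel:
    """Grow (and optionally pessimistically prune) the morphological tree."""
    if features is None:
        features = [c for c in table.columns if c != LABEL_COLUMN]
    X, y = _check_table(table, features)
    root = _grow(X, y, list(features), cfg.min_leaf)
    if cfg.pruned:
        root = _prune(root, cfg.confidence_factor)
    return DecisionTreeModel(features=tuple(features), root=root, config=cfg)


# ---------------------------------------------------------------------------
# Gaussian naive Bayes
# ---------------------------------------------------------------------------

@dataclass
class NaiveBayesModel:
    features: tuple[str, ...]
    priors: dict          # class -> prior
    means: dict           # class -> np.ndarray
    vars: dict            # class -> np.ndarray

    def _log_posteriors(self, X: np.ndarray) -> np.ndarray:
        """Rows: samples; columns ordered (benign, malignant)."""
        logs = np.empty((len(X), 2))
        for k, cls in enumerate(CLASSES):
            mu, var = np.asarray(self.means[cls]), np.asarray(self.vars[cls])
            ll = -0.5 * (np.log(2 * np.pi * var) + (X - mu) ** 2 / var).sum(axis=1)
            logs[:, k] = np.log(self.priors[cls]) + ll
        return logs

    def predict_proba_matrix(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) posterior matrix, columns (benign, malignant)."""
        logs = self._log_posteriors(np.asarray(X, dtype=float))
        logs -= logs.max(axis=1, keepdims=True)
        p = np.exp(logs)
        return p / p.sum(axis=1, keepdims=True)

    def predict_proba(self, x: Mapping[str, float]) -> ProbPair:
        missing = [f for f in self.features if f not in x]
        if missing:
            raise ValueError(f"missing feature(s) {missing} in query")
        row = np.asarray([[x[f] for f in self.features]], dtype=float)
        p_b, p_m = self.predict_proba_matrix(row)[0]
        return ProbPair(p_malignant=float(p_m), p_benign=float(p_b))

    def to_json(self) -> str:
        return json.dumps({
            "kind": "nb", "features": list(self.features),
            "priors": self.priors,
            "means": {c: list(v) for c, v in self.means.items()},
            "vars": {c: list(v) for c, v in self.vars.items()},
        })

    @classmethod
    def from_json(cls, text: str) -> "NaiveBayesModel":
        d = json.loads(text)
        return cls(features=tuple(d["features"]), priors=d["priors"],
                   means={c: np.asarray(v) for c, v in d["means"].items()},
                   vars={c: np.asarray(v) for c, v in d["vars"].items()})


def train_nb(table: pd.DataFrame, cfg: NBConfig = NBConfig(),
             features: Sequence[str] | None = None) -> NaiveBayesModel:
    """Fit class priors and per-class independent Gaussians (ML variances,
    floored at 1e-9)."""
    if cfg.kernel_estimator:
        raise NotImplementedError("kernel density class-conditionals are not supported")
    if features is None:
        features = [c for c in table.columns if c != LABEL_COLUMN]
    X, y = _check_table(table, features)
    priors, means, variances = {}, {}, {}
    for cls in CLASSES:
        rows = X[y] if cls == "malignant" else X[~y]
        priors[cls] = len(rows) / len(X)
        means[cls] = rows.mean(axis=0)
        variances[cls] = np.maximum(rows.var(axis=0), VAR_FLOOR)
    return NaiveBayesModel(features=tuple(features), priors=priors,
                           means=means, vars=variances)


# ---------------------------------------------------------------------------
# common contract + lesion-level dynamic vote
# ---------------------------------------------------------------------------

def predict_proba(model, x: Mapping[str, float]) -> ProbPair:
    """Uniform probability contract over both model kinds."""
    return model.predict_proba(x)


def voxel_dynamic_probabilities(voi: VOI | int, dyn: Sequence[DynFeatures],
                                model: NaiveBayesModel) -> tuple[float, float]:
    """(D_m, D_b) = voxel-vote fractions (n_m/N, n_b/N).

    Each voxel is hard-labelled by posterior argmax (ties to malignant).
    ``voi`` is accepted for interface symmetry; N is len(dyn).
    """
    if len(dyn) == 0:
        raise ValueError("no voxel features supplied")
    X = np.asarray([[getattr(d, f) for f in model.features] for d in dyn], dtype=float)
    post = model.predict_proba_matrix(X)
    n_m = int((post[:, 1] >= post[:, 0]).sum())     # tie -> malignant
    n = len(dyn)
    return n_m / n, (n - n_m) / n


def cross_validate(table: pd.DataFrame, kind: str, cfg=None, folds: int = 10,
                   seed: int = 0, features: Sequence[str] | None = None) -> float:
    """Mean held-out accuracy over stratified k-fold CV (seeded shuffle).

    If a training fold loses a class, refolding is retried with a new seed
    up to 5 times before raising.
    """
    if len(table) < folds:
        raise ValueError(f"need at least {folds} instances for {folds}-fold CV")
    trainers = {"tree": (train_tree, TreeConfig), "nb": (train_nb, NBConfig)}
    if kind not in trainers:
        raise ValueError(f"unknown model kind {kind!r}")
    train_fn, default_cfg = trainers[kind]
    cfg = cfg if cfg is not None else default_cfg()
    if features is None:
        features = [c for c in table.columns if c != LABEL_COLUMN]
    y = table[LABEL_COLUMN].to_numpy()
    last_err = None
    for attempt in range(5):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        accs = []
        try:
            for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
                model = train_fn(table.iloc[train_idx], cfg, features=features)
                correct = 0
                for _, row in table.iloc[test_idx].iterrows():
                    pred = model.predict_proba({f: row[f] for f in features}).predicted
                    correct += pred == row[LABEL_COLUMN]
                accs.append(correct / len(test_idx))
            return float(np.mean(accs))
        except ValueError as err:   # class missing from a fold
            last_err = err
    raise ValueError(f"cross-validation failed after 5 refolds: {last_err}")
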