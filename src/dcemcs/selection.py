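"""Feature-subset selection: correlation-based (CFS) and consistency-based
scoring, searched by best-first (forward / backward / bidirectional),
greedy hill-climbing, or single-feature ranking.

CFS rewards subsets whose features correlate with the class label but not
with each other:

    merit(S) = k * r_cf / sqrt(k + k (k-1) * r_ff)

with k = |S|, r_cf the mean |Pearson| feature-label correlation (label
coded benign=0 / malignant=1) and r_ff the mean |Pearson| pairwise
feature-feature correlation. The consistency score discretises features
into equal-width bins and measures how often instances sharing a
discretised pattern share a label.

All searches are deterministic: ties break by lexicographic feature name.
"""
from __future__ import annotations

import heapq
import itertools
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SelectionResult",
    "label_vector",
    "cfs_merit",
    "consistency_score",
    "select_features",
    "SEARCHES",
    "METHODS",
]

METHODS = ("cfs", "consistency")
SEARCHES = ("forward", "backward", "bidirectional", "greedy", "ranking")

LABEL_COLUMN = "label"


@dataclass(frozen=True)
class SelectionResult:
    method: str
    search: str
    selected: tuple[str, ...]   # sorted feature names
    score: float


def label_vector(table: pd.DataFrame) -> np.ndarray:
    labels = table[LABEL_COLUMN]
    bad = set(labels) - {"benign", "malignant"}
    if bad:
        raise ValueError(f"labels outside benign/malignant: {sorted(bad)}")
    return (labels == "malignant").to_numpy(dtype=float)


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c != LABEL_COLUMN]


def _abs_pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(abs(np.corrcoef(x, y)[0, 1]))


def cfs_merit(subset: Sequence[str], table: pd.DataFrame) -> float:
    """CFS merit of a feature subset (0 for the degenerate all-constant case)."""
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    y = label_vector(table)
    usable = []
    for name in subset:
        if table[name].std() == 0:
            warnings.warn(f"zero-variance feature {name!r} excluded from merit",
                          stacklevel=2)
        else:
            usable.append(name)
    if not usable:
        return 0.0
    k = len(usable)
    cols = {name: table[name].to_numpy(dtype=float) for name in usable}
    r_cf = float(np.mean([_abs_pearson(cols[n], y) for n in usable]))
    if k == 1:
        r_ff = 0.0
    else:
        r_ff = float(np.mean([_abs_pearson(cols[a], cols[b])
                              for a, b in itertools.combinations(usable, 2)]))
    return k * r_cf / np.sqrt(k + k * (k - 1) * r_ff)


def consistency_score(subset: Sequence[str], table: pd.DataFrame,
                      bins: int = 10) -> float:
    """1 - (inconsistency count)/n over equal-width-discretised patterns.

    The empty subset lumps all instances into one pattern, scoring the
    majority-class fraction.
    """
    n = len(table)
    if n == 0:
        raise ValueError("empty table")
    y = label_vector(table)
    if not subset:
        codes = np.zeros(n, dtype=int)[:, None]
    else:
        codes = np.empty((n, len(subset)), dtype=int)
        for j, name in enumerate(subset):
            x = table[name].to_numpy(dtype=float)
            lo, hi = x.min(), x.max()
            if hi == lo:
                codes[:, j] = 0
            else:
                codes[:, j] = np.minimum(((x - lo) / (hi - lo) * bins).astype(int),
                                         bins - 1)
    df = pd.DataFrame(codes)
    df["_y"] = y
    inconsistency = 0
    for _, grp in df.groupby(list(range(codes.shape[1])), sort=False):
        counts = grp["_y"].value_counts()
        inconsistency += len(grp) - counts.max()
    return 1.0 - inconsistency / n


# ---------------------------------------------------------------------------
# searches
# ---------------------------------------------------------------------------

def _make_scorer(method: str, table: pd.DataFrame, bins: int) -> Callable:
    if method == "cfs":
        def score(subset):
            return cfs_merit(subset, table) if subset else -np.inf
    elif method == "consistency":
        def score(subset):
            return consistency_score(subset, table, bins=bins)
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return score


def _expansions(subset: tuple[str, ...], all_features: list[str],
                ops: str) -> list[tuple[str, ...]]:
    children = []
    current = set(subset)
    if "add" in ops:
        for f in all_features:
            if f not in current:
                children.append(tuple(sorted(current | {f})))
    if "remove" in ops and len(subset) > 1:
        for f in subset:
            children.append(tuple(sorted(current - {f})))
    return children


def _best_first(all_features: list[str], score: Callable, ops: str,
                start: tuple[str, ...], stall_limit: int = 5):
    """Best-first search; stops after ``stall_limit`` consecutive expanded
    nodes that fail to improve the best score."""
    best_subset, best_score = start, score(start)
    # heap orders by (-score, size, names) -> highest score, smallest, lexicographic
    heap = [(-best_score, len(start), start)]
    visited = {start}
    stall = 0
    while heap and stall < stall_limit:
        _, _, subset = heapq.heappop(heap)
        improved = False
        for child in _expansions(subset, all_features, ops):
            if child in visited:
                continue
            visited.add(child)
            s = score(child)
            heapq.heappush(heap, (-s, len(child), child))
            if s > best_score + 1e-12:
                best_subset, best_score = child, s
                improved = True
        stall = 0 if improved else stall + 1
    return best_subset, best_score


def _greedy(all_features: list[str], score: Callable, start: tuple[str, ...]):
    """Pure hill-climbing: take the best forward step; stop at the first
    non-improving step."""
    current, current_score = start, score(start)
    while True:
        children = _expansions(current, all_features, "add")
        if not children:
            break
        scored = sorted(((score(c), c) for c in children),
                        key=lambda t: (-t[0], t[1]))
        best_score, best_child = scored[0]
        if best_score <= current_score + 1e-12 and np.isfinite(current_score):
            break
        current, current_score = best_child, best_score
    return current, current_score


def _ranking(all_features: list[str], score: Callable, cap: int | None):
    """Order features by singleton score (ties lexicographic); cut at the
    largest consecutive score drop, or at ``cap`` if given."""
    singles = sorted(((score((f,)), f) for f in all_features),
                     key=lambda t: (-t[0], t[1]))
    scores = [s for s, _ in singles]
    names = [f for _, f in singles]
    if cap is not None:
        k = max(1, min(cap, len(names)))
    elif len(names) == 1:
        k = 1
    else:
        drops = np.diff(scores)                     # <= 0
        k = int(np.argmin(drops)) + 1               # cut after the largest drop
    chosen = tuple(sorted(names[:k]))
    return chosen, score(chosen)


def select_features(table: pd.DataFrame, method: str = "cfs",
                    search: str = "forward", cap: int | None = None,
                    bins: int = 10, stall_limit: int = 5) -> SelectionResult:
    """Run one method/search combination on a feature table.

    The table holds numeric feature columns plus a ``label`` column with
    values benign/malignant. Deterministic for a given table.
    """
    features = sorted(_feature_columns(table))
    if not features:
        raise ValueError("table has no feature columns")
    score = _make_scorer(method, table, bins)
    if search == "forward":
        subset, s = _best_first(features, score, "add", (), stall_limit)
    elif search == "backward":
        subset, s = _best_first(features, score, "remove", tuple(features), stall_limit)
    elif search == "bidirectional":
        subset, s = _best_first(features, score, "addremove", (), stall_limit)
    elif search == "greedy":
        subset, s = _greedy(features, score, ())
    elif search == "ranking":
        subset, s = _ranking(features, score, cap)
    else:
        raise ValueError(f"unknown search {search!r}; expected one of {SEARCHES}")
    if not subset:   # nothing ever improved on the start state
        subset, s = _ranking(features, score, 1)
    return SelectionResult(method=method, search=search,
                           selected=tuple(sorted(subset)), score=float(s))
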