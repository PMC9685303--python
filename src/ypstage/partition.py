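"""Recursive-partitioning survival tree over an integer covariate.

Reclassifies the nodal stage from the count of pathologically positive
regional lymph nodes: the tree splits on integer thresholds chosen to
maximise the two-group log-rank chi-square (LeBlanc–Crowley style
splitting), with a Bonferroni correction over the candidate thresholds
to counter the anti-conservatism of maximally selected statistics.
Leaves define contiguous node-count intervals that serve as modified
nodal (mypN-style) groups.

The engine accepts any single integer covariate, but the shipped
pipeline only ever splits on the positive-node count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from .cohort import Cohort
from .exceptions import DomainError
from .survstats import logrank


@dataclass
class StoppingRule:
    """Pre-pruning knobs for tree growth."""

    min_leaf: int = 20
    alpha: float = 0.05
    max_depth: int = 3
    adjust: str = "bonferroni"  # or "none"

    def __post_init__(self):
        if self.min_leaf < 1:
            raise DomainError("min_leaf must be >= 1")
        if not (0 < self.alpha <= 1):
            raise DomainError("alpha must be in (0, 1]")
        if self.max_depth < 0:
            raise DomainError("max_depth must be >= 0")
        if self.adjust not in ("bonferroni", "none"):
            raise DomainError("adjust must be 'bonferroni' or 'none'")


@dataclass
class BestSplit:
    cutpoint: Optional[int]
    chi2: float = 0.0
    p_raw: float = 1.0
    p_adjusted: float = 1.0
    n_candidates: int = 0

    @property
    def found(self) -> bool:
        return self.cutpoint is not None


@dataclass
class SplitNode:
    """One node of the survival tree; leaves have ``cutpoint is None``."""

    n: int
    depth: int
    lo: int  # inclusive lower bound of the covariate interval
    hi: Optional[int]  # inclusive upper bound, None = unbounded
    cutpoint: Optional[int] = None
    chi2: float = 0.0
    p: float = 1.0
    left: Optional["SplitNode"] = None
    right: Optional["SplitNode"] = None
    stop_reason: str = ""

    @property
    def is_leaf(self) -> bool:
        return self.cutpoint is None

    def leaves(self) -> list["SplitNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def to_dict(self) -> dict:
        d = {"n": self.n, "depth": self.depth, "lo": self.lo, "hi": self.hi}
        if self.is_leaf:
            d["leaf"] = True
            d["stop_reason"] = self.stop_reason
        else:
            d.update(leaf=False, cutpoint=self.cutpoint, chi2=self.chi2,
                     p=self.p, left=self.left.to_dict(),
                     right=self.right.to_dict())
        return d


def best_split(times, events, values, min_leaf: int = 1,
               adjust: str = "bonferroni") -> BestSplit:
    """Exhaustive scan of integer thresholds for the best log-rank split.

    A threshold c dichotomises subjects into {value < c} vs
    {value >= c}; every integer strictly between the smallest and the
    largest observed distinct value (i.e. each distinct value except
    the smallest) is a candidate.  Returns the threshold maximising the
    two-group log-rank chi-square, with the p-value Bonferroni-adjusted
    over the number of admissible candidates.  When no candidate
    respects ``min_leaf`` (or all values are equal) a no-split result
    is returned rather than an exception.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    values = np.asarray(values, dtype=int)
    distinct = np.unique(values)
    if distinct.size < 2 or times.size < 2 * min_leaf:
        return BestSplit(None)
    candidates = [int(c) for c in distinct[1:]]
    admissible = [c for c in candidates
                  if min_leaf <= (values < c).sum()
                  and (values >= c).sum() >= min_leaf]
    if not admissible:
        return BestSplit(None)
    best = BestSplit(None)
    for c in admissible:
        res = logrank(np.where(values < c, "lo", "hi"), times, events)
        if res.chi2 > best.chi2 or best.cutpoint is None:
            best = BestSplit(c, res.chi2, res.p, res.p, len(admissible))
    if adjust == "bonferroni":
        best.p_adjusted = min(1.0, best.p_raw * len(admissible))
    return best


class NodeCountPartitioner(BaseEstimator):
    """Survival tree over an integer covariate, scikit-learn style.

    Parameters mirror :class:`StoppingRule`.  ``fit`` takes the
    covariate values ``X`` (shape (n,) or (n, 1)) and a survival
    outcome ``y``: either a ``(times, events)`` tuple or a structured
    array with fields ``time``/``event``.  After fitting,

    ``tree_``
        the root :class:`SplitNode`;
    ``cut_points_``
        sorted selected thresholds;
    ``intervals_``
        the leaf intervals as (lo, hi) with hi = None for the last;
    ``labels_``
        human-readable interval labels such as ``"0"``, ``"1-2"``,
        ``"3+"``.

    ``predict`` maps covariate values to leaf-group indices ordered by
    interval lower bound.
    """

    def __init__(self, min_leaf: int = 20, alpha: float = 0.05,
                 max_depth: int = 3, adjust: str = "bonferroni"):
        self.min_leaf = min_leaf
        self.alpha = alpha
        self.max_depth = max_depth
        self.adjust = adjust

    # -- helpers ------------------------------------------------------
    @staticmethod
    def _unpack_y(y):
        if isinstance(y, tuple) and len(y) == 2:
            times, events = y
        elif hasattr(y, "dtype") and y.dtype.names:
            names = set(y.dtype.names)
            tname = "time" if "time" in names else "time_months"
            ename = "event" if "event" in names else "status"
            times, events = y[tname], y[ename]
        else:
            raise DomainError(
                "y must be a (times, events) tuple or structured array")
        return (np.asarray(times, dtype=float),
                np.asarray(events).astype(int))

    def fit(self, X, y):
        rule = StoppingRule(self.min_leaf, self.alpha, self.max_depth,
                            self.adjust)
        X = np.asarray(X)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise DomainError("only a single split covariate is supported")
            X = X[:, 0]
        values = X.astype(int)
        if np.any(values < 0):
            raise DomainError("covariate values must be nonnegative integers")
        times, events = self._unpack_y(y)
        if times.size == 0:
            raise DomainError("empty cohort")

        def grow(mask: np.ndarray, depth: int, lo: int, hi) -> SplitNode:
            node = SplitNode(n=int(mask.sum()), depth=depth, lo=lo, hi=hi)
            if depth >= rule.max_depth:
                node.stop_reason = "max_depth"
                return node
            if node.n < 2 * rule.min_leaf:
                node.stop_reason = "min_leaf"
                return node
            sp = best_split(times[mask], events[mask], values[mask],
                            min_leaf=rule.min_leaf, adjust=rule.adjust)
            if not sp.found:
                node.stop_reason = "no_admissible_split"
                return node
            if sp.p_adjusted >= rule.alpha:
                node.stop_reason = "alpha"
                return node
            node.cutpoint, node.chi2, node.p = sp.cutpoint, sp.chi2, sp.p_adjusted
            left_mask = mask & (values < sp.cutpoint)
            right_mask = mask & (values >= sp.cutpoint)
            node.left = grow(left_mask, depth + 1, lo, sp.cutpoint - 1)
            node.right = grow(right_mask, depth + 1, sp.cutpoint, hi)
            return node

        self.tree_ = grow(np.ones(values.size, dtype=bool), 0,
                          int(values.min()), None)
        leaves = self.tree_.leaves()
        self.cut_points_ = sorted(leaf.lo for leaf in leaves[1:]) if len(
            leaves) > 1 else []
        # normalise intervals to tile [0, inf)
        los = [0] + list(self.cut_points_)
        self.intervals_ = [
            (lo, (self.cut_points_[i] - 1 if i < len(self.cut_points_) else None))
            for i, lo in enumerate(los)
        ]
        self.labels_ = [interval_label(lo, hi) for lo, hi in self.intervals_]
        self.n_groups_ = len(self.intervals_)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "tree_"):
            raise DomainError("partitioner is not fitted")
        X = np.asarray(X)
        if X.ndim == 2:
            X = X[:, 0]
        return np.searchsorted(np.asarray(self.cut_points_), X.astype(int),
                               side="right")


def interval_label(lo: int, hi) -> str:
    if hi is None:
        return f"{lo}+"
    if hi == lo:
        return f"{lo}"
    return f"{lo}-{hi}"


@dataclass
class NodeGroups:
    """Ordered, exhaustive node-count intervals emitted by the tree.

    Acts as a reusable modified-nodal mapping: ``group_of(n_pos)``
    returns the group index, ``label_of`` the interval label.
    """

    cut_points: tuple[int, ...]
    intervals: tuple[tuple[int, Optional[int]], ...]
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if not self.labels:
            self.labels = tuple(interval_label(lo, hi)
                                for lo, hi in self.intervals)

    def group_of(self, n_pos: int) -> int:
        if n_pos < 0:
            raise DomainError("n_pos must be nonnegative")
        return int(np.searchsorted(np.asarray(self.cut_points), n_pos,
                                   side="right"))

    def label_of(self, n_pos: int) -> str:
        return self.labels[self.group_of(n_pos)]

    @property
    def n_groups(self) -> int:
        return len(self.intervals)


#: The published modified nodal mapping: 0 / 1-2 / >=3 positive nodes.
MYPN_GROUPS_FIXED = NodeGroups((1, 3), ((0, 0), (1, 2), (3, None)),
                               ("0", "1-2", "3+"))


def grow_tree(cohort: Cohort, stopping: Optional[StoppingRule] = None
              ) -> NodeCountPartitioner:
    """Fit the survival tree on a cohort's positive-node counts."""
    stopping = stopping or StoppingRule()
    est = NodeCountPartitioner(stopping.min_leaf, stopping.alpha,
                               stopping.max_depth, stopping.adjust)
    return est.fit(cohort.n_pos, (cohort.times, cohort.events))


def leaves_to_groups(fitted: NodeCountPartitioner) -> NodeGroups:
    """Contiguous, exhaustive, non-overlapping intervals from the leaves."""
    if not hasattr(fitted, "intervals_"):
        raise DomainError("partitioner is not fitted")
    return NodeGroups(tuple(fitted.cut_points_), tuple(fitted.intervals_),
                      tuple(fitted.labels_))


def tree_to_json(fitted: NodeCountPartitioner, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({
            "tree": fitted.tree_.to_dict(),
            "cut_points": list(fitted.cut_points_),
            "labels": list(fitted.labels_),
        }, fh, indent=2)


def groups_from_json(path) -> NodeGroups:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    cuts = tuple(int(c) for c in data["cut_points"])
    los = (0,) + cuts
    intervals = tuple(
        (lo, (cuts[i] - 1 if i < len(cuts) else None))
        for i, lo in enumerate(los)
    )
    return NodeGroups(cuts, intervals)
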