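"""T x N x TRG subgroup construction and p-threshold merging.

Prognostic subgroup cells are built by crossing the WECC yp tumour
groups (T0-2, T3, T4a, T4b) with a nodal grouping (by default the
tree-derived or published modified one) and the collapsed tumour
regression grade.  Cells are ordered by risk (5-year overall survival
descending, median survival as tie-breaker) and merged agglomeratively:
while any adjacent pair of clusters has a pooled two-group log-rank
p-value at or above the threshold (0.15 by default), the pair with the
largest p merges and all adjacent tests are recomputed.  Adjacency on
the risk order keeps the resulting stage groups ordinal.

T4b is a special cell: it is never subdivided by regression grade and
is pinned to the top (worst) stage group rather than entering the
merge, mirroring the rule that T4b disease is highest-stage for any
nodal status.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .cohort import Cohort
from .exceptions import AssemblyError, DomainError
from .partition import MYPN_GROUPS_FIXED, NodeGroups
from .staging import STAGE_LABELS, StagingSystem, t_group, trg_group
from .survstats import km_estimate, logrank, median_survival, survival_at

T_CELL_GROUPS = ("T0-2", "T3", "T4a", "T4b")
TRG_CELL_GROUPS = ("0-1", "2", "3")


@dataclass
class SubgroupCell:
    """One prognostic cell with its members and KM summaries."""

    t_group: str
    n_group: str
    trg_group: str  # "any" for the undivided T4b cell
    indices: np.ndarray
    n: int
    n_events: int
    os5: float  # KM survival at 60 months
    median: float
    pinned_top: bool = False

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.t_group, self.n_group, self.trg_group)


def build_subgroups(cohort: Cohort,
                    node_groups: Optional[NodeGroups] = None
                    ) -> list[SubgroupCell]:
    """One cell per observed (T group, nodal group, TRG group) combination.

    TRG is collapsed to {0-1, 2, 3}; T4b forms a single undivided cell
    pinned to the top stage.  Cells partition the cohort and are
    returned in deterministic (T, N, TRG) rank order.
    """
    if len(cohort) == 0:
        raise DomainError("empty cohort")
    node_groups = node_groups or MYPN_GROUPS_FIXED
    tg = np.array([t_group(t) for t in cohort.ypT])
    ng = np.array([node_groups.label_of(int(v)) for v in cohort.n_pos])
    gg = np.array([trg_group(int(v)) for v in cohort.trg])
    gg = np.where(tg == "T4b", "any", gg)
    ng_eff = np.where(tg == "T4b", "any", ng)

    times, events = cohort.times, cohort.events
    cells = []
    for t in T_CELL_GROUPS:
        n_labels = ["any"] if t == "T4b" else list(node_groups.labels)
        g_labels = ["any"] if t == "T4b" else list(TRG_CELL_GROUPS)
        for nl in n_labels:
            for gl in g_labels:
                mask = (tg == t) & (ng_eff == nl) & (gg == gl)
                if not mask.any():
                    continue
                idx = np.flatnonzero(mask)
                km = km_estimate(times[idx], events[idx])
                cells.append(SubgroupCell(
                    t, nl, gl, idx, idx.size, int(events[idx].sum()),
                    survival_at(km, 60.0), median_survival(km),
                    pinned_top=(t == "T4b"),
                ))
    return cells


def pairwise_logrank(cells: Sequence[SubgroupCell], times, events) -> np.ndarray:
    """Symmetric matrix of unadjusted two-group log-rank p-values.

    Diagonal entries are 1; pairs involving a cell with fewer than two
    subjects are recorded as NaN (undefined, excluded from merging).
    """
    if len(cells) < 2:
        raise DomainError("need at least two cells")
    k = len(cells)
    P = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if cells[i].n < 2 or cells[j].n < 2:
                P[i, j] = P[j, i] = np.nan
                continue
            idx = np.concatenate([cells[i].indices, cells[j].indices])
            lab = np.concatenate([np.zeros(cells[i].n), np.ones(cells[j].n)])
            res = logrank(lab, times[idx], events[idx])
            P[i, j] = P[j, i] = res.p
    return P


@dataclass
class MergeEvent:
    """One merge step: positions (in risk order) pooled and its p-value."""

    left: tuple[int, ...]
    right: tuple[int, ...]
    p: float


@dataclass
class MergeResult:
    """Assignment of cells to ordered stage groups plus the audit trace."""

    cells: list
    risk_order: list  # cell positions sorted best -> worst survival
    assignment: dict  # cell.key -> group index (0 = best prognosis)
    n_groups: int
    trace: list = field(default_factory=list)
    threshold: float = 0.15
    flagged: list = field(default_factory=list)

    def replay(self) -> dict:
        """Re-derive the assignment from the trace (audit property)."""
        clusters = [[pos] for pos in self.risk_order
                    if not self.cells[pos].pinned_top and self.cells[pos].n >= 2]
        for ev in self.trace:
            li = next(i for i, c in enumerate(clusters) if tuple(c) == ev.left)
            assert tuple(clusters[li + 1]) == ev.right
            clusters[li] = clusters[li] + clusters[li + 1]
            del clusters[li + 1]
        out = {}
        for gi, cluster in enumerate(clusters):
            for pos in cluster:
                out[self.cells[pos].key] = gi
        return out


def merge_subgroups(cells: Sequence[SubgroupCell], times, events,
                    threshold: float = 0.15,
                    method: str = "pairwise") -> MergeResult:
    """Agglomerative merging of risk-ordered cells under a log-rank cutoff.

    Cells are ordered best-to-worst prognosis (5-year OS descending,
    median survival as tie-breaker) and only adjacent clusters on that
    order may merge, which keeps the resulting stage groups ordinal.

    With the default ``method='pairwise'`` the merge criterion for two
    adjacent clusters is the largest cell-level log-rank p-value across
    the cluster boundary: while any adjacent pair of clusters contains
    a cross-boundary cell pair that fails to separate at ``threshold``,
    the adjacent pair with the largest such p merges.  Cell-level tests
    are computed once, between cells defined a priori, so they remain
    calibrated under the null; pooled tests between clusters formed by
    sorting on the observed outcome are systematically anti-null and
    are offered only as a sensitivity analysis (``method='pooled'``,
    recomputing the pooled two-group log-rank after every merge).

    Pinned (T4b) cells and cells with fewer than two subjects are kept
    out of the agglomeration: pinned cells become the final (worst)
    group, undersized cells are flagged and attached to the
    risk-nearest cluster.
    """
    if not (0 < threshold <= 1):
        raise DomainError("threshold must be in (0, 1]")
    if method not in ("pairwise", "pooled"):
        raise DomainError("method must be 'pairwise' or 'pooled'")
    cells = list(cells)
    order = sorted(
        range(len(cells)),
        key=lambda i: (-cells[i].os5,
                       -(cells[i].median if np.isfinite(cells[i].median)
                         else 1e18)),
    )
    mergeable = [pos for pos in order
                 if not cells[pos].pinned_top and cells[pos].n >= 2]
    tiny = [pos for pos in order
            if not cells[pos].pinned_top and cells[pos].n < 2]
    pinned = [pos for pos in order if cells[pos].pinned_top]
    if not mergeable:
        raise DomainError("no mergeable cells")

    clusters: list[list[int]] = [[pos] for pos in mergeable]
    trace: list[MergeEvent] = []

    p_matrix = pairwise_logrank(cells, times, events) if len(cells) > 1 else None

    def pooled_p(a: list[int], b: list[int]) -> float:
        idx_a = np.concatenate([cells[p].indices for p in a])
        idx_b = np.concatenate([cells[p].indices for p in b])
        idx = np.concatenate([idx_a, idx_b])
        lab = np.concatenate([np.zeros(idx_a.size), np.ones(idx_b.size)])
        return logrank(lab, times[idx], events[idx]).p

    def boundary_p(a: list[int], b: list[int]) -> float:
        if method == "pooled":
            return pooled_p(a, b)
        ps = [p_matrix[i, j] for i in a for j in b]
        ps = [p for p in ps if np.isfinite(p)]
        return max(ps) if ps else float("nan")

    while len(clusters) > 1:
        ps = [boundary_p(clusters[i], clusters[i + 1])
              for i in range(len(clusters) - 1)]
        with np.errstate(invalid="ignore"):
            i_best = int(np.nanargmax(ps)) if np.isfinite(ps).any() else 0
        if not np.isfinite(ps[i_best]) or ps[i_best] < threshold:
            break
        trace.append(MergeEvent(tuple(clusters[i_best]),
                                tuple(clusters[i_best + 1]), ps[i_best]))
        clusters[i_best] = clusters[i_best] + clusters[i_best + 1]
        del clusters[i_best + 1]

    assignment: dict = {}
    for gi, cluster in enumerate(clusters):
        for pos in cluster:
            assignment[cells[pos].key] = gi
    n_groups = len(clusters)
    flagged = []
    # undersized cells: attach to the cluster of the risk-nearest cell
    for pos in tiny:
        rank_in_order = order.index(pos)
        neighbour = None
        for offset in range(1, len(order)):
            for cand_rank in (rank_in_order - offset, rank_in_order + offset):
                if 0 <= cand_rank < len(order):
                    cand = order[cand_rank]
                    if cells[cand].key in assignment:
                        neighbour = cand
                        break
            if neighbour is not None:
                break
        assignment[cells[pos].key] = assignment[cells[neighbour].key]
        flagged.append(cells[pos].key)
    if pinned:
        for pos in pinned:
            assignment[cells[pos].key] = n_groups
        n_groups += 1
    return MergeResult(cells, order, assignment, n_groups, trace, threshold,
                       flagged)


def assemble_system(merge: MergeResult, name: str = "refined",
                    labels: Optional[Sequence[str]] = None,
                    node_groups: Optional[NodeGroups] = None) -> StagingSystem:
    """Turn a merge result into a total, deployable staging system.

    The assignment is defined on observed cells; domain cells absent
    from the cohort inherit the group of the nearest observed cell in
    (T rank, N rank, TRG rank) lexicographic distance and are flagged.
    T4b always maps to the top group.  ``labels`` defaults to the
    conventional stage names when the group count allows, otherwise to
    generated ordinal labels.
    """
    node_groups = node_groups or MYPN_GROUPS_FIXED
    k = merge.n_groups
    if k < 2:
        raise AssemblyError("merge produced a single group; a staging system "
                            "needs at least 2 labels")
    if labels is None:
        labels = STAGE_LABELS if k == len(STAGE_LABELS) else tuple(
            f"G{i + 1}" for i in range(k))
    labels = tuple(labels)
    if len(labels) != k:
        raise AssemblyError(
            f"{k} merged groups but {len(labels)} labels supplied")

    t_ranks = {t: i for i, t in enumerate(T_CELL_GROUPS)}
    g_ranks = {g: i for i, g in enumerate(TRG_CELL_GROUPS)}
    observed = {key: grp for key, grp in merge.assignment.items()}

    table: dict[tuple[str, str, str], int] = {}
    flagged = []
    for t in T_CELL_GROUPS:
        if t == "T4b":
            table[("T4b", "any", "any")] = k - 1
            if ("T4b", "any", "any") not in observed:
                flagged.append(("T4b", "any", "any"))
            continue
        for nl in node_groups.labels:
            for gl in TRG_CELL_GROUPS:
                key = (t, nl, gl)
                if key in observed:
                    table[key] = observed[key]
                    continue
                # nearest observed cell, lexicographic (dT, dN, dTRG)
                n_rank = {lab: i for i, lab in enumerate(node_groups.labels)}
                cands = [
                    (abs(t_ranks[ot] - t_ranks[t]),
                     abs(n_rank.get(on, 0) - n_rank[nl]),
                     abs(g_ranks.get(og, 0) - g_ranks[gl]),
                     t_ranks[ot], n_rank.get(on, 0), g_ranks.get(og, 0), okey)
                    for okey in observed
                    for ot, on, og in [okey]
                    if ot != "T4b"
                ]
                if not cands:
                    raise AssemblyError(f"no observed cell to back-fill {key}")
                best = min(cands)
                table[key] = observed[best[-1]]
                flagged.append(key)

    def assign(ypT: str, n_pos: int, trg: int) -> str:
        t = t_group(ypT)
        if t == "T4b":
            return labels[k - 1]
        key = (t, node_groups.label_of(n_pos), trg_group(trg))
        return labels[table[key]]

    system = StagingSystem(name, labels, assign, tuple(flagged))
    system.cell_table = {key: labels[g] for key, g in table.items()}
    return system


class SubgroupMerger(BaseEstimator):
    """End-to-end subgroup refinement, scikit-learn style.

    ``fit(X, y)`` takes a cohort-shaped DataFrame ``X`` (columns
    ``ypT``, ``n_pos``, ``trg``) and a survival outcome ``y`` as a
    ``(times, events)`` tuple; it builds the cells, merges them under
    the p-value threshold and assembles a staging system.  Fitted
    attributes: ``cells_``, ``merge_result_``, ``system_``,
    ``n_groups_``.  ``predict(X)`` returns stage labels.
    """

    def __init__(self, threshold: float = 0.15,
                 node_groups: Optional[NodeGroups] = None,
                 name: str = "refined",
                 labels: Optional[Sequence[str]] = None):
        self.threshold = threshold
        self.node_groups = node_groups
        self.name = name
        self.labels = labels

    def fit(self, X, y):
        import pandas as pd

        if not isinstance(X, pd.DataFrame):
            raise DomainError("X must be a DataFrame with ypT, n_pos, trg")
        times, events = y
        df = X.copy()
        df["time_months"] = np.asarray(times, dtype=float)
        df["event"] = np.asarray(events, dtype=int)
        if "id" not in df.columns:
            df["id"] = [str(i) for i in range(len(df))]
        if "n_resected" not in df.columns:
            df["n_resected"] = df["n_pos"]
        cohort = Cohort(df)
        self.cells_ = build_subgroups(cohort, self.node_groups)
        self.merge_result_ = merge_subgroups(
            self.cells_, cohort.times, cohort.events, self.threshold)
        self.system_ = assemble_system(self.merge_result_, self.name,
                                       self.labels,
                                       self.node_groups or MYPN_GROUPS_FIXED)
        self.n_groups_ = self.merge_result_.n_groups
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "system_"):
            raise DomainError("merger is not fitted")
        return np.array([
            self.system_.assign(t, int(n), int(g))
            for t, n, g in zip(X["ypT"], X["n_pos"], X["trg"])
        ], dtype=object)


def system_to_json(system: StagingSystem, path) -> None:
    """Serialise a cell-table system as an exhaustive JSON lookup."""
    if not hasattr(system, "cell_table"):
        raise DomainError("system has no cell table to serialise")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({
            "name": system.name,
            "labels": list(system.labels),
            "cells": {"|".join(key): lab
                      for key, lab in system.cell_table.items()},
            "flagged": ["|".join(key) for key in system.flagged_cells],
        }, fh, indent=2)


def system_from_json(path, node_groups: Optional[NodeGroups] = None
                     ) -> StagingSystem:
    node_groups = node_groups or MYPN_GROUPS_FIXED
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    table = {tuple(k.split("|")): v for k, v in data["cells"].items()}
    labels = tuple(data["labels"])

    def assign(ypT: str, n_pos: int, trg: int) -> str:
        t = t_group(ypT)
        if t == "T4b":
            return table[("T4b", "any", "any")]
        return table[(t, node_groups.label_of(n_pos), trg_group(trg))]

    system = StagingSystem(data["name"], labels, assign,
                           tuple(tuple(k.split("|")) for k in data["flagged"]))
    system.cell_table = table
    return system
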