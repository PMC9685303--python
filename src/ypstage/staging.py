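"""Post-neoadjuvant (yp) staging lookups.

Two staging systems are shipped as total, validated mappings from
(ypT category, count of positive regional nodes, tumour regression
grade) to an ordered stage label:

* the eighth AJCC ypTNM system (T and N only; WECC T groups ypT0-2,
  ypT3, ypT4a, ypT4b and N by 0 / 1-2 / 3-6 / >=7 positive nodes), and
* the modified (myp) system, which recodes N as 0 / 1-2 / >=3 positive
  nodes and adds the collapsed tumour-regression grade (0-1, 2, 3) as a
  staging element.

The myp system modifies only the nodal grouping and adds TRG; its T
boundaries are the unchanged yp ones.  Stage order for trend and
concordance scoring is I < II < IIIA < IIIB < IVA with integer ranks
0..4, treating stages as ordinal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .cohort import Cohort, TRG_GRADES, YPT_CATEGORIES
from .exceptions import DomainError

STAGE_LABELS: tuple[str, ...] = ("I", "II", "IIIA", "IIIB", "IVA")

T_GROUPS: tuple[str, ...] = ("T0-2", "T3", "T4a", "T4b")
TRG_GROUPS: tuple[str, ...] = ("0-1", "2", "3")
MYPN_GROUPS: tuple[str, ...] = ("mypN0", "mypN1", "mypN2")


def t_group(ypT: str) -> str:
    """Collapse a ypT category to its WECC yp stage group."""
    if ypT not in YPT_CATEGORIES:
        raise DomainError(f"unknown ypT category {ypT!r}; valid: {YPT_CATEGORIES}")
    if ypT in ("T0", "T1", "T2"):
        return "T0-2"
    return ypT


def trg_group(trg: int) -> str:
    """Collapse the four-level CAP regression grade to {0-1, 2, 3}."""
    if trg not in TRG_GRADES:
        raise DomainError(f"trg must be one of {TRG_GRADES}")
    return "0-1" if trg <= 1 else str(trg)


def ajcc_ypN(n_pos: int) -> str:
    """Eighth AJCC ypN category from the positive-node count."""
    if n_pos < 0:
        raise DomainError("n_pos must be nonnegative")
    if n_pos == 0:
        return "N0"
    if n_pos <= 2:
        return "N1"
    if n_pos <= 6:
        return "N2"
    return "N3"


def mypN(n_pos: int) -> str:
    """Modified nodal group: 0, 1-2, or >=3 positive nodes."""
    if n_pos < 0:
        raise DomainError("n_pos must be nonnegative")
    if n_pos == 0:
        return "mypN0"
    if n_pos <= 2:
        return "mypN1"
    return "mypN2"


def ajcc_ypTNM(ypT: str, n_pos: int) -> str:
    """Eighth AJCC ypTNM stage group (squamous, M0 surgical cohort).

    N3 forces IVA regardless of T, and T4b forces IVA regardless of N.
    TRG is never consulted.
    """
    tg = t_group(ypT)
    N = ajcc_ypN(n_pos)
    if N == "N3" or tg == "T4b":
        return "IVA"
    if tg == "T0-2":
        return {"N0": "I", "N1": "IIIA", "N2": "IIIB"}[N]
    if tg == "T3":
        return {"N0": "II", "N1": "IIIB", "N2": "IIIB"}[N]
    # T4a
    return {"N0": "IIIB", "N1": "IVA", "N2": "IVA"}[N]


def myp_stage(ypT: str, n_pos: int, trg: int) -> str:
    """Modified yp stage from T group, modified N group and TRG group.

    T4b maps to IVA for any nodal status or regression grade; T4a is
    staged by nodes only (N0 -> IIIA, N1-2 -> IIIB).
    """
    tg = t_group(ypT)
    if tg == "T4b":
        if n_pos < 0:
            raise DomainError("n_pos must be nonnegative")
        if trg not in TRG_GRADES:
            raise DomainError(f"trg must be one of {TRG_GRADES}")
        return "IVA"
    N = mypN(n_pos)
    g = trg_group(trg)
    if tg == "T4a":
        return "IIIA" if N == "mypN0" else "IIIB"
    if tg == "T0-2":
        if N == "mypN0":
            return "I" if g == "0-1" else "II"
        if N == "mypN1":
            return "IIIA" if g == "3" else "II"
        return "IIIA"  # mypN2
    # T3
    if N == "mypN0":
        return {"0-1": "I", "2": "II", "3": "IIIA"}[g]
    if N == "mypN1":
        return "IIIA"
    return "IIIB"  # mypN2


@dataclass(frozen=True)
class StageLabel:
    label: str
    rank: int


@dataclass
class StagingSystem:
    """An ordered set of stage labels plus a total assignment rule."""

    name: str
    labels: tuple[str, ...]
    assign: Callable[[str, int, int], str]
    flagged_cells: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if len(self.labels) < 2:
            raise DomainError("a staging system needs at least 2 labels")
        if len(set(self.labels)) != len(self.labels):
            raise DomainError("stage labels must be unique")

    def rank_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise DomainError(f"unknown stage label {label!r}") from None

    def stage_labels(self) -> list[StageLabel]:
        return [StageLabel(lab, i) for i, lab in enumerate(self.labels)]

    def check_total(self, max_nodes: int = 20) -> None:
        """Exhaustively verify the mapping over the input domain."""
        for ypT in YPT_CATEGORIES:
            for n_pos in range(max_nodes + 1):
                for trg in TRG_GRADES:
                    lab = self.assign(ypT, n_pos, trg)
                    if lab not in self.labels:
                        raise DomainError(
                            f"{self.name}: ({ypT}, {n_pos}, {trg}) -> "
                            f"unknown label {lab!r}"
                        )


AJCC8_YP = StagingSystem(
    "ajcc8yp", STAGE_LABELS, lambda ypT, n_pos, trg: ajcc_ypTNM(ypT, n_pos)
)
MYP = StagingSystem("myp", STAGE_LABELS, myp_stage)

BUILTIN_SYSTEMS = {"ajcc8yp": AJCC8_YP, "myp": MYP}


def annotate_cohort(cohort: Cohort, system: StagingSystem) -> np.ndarray:
    """One stage label per patient, in cohort order."""
    return np.array(
        [system.assign(t, int(n), int(g))
         for t, n, g in zip(cohort.ypT, cohort.n_pos, cohort.trg)],
        dtype=object,
    )


def stage_ranks(cohort: Cohort, system: StagingSystem) -> np.ndarray:
    """Integer ordinal rank of each patient's stage label."""
    labels = annotate_cohort(cohort, system)
    lut = {lab: i for i, lab in enumerate(system.labels)}
    return np.array([lut[lab] for lab in labels], dtype=int)
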