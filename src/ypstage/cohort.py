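"""Patient-level cohort container and delimited-text I/O.

A cohort is a table of surgically resected patients staged after
neoadjuvant radiotherapy / chemoradiotherapy.  Each row carries the
post-neoadjuvant tumour depth category (ypT0–T4b), the count of
pathologically positive regional lymph nodes, the count of resected
nodes, the CAP/modified-Ryan tumour regression grade (TRG 0–3), and a
right-censored overall-survival outcome (months from operation, event
indicator).  Optional treatment covariates (sex, concurrent
chemotherapy, radiation dose) may be present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .exceptions import DomainError, SchemaError

YPT_CATEGORIES: tuple[str, ...] = ("T0", "T1", "T2", "T3", "T4a", "T4b")
TRG_GRADES: tuple[int, ...] = (0, 1, 2, 3)

MANDATORY_COLUMNS = ("id", "ypT", "n_pos", "n_resected", "trg", "time_months", "event")
OPTIONAL_COLUMNS = ("sex", "chemo", "dose_gy")


@dataclass(frozen=True)
class Patient:
    """One subject: staging inputs plus censored survival outcome.

    ``trg`` is on the four-level CAP scale; downstream staging collapses
    it to {0–1, 2, 3}.  ``event`` is 1 for death, 0 for censoring.
    """

    id: str
    ypT: str
    n_pos: int
    n_resected: int
    trg: int
    time_months: float
    event: int
    sex: Optional[str] = None
    chemo: Optional[int] = None
    dose_gy: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ypT not in YPT_CATEGORIES:
            raise DomainError(
                f"unknown ypT category {self.ypT!r}; valid: {YPT_CATEGORIES}"
            )
        if self.n_pos < 0:
            raise DomainError("n_pos must be nonnegative")
        if self.n_resected < self.n_pos:
            raise DomainError("n_resected must be >= n_pos")
        if self.trg not in TRG_GRADES:
            raise DomainError(f"trg must be one of {TRG_GRADES}")
        if not self.time_months > 0:
            raise DomainError("time_months must be positive")
        if self.event not in (0, 1):
            raise DomainError("event must be 0 or 1")


class Cohort:
    """Ordered, validated collection of patients backed by a DataFrame."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        self.df = df.reset_index(drop=True)
        if validate:
            self.validate()

    # -- construction -------------------------------------------------
    @classmethod
    def from_patients(cls, patients: Iterable[Patient]) -> "Cohort":
        rows = [vars(p) for p in patients]
        if not rows:
            raise DomainError("cohort must be non-empty")
        df = pd.DataFrame(rows)
        # drop all-missing optional columns so round-trips are clean
        for col in OPTIONAL_COLUMNS:
            if col in df.columns and df[col].isna().all():
                df = df.drop(columns=[col])
        return cls(df)

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        df = self.df
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing mandatory column {col!r}")
        if len(df) == 0:
            raise SchemaError("cohort must be non-empty")
        ids = df["id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise SchemaError(f"duplicate patient id {dup!r}")

        def _bad_row(mask: np.ndarray) -> int:
            # 1-based data-row number, as users count rows in the file
            return int(np.flatnonzero(mask)[0]) + 1

        bad = ~df["ypT"].isin(YPT_CATEGORIES)
        if bad.any():
            raise SchemaError(
                f"invalid ypT category on row {_bad_row(bad.to_numpy())}; "
                f"valid: {YPT_CATEGORIES}"
            )
        time = pd.to_numeric(df["time_months"], errors="coerce")
        bad = time.isna() | (time <= 0)
        if bad.any():
            raise SchemaError(
                f"non-numeric or non-positive time_months on row "
                f"{_bad_row(bad.to_numpy())}"
            )
        event = pd.to_numeric(df["event"], errors="coerce")
        bad = ~event.isin([0, 1])
        if bad.any():
            raise SchemaError(f"event outside {{0,1}} on row {_bad_row(bad.to_numpy())}")
        for col in ("n_pos", "n_resected"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() | (vals < 0) | (vals != vals.round())
            if bad.any():
                raise SchemaError(
                    f"{col} must be a nonnegative integer; bad value on row "
                    f"{_bad_row(bad.to_numpy())}"
                )
        bad = df["n_pos"].to_numpy() > df["n_resected"].to_numpy()
        if bad.any():
            raise SchemaError(f"n_pos > n_resected on row {_bad_row(bad)}")
        bad = ~df["trg"].isin(TRG_GRADES)
        if bad.any():
            raise SchemaError(f"trg outside {TRG_GRADES} on row {_bad_row(bad.to_numpy())}")

    # -- accessors ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        a, b = self.df, other.df
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        return all(
            a[c].astype(a[c].dtype).equals(b[c].astype(a[c].dtype)) for c in a.columns
        )

    @property
    def times(self) -> np.ndarray:
        return self.df["time_months"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.df["event"].to_numpy(dtype=int)

    @property
    def n_pos(self) -> np.ndarray:
        return self.df["n_pos"].to_numpy(dtype=int)

    @property
    def ypT(self) -> np.ndarray:
        return self.df["ypT"].to_numpy(dtype=object)

    @property
    def trg(self) -> np.ndarray:
        return self.df["trg"].to_numpy(dtype=int)

    def patients(self) -> list[Patient]:
        cols = [c for c in self.df.columns if c in MANDATORY_COLUMNS + OPTIONAL_COLUMNS]
        out = []
        for row in self.df[cols].itertuples(index=False):
            d = row._asdict()
            d["id"] = str(d["id"])
            d["n_pos"] = int(d["n_pos"])
            d["n_resected"] = int(d["n_resected"])
            d["trg"] = int(d["trg"])
            d["event"] = int(d["event"])
            out.append(Patient(**d))
        return out


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as comma-delimited UTF-8 text with a header row.

    Floats are written at full precision so the file round-trips
    exactly (reading uses the round-trip float parser).
    """
    cohort.df.to_csv(path, index=False, encoding="utf-8")


def read_cohort(path) -> Cohort:
    """Read and validate a cohort file written by :func:`write_cohort`."""
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    if "dose_gy" in df.columns:  # float column even when values are whole
        df["dose_gy"] = df["dose_gy"].astype(float)
    cohort = Cohort(df)
    cohort.df["id"] = cohort.df["id"].astype(str)
    return cohort
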