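"""Head-to-head evaluation of staging systems on a cohort.

Each system is scored on four complementary axes:

* monotonicity — linear-trend log-rank chi-square across the ordered
  stage groups (larger = better ordered separation);
* homogeneity — likelihood-ratio chi-square of a Cox model on stage
  indicator variables (larger = more within-stage homogeneity);
* parsimony-adjusted fit — AIC of that Cox model (smaller = better);
* discrimination — Harrell's c of a per-patient risk score
  (0.5 = random, 1 = perfect).

Prognostic performance over time is compared with IPCW cumulative/
dynamic time-dependent AUC curves on a common grid, with paired-
bootstrap p-values for between-system differences at named times.

The risk score for c and AUC has two modes: the Cox linear predictor
on stage indicators (default, matching common practice for staging
comparisons) or the raw ordinal stage rank.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .exceptions import DomainError, EvaluationError, UndefinedResultError
from .staging import StagingSystem, annotate_cohort
from . import survstats as ss

RISK_MODES = ("ordinal", "cox_predictor")
DEFAULT_GRID = (12.0, 24.0, 36.0, 48.0, 60.0)


@dataclass
class SystemScore:
    """Table-2-style metrics for one staging system on one cohort."""

    system: str
    mode: str
    trend_chi2: float
    trend_p: float
    lr_chi2: float
    lr_df: int
    aic: float
    harrell_c: float
    n: int
    n_events: int
    n_observed_stages: int
    dropped_labels: tuple = ()


def _stage_design(labels: np.ndarray, system: StagingSystem):
    """Observed ordinal ranks and an indicator design (reference = lowest)."""
    observed = [lab for lab in system.labels if (labels == lab).any()]
    dropped = tuple(lab for lab in system.labels if lab not in observed)
    if len(observed) < 2:
        raise EvaluationError(
            f"system {system.name!r} has {len(observed)} observed stage "
            "group(s); need at least 2")
    rank = {lab: i for i, lab in enumerate(observed)}
    ranks = np.array([rank[lab] for lab in labels], dtype=float)
    X = np.column_stack([(labels == lab).astype(float) for lab in observed[1:]])
    names = [f"stage[{lab}]" for lab in observed[1:]]
    return observed, dropped, ranks, X, names


def risk_scores(cohort: Cohort, system: StagingSystem,
                mode: str = "cox_predictor") -> np.ndarray:
    """Per-patient risk score under the requested mode."""
    if mode not in RISK_MODES:
        raise DomainError(f"mode must be one of {RISK_MODES}")
    labels = annotate_cohort(cohort, system)
    observed, _, ranks, X, names = _stage_design(labels, system)
    if mode == "ordinal":
        return ranks
    model = ss.cox_fit(X, cohort.times, cohort.events, names=names)
    return ss.cox_linear_predictor(model, X)


def score_system(cohort: Cohort, system: StagingSystem,
                 mode: str = "cox_predictor") -> SystemScore:
    """Monotonicity, homogeneity, AIC and discrimination for one system."""
    if mode not in RISK_MODES:
        raise DomainError(f"mode must be one of {RISK_MODES}")
    if len(cohort) == 0:
        raise DomainError("empty cohort")
    labels = annotate_cohort(cohort, system)
    observed, dropped, ranks, X, names = _stage_design(labels, system)
    times, events = cohort.times, cohort.events
    trend = ss.trend_logrank(ranks, times, events)
    model = ss.cox_fit(X, times, events, names=names)
    score = (ranks if mode == "ordinal"
             else ss.cox_linear_predictor(model, X))
    conc = ss.harrell_c(score, times, events)
    return SystemScore(
        system.name, mode, trend.chi2, trend.p, ss.lr_chi2(model),
        model.n_params, ss.aic(model), conc.c, len(cohort),
        int(events.sum()), len(observed), dropped,
    )


@dataclass
class ComparisonReport:
    """Joint evaluation of several systems on one cohort."""

    scores: list
    grid_times: tuple
    auc: dict  # system name -> {"auc": [...], "se": [...], "defined": [...]}
    auc_pvalues: dict  # "a|b|t" -> p
    config: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "scores": [asdict(s) for s in self.scores],
            "grid_times": list(self.grid_times),
            "auc": self.auc,
            "auc_pvalues": self.auc_pvalues,
            "config": self.config,
        }
        text = json.dumps(payload, indent=2, default=_jsonify)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ComparisonReport":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source, encoding="utf-8") as fh:
                data = json.load(fh)
        scores = [SystemScore(**{**d, "dropped_labels": tuple(d["dropped_labels"])})
                  for d in data["scores"]]
        return cls(scores, tuple(data["grid_times"]), data["auc"],
                   data["auc_pvalues"], data["config"])

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"system": s.system, "trend_chi2": s.trend_chi2,
             "lr_chi2": s.lr_chi2, "aic": s.aic, "harrell_c": s.harrell_c}
            for s in self.scores
        ])


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def compare_systems(cohort: Cohort, systems: Sequence[StagingSystem],
                    grid_times: Sequence[float] = DEFAULT_GRID,
                    seed: int = 0, mode: str = "cox_predictor",
                    n_boot: int = 1000,
                    compare_times: Optional[Sequence[float]] = None
                    ) -> ComparisonReport:
    """Score every system and compare their AUC curves pairwise.

    All systems are evaluated on the identical cohort and AUC grid;
    ``compare_times`` (default: the whole grid) selects where the
    paired-bootstrap AUC difference test is run.
    """
    if len(systems) < 2:
        raise DomainError("need at least two systems to compare")
    names = [s.name for s in systems]
    if len(set(names)) != len(names):
        raise DomainError("system names must be unique")
    grid = tuple(float(t) for t in grid_times)
    compare_times = tuple(float(t) for t in
                          (grid if compare_times is None else compare_times))

    scores = [score_system(cohort, s, mode) for s in systems]
    curves = {}
    auc_out = {}
    for s in systems:
        r = risk_scores(cohort, s, mode)
        curve = ss.td_auc(r, cohort.times, cohort.events, grid)
        curves[s.name] = curve
        auc_out[s.name] = {
            "auc": curve.auc.tolist(),
            "se": curve.se.tolist(),
            "defined": curve.defined.tolist(),
            "estimator": curve.estimator,
        }
    pvals = {}
    for i in range(len(systems)):
        for j in range(i + 1, len(systems)):
            a, b = systems[i].name, systems[j].name
            for t in compare_times:
                try:
                    p = ss.compare_auc(curves[a], curves[b], t,
                                       n_boot=n_boot, seed=seed)
                except UndefinedResultError:
                    p = float("nan")
                pvals[f"{a}|{b}|{t:g}"] = p
    config = {"seed": seed, "mode": mode, "n_boot": n_boot,
              "n": len(cohort), "systems": names}
    return ComparisonReport(scores, grid, auc_out, pvals, config)


# ---------------------------------------------------------------------
# univariable screen -> multivariable Cox workflow
# ---------------------------------------------------------------------
def univariable_screen(cohort: Cohort, factors: Sequence[str],
                       alpha: float = 0.05) -> pd.DataFrame:
    """Log-rank p-value per categorical factor.

    Factors with p < ``alpha`` are flagged for the multivariable step;
    constant factors are recorded as undefined and excluded.
    """
    rows = []
    for factor in factors:
        if factor not in cohort.df.columns:
            raise DomainError(f"factor {factor!r} not in cohort")
        values = cohort.df[factor].astype(str).to_numpy()
        if len(set(values)) < 2:
            rows.append({"factor": factor, "p": np.nan, "defined": False,
                         "selected": False})
            continue
        res = ss.logrank(values, cohort.times, cohort.events)
        rows.append({"factor": factor, "p": res.p, "defined": True,
                     "selected": bool(res.p < alpha)})
    return pd.DataFrame(rows)


def multivariable_fit(cohort: Cohort, factors: Sequence[str]):
    """Cox fit with indicator coding plus a hazard-ratio table.

    Reference level per factor is its most frequent category.  Returns
    ``(model, hr_table, schoenfeld)`` where the table carries hazard
    ratios with 95% Wald confidence intervals and the proportional-
    hazards global test is attached.
    """
    if not factors:
        raise DomainError("need at least one factor")
    cols, names = [], []
    for factor in factors:
        values = cohort.df[factor].astype(str).to_numpy()
        levels = pd.Series(values).value_counts().index.tolist()
        ref = levels[0]
        for lev in sorted(set(values) - {ref}):
            cols.append((values == lev).astype(float))
            names.append(f"{factor}[{lev} vs {ref}]")
    X = np.column_stack(cols)
    model = ss.cox_fit(X, cohort.times, cohort.events, names=names)
    z = 1.959963984540054  # Phi^{-1}(0.975)
    hr = np.exp(model.coef)
    lo = np.exp(model.coef - z * model.se)
    hi = np.exp(model.coef + z * model.se)
    table = pd.DataFrame({
        "term": names, "coef": model.coef, "hr": hr,
        "hr_lo95": lo, "hr_hi95": hi, "se": model.se,
    })
    schoenfeld = ss.schoenfeld_global_test(model, X, cohort.times,
                                           cohort.events)
    return model, table, schoenfeld
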