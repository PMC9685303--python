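"""From-first-principles survival statistics.

Everything downstream — nodal reclassification, subgroup merging and
staging-system comparison — rests on the estimators and tests in this
module: the Kaplan–Meier product-limit estimator, the (linear-trend)
log-rank test, Cox partial-likelihood fitting with Efron or Breslow tie
handling, likelihood-ratio chi-square and AIC, Harrell's concordance
index, the Grambsch–Therneau global test on scaled Schoenfeld
residuals, and the IPCW cumulative/dynamic time-dependent AUC.

Conventions
-----------
* At tied observed times, deaths are processed before censorings: a
  subject censored at an event time is still at risk at that time.
* All p-values are two-sided upper-tail chi-square probabilities.
* Higher risk score means higher hazard (shorter expected survival).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    ConvergenceError,
    DomainError,
    RankError,
    UndefinedResultError,
)

__all__ = [
    "KMEstimate",
    "LogRankResult",
    "TrendLogRankResult",
    "CoxModel",
    "ConcordanceResult",
    "SchoenfeldResult",
    "AUCCurve",
    "km_estimate",
    "survival_at",
    "median_survival",
    "logrank",
    "trend_logrank",
    "cox_fit",
    "lr_chi2",
    "aic",
    "harrell_c",
    "schoenfeld_global_test",
    "td_auc",
    "compare_auc",
]


def _check_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise DomainError("empty survival data")
    if times.shape != events.shape:
        raise DomainError("times and events must have the same length")
    if np.any(times <= 0):
        raise DomainError("survival times must be positive")
    if not np.isin(events, [0, 1]).all():
        raise DomainError("event indicators must be 0 or 1")
    return times, events.astype(int)


# ---------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------
@dataclass
class KMEstimate:
    """Product-limit estimate of a survival function.

    ``event_times`` lists the distinct times with at least one death;
    ``survival`` is the estimate just after each such time (the curve is
    a right-continuous step function with S(0) = 1).
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    variance: np.ndarray
    n: int
    max_time: float


def km_estimate(times, events) -> KMEstimate:
    times, events = _check_surv(times, events)
    order = np.argsort(times, kind="mergesort")
    t, e = times[order], events[order]
    n = t.size
    # distinct times, deaths and removals at each
    ut, first = np.unique(t, return_index=True)
    counts = np.diff(np.append(first, n))
    deaths = np.add.reduceat(e, first) if n else np.array([])
    at_risk = n - np.concatenate(([0], np.cumsum(counts)[:-1]))
    keep = deaths > 0
    ut, deaths, at_risk = ut[keep], deaths[keep], at_risk[keep]
    surv = np.cumprod(1.0 - deaths / at_risk)
    # Greenwood variance
    terms = deaths / (at_risk * (at_risk - deaths).clip(min=1))
    terms = np.where(at_risk == deaths, np.inf, terms)
    with np.errstate(invalid="ignore"):
        var = surv**2 * np.cumsum(terms)
    var = np.where(np.isfinite(var), var, 0.0)
    return KMEstimate(ut, surv, at_risk, deaths, var, n, float(t[-1]))


def survival_at(km: KMEstimate, t: float, side: str = "right",
                return_flag: bool = False):
    """Evaluate the KM step function at time ``t``.

    ``side='right'`` gives the right-continuous value S(t); ``side='left'``
    the left limit S(t-) (used for IPCW weights).  Beyond the last
    observed time the last value is carried forward; ``return_flag``
    additionally reports whether that extrapolation happened.
    """
    if t < 0:
        raise DomainError("t must be nonnegative")
    side_arg = "right" if side == "right" else "left"
    idx = np.searchsorted(km.event_times, t, side=side_arg)
    value = 1.0 if idx == 0 else float(km.survival[idx - 1])
    extrapolated = t > km.max_time
    return (value, extrapolated) if return_flag else value


def median_survival(km: KMEstimate) -> float:
    """Smallest event time with S(t) <= 0.5, or inf if never reached."""
    below = km.survival <= 0.5
    return float(km.event_times[below][0]) if below.any() else float("inf")


# ---------------------------------------------------------------------
# Log-rank family
# ---------------------------------------------------------------------
@dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float
    groups: list
    observed: np.ndarray
    expected: np.ndarray


@dataclass
class TrendLogRankResult:
    chi2: float
    df: int
    p: float
    groups: list
    scores: np.ndarray
    observed: np.ndarray
    expected: np.ndarray


def _logrank_tables(labels, times, events):
    """Per-event-time O, E and full hypergeometric covariance, summed."""
    times, events = _check_surv(times, events)
    labels = np.asarray(labels)
    if labels.shape != times.shape:
        raise DomainError("labels must match times in length")
    groups = sorted(set(labels.tolist()), key=str)
    G = len(groups)
    if G < 2:
        raise DomainError("need at least two non-empty groups")
    gidx = np.searchsorted(np.array([str(g) for g in groups]), labels.astype(str))

    et = np.unique(times[events == 1])
    T = et.size
    n_gt = np.empty((G, T))
    d_gt = np.zeros((G, T))
    for g in range(G):
        sel = gidx == g
        tg = np.sort(times[sel])
        n_gt[g] = tg.size - np.searchsorted(tg, et, side="left")
        tg_e = times[sel & (events == 1)]
        if tg_e.size:
            pos = np.searchsorted(et, tg_e)
            np.add.at(d_gt[g], pos, 1.0)
    N_t = n_gt.sum(axis=0)
    d_t = d_gt.sum(axis=0)
    O = d_gt.sum(axis=1)
    E = (d_t * n_gt / N_t).sum(axis=1)
    # covariance of (O - E): sum over event times of hypergeometric cov
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = d_t * (N_t - d_t) / (N_t - 1)
    factor = np.where(N_t > 1, factor, 0.0)
    P = n_gt / N_t  # (G, T)
    V = np.einsum("t,gt,ht->gh", factor, P, -P)
    V[np.diag_indices(G)] += np.einsum("t,gt->g", factor, P)
    return groups, O, E, V


def logrank(labels, times, events) -> LogRankResult:
    """Standard (unweighted) log-rank test across G groups, df = G-1."""
    groups, O, E, V = _logrank_tables(labels, times, events)
    G = len(groups)
    d = (O - E)[:-1]
    Vr = V[:-1, :-1]
    try:
        chi2 = float(d @ np.linalg.solve(Vr, d))
    except np.linalg.LinAlgError:
        chi2 = float(d @ np.linalg.pinv(Vr) @ d)
    chi2 = max(chi2, 0.0)
    df = G - 1
    p = float(stats.chi2.sf(chi2, df))
    return LogRankResult(chi2, df, p, groups, O, E)


def trend_logrank(labels, times, events,
                  scores: Optional[Sequence[float]] = None) -> TrendLogRankResult:
    """Linear-trend (1-df) log-rank test for ordered groups.

    Groups are taken in sorted-label order; ``scores`` default to the
    ranks 0..G-1.  The statistic is invariant to affine transformations
    of the scores, and for G = 2 coincides with the ordinary log-rank
    chi-square.  A larger chi-square indicates a stronger monotone
    separation of the ordered groups.
    """
    groups, O, E, V = _logrank_tables(labels, times, events)
    G = len(groups)
    if scores is None:
        scores = np.arange(G, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (G,):
        raise DomainError(f"need one score per group ({G})")
    U = float(scores @ (O - E))
    varU = float(scores @ V @ scores)
    if varU <= 0:
        raise UndefinedResultError("degenerate variance in trend test")
    chi2 = U * U / varU
    p = float(stats.chi2.sf(chi2, 1))
    return TrendLogRankResult(chi2, 1, p, groups, scores, O, E)


# ---------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------
@dataclass
class CoxModel:
    """Fitted proportional-hazards model (partial likelihood)."""

    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    n_params: int
    ties: str
    n_iter: int
    converged: bool
    names: list
    information: np.ndarray = field(repr=False, default=None)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _cox_quantities(X, w, t_sorted, e_sorted, ties):
    """loglik, score and information at weights w = exp(X beta).

    Arrays are pre-sorted ascending in time.  Ties are handled with the
    Efron or Breslow correction.
    """
    n, p = X.shape
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    # suffix sums: risk-set aggregates at each sorted position
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ev = np.flatnonzero(e_sorted == 1)
    t_ev = t_sorted[ev]
    # group tied event times
    ut, gfirst = np.unique(t_ev, return_index=True)
    gcount = np.diff(np.append(gfirst, ev.size))
    # risk-set entry index: first sorted position with time == ut[j]
    entry = np.searchsorted(t_sorted, ut, side="left")
    S0R, S1R, S2R = S0[entry], S1[entry], S2[entry]
    # tied-death sums
    S0D = np.add.reduceat(w[ev], gfirst)
    S1D = np.add.reduceat(wx[ev], gfirst, axis=0)
    S2D = np.add.reduceat(wxx[ev], gfirst, axis=0)
    xev_sum = X[ev].sum(axis=0)

    # expand Efron death slots: for group j, l = 0..D_j-1
    reps = gcount
    l_over_D = (
        np.concatenate([np.arange(d) / d for d in gcount])
        if ties == "efron"
        else np.zeros(int(gcount.sum()))
    )
    j_of_slot = np.repeat(np.arange(ut.size), reps)
    phi0 = S0R[j_of_slot] - l_over_D * S0D[j_of_slot]
    phi1 = S1R[j_of_slot] - l_over_D[:, None] * S1D[j_of_slot]
    phi2 = S2R[j_of_slot] - l_over_D[:, None, None] * S2D[j_of_slot]

    log_terms = np.log(phi0)
    psi = phi1 / phi0[:, None]
    info = (phi2 / phi0[:, None, None] - psi[:, :, None] * psi[:, None, :]).sum(axis=0)
    score = xev_sum - psi.sum(axis=0)
    return log_terms.sum(), score, info, (ut, gfirst, gcount, entry)


def cox_fit(X, times, events, ties: str = "efron",
            names: Optional[Sequence[str]] = None,
            max_iter: int = 100, tol_score: float = 1e-8,
            tol_loglik: float = 1e-10) -> CoxModel:
    """Maximise the Cox partial likelihood by Newton–Raphson.

    ``X`` may have zero columns (the null model).  Raises
    :class:`ConvergenceError` on monotone likelihood (separation),
    naming the offending covariate, and :class:`RankError` on a
    singular information matrix.
    """
    times, events = _check_surv(times, events)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != times.size:
        X = X.T
    n, p = X.shape
    if n != times.size:
        raise DomainError("design matrix rows must match number of subjects")
    if events.sum() < 1:
        raise DomainError("need at least one event")
    if ties not in ("efron", "breslow"):
        raise DomainError("ties must be 'efron' or 'breslow'")
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]
    if p and np.any(X.std(axis=0) == 0):
        j = int(np.flatnonzero(X.std(axis=0) == 0)[0])
        raise DomainError(f"constant column in design matrix: {names[j]}")

    order = np.argsort(times, kind="mergesort")
    Xs, ts, es = X[order], times[order], events[order]

    def full_loglik(beta):
        lp = Xs @ beta
        logsum, score, info, _ = _cox_quantities(Xs, np.exp(lp), ts, es, ties)
        ll = float(lp[es == 1].sum() - logsum)
        return ll, score, info

    if p == 0:
        logsum, _, _, _ = _cox_quantities(Xs.reshape(n, 0), np.ones(n), ts, es, ties)
        ll = -float(logsum)
        return CoxModel(np.zeros(0), np.zeros((0, 0)), ll, ll, 0, ties, 0, True,
                        [], np.zeros((0, 0)))

    beta = np.zeros(p)
    ll, score, info = full_loglik(beta)
    ll_null = ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise RankError("singular information matrix in Cox fit")
        # step halving to guarantee ascent
        new_beta = beta + step
        new_ll, new_score, new_info = full_loglik(new_beta)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll) and halvings < 30:
            step = step / 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = full_loglik(new_beta)
            halvings += 1
        beta, prev_ll, ll, score, info = new_beta, ll, new_ll, new_score, new_info
        # scale-aware divergence check: a log hazard ratio above ~15 per
        # covariate standard deviation only arises under monotone
        # likelihood (perfect separation)
        scaled = np.abs(beta) * X.std(axis=0)
        if np.any(scaled > 15):
            j = int(np.argmax(scaled))
            raise ConvergenceError(
                f"monotone partial likelihood (perfect separation) for "
                f"covariate {names[j]!r}"
            )
        if np.max(np.abs(score)) < tol_score or (
            abs(ll - prev_ll) < tol_loglik * (abs(prev_ll) + 1e-300)
        ):
            converged = True
            break
    if not converged:
        j = int(np.argmax(np.abs(beta)))
        raise ConvergenceError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(largest coefficient: {names[j]!r})"
        )
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise RankError("singular information matrix at the optimum")
    return CoxModel(beta, cov, float(ll), float(ll_null), p, ties, it, True,
                    names, info)


def cox_linear_predictor(model: CoxModel, X) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return X @ model.coef


def lr_chi2(model: CoxModel) -> float:
    """Likelihood-ratio chi-square, 2*(fitted - null) partial log-lik."""
    return 2.0 * (model.loglik - model.loglik_null)


def aic(model: CoxModel) -> float:
    """Akaike information criterion: -2 log L + 2 * #parameters."""
    return -2.0 * model.loglik + 2.0 * model.n_params


# ---------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------
@dataclass
class ConcordanceResult:
    c: float
    concordant: float
    discordant: float
    tied_risk: float
    comparable: float


def harrell_c(scores, times, events) -> ConcordanceResult:
    """Harrell's concordance index for right-censored data.

    A pair (i, j) is comparable when the shorter observed time is an
    event and is strictly shorter than the other time; pairs of equal
    event times are not comparable.  The pair is concordant when the
    shorter-lived subject has the higher risk score; score ties count
    one half.
    """
    times, events = _check_surv(times, events)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != times.shape:
        raise DomainError("scores must match times in length")
    ti, tj = times[:, None], times[None, :]
    si, sj = scores[:, None], scores[None, :]
    comp = (ti < tj) & (events[:, None] == 1)
    concordant = float((comp & (si > sj)).sum())
    discordant = float((comp & (si < sj)).sum())
    tied = float((comp & (si == sj)).sum())
    comparable = float(comp.sum())
    if comparable == 0:
        raise UndefinedResultError("no comparable pairs for concordance")
    c = (concordant + 0.5 * tied) / comparable
    return ConcordanceResult(c, concordant, discordant, tied, comparable)


# ---------------------------------------------------------------------
# Proportional-hazards diagnostic
# ---------------------------------------------------------------------
@dataclass
class SchoenfeldResult:
    chi2: float
    df: int
    p: float
    transform: str


def schoenfeld_global_test(model: CoxModel, X, times, events,
                           transform: str = "km") -> SchoenfeldResult:
    """Grambsch–Therneau global test on scaled Schoenfeld residuals.

    Schoenfeld residuals at each event are correlated with a transform
    of time (default: 1 - KM survival estimate); under proportional
    hazards the correlation vanishes.  The global statistic is
    chi-square with one df per covariate.
    """
    times, events = _check_surv(times, events)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != times.size:
        X = X.T
    n, p = X.shape
    if p < 1:
        raise DomainError("need at least one covariate")
    d = int(events.sum())
    if d <= p:
        raise RankError("fewer events than covariates plus one")

    order = np.argsort(times, kind="mergesort")
    Xs, ts, es = X[order], times[order], events[order]
    w = np.exp(Xs @ model.coef)
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
    ev = np.flatnonzero(es == 1)
    entry = np.searchsorted(ts, ts[ev], side="left")
    xbar = S1[entry] / S0[entry][:, None]
    resid = Xs[ev] - xbar  # (d, p)

    t_ev = ts[ev]
    if transform == "km":
        km = km_estimate(times, events)
        g = np.array([1.0 - survival_at(km, t, side="left") for t in t_ev])
    elif transform == "identity":
        g = t_ev.astype(float)
    elif transform == "rank":
        g = stats.rankdata(t_ev, method="average")
    else:
        raise DomainError("transform must be 'km', 'identity' or 'rank'")
    gc = g - g.mean()
    denom = float(gc @ gc)
    if denom <= 0:
        raise UndefinedResultError("degenerate time transform")
    u = resid.T @ gc  # (p,)
    try:
        chi2 = float(d * u @ np.linalg.solve(model.information, u) / denom)
    except np.linalg.LinAlgError:
        raise RankError("singular information matrix in Schoenfeld test")
    chi2 = max(chi2, 0.0)
    pval = float(stats.chi2.sf(chi2, p))
    return SchoenfeldResult(chi2, p, pval, transform)


# ---------------------------------------------------------------------
# Time-dependent AUC (IPCW cumulative/dynamic)
# ---------------------------------------------------------------------
@dataclass
class AUCCurve:
    """Time-dependent AUC on a grid, with undefined points flagged.

    Standard errors use a Hanley–McNeil approximation with effective
    (weighted) case/control counts; they are descriptive, not used for
    the bootstrap comparison test.
    """

    grid_times: np.ndarray
    auc: np.ndarray
    se: np.ndarray
    defined: np.ndarray
    estimator: str
    _scores: np.ndarray = field(repr=False, default=None)
    _times: np.ndarray = field(repr=False, default=None)
    _events: np.ndarray = field(repr=False, default=None)


def _ipcw_auc_at(scores, times, events, cens_km, t):
    """IPCW cumulative-case / dynamic-control AUC at a single time."""
    cases = (times <= t) & (events == 1)
    controls = times > t
    if not cases.any() or not controls.any():
        return np.nan, np.nan, False
    Gt = survival_at(cens_km, t, side="right")
    if Gt <= 0:
        return np.nan, np.nan, False
    w_case = np.array([1.0 / max(survival_at(cens_km, ti, side="left"), 1e-12)
                       for ti in times[cases]])
    w_ctrl = np.full(int(controls.sum()), 1.0 / Gt)
    sc, st = scores[cases][:, None], scores[controls][None, :]
    win = (sc > st) + 0.5 * (sc == st)
    W = w_case[:, None] * w_ctrl[None, :]
    denom = w_case.sum() * w_ctrl.sum()
    auc = float((W * win).sum() / denom)
    # Hanley–McNeil SE with effective sample sizes
    n1 = w_case.sum() ** 2 / (w_case**2).sum()
    n2 = w_ctrl.sum() ** 2 / (w_ctrl**2).sum()
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2)
           + (n2 - 1) * (q2 - auc**2)) / (n1 * n2)
    return auc, float(np.sqrt(max(var, 0.0))), True


def td_auc(scores, times, events, grid_times) -> AUCCurve:
    """Cumulative/dynamic time-dependent AUC with IPCW weights.

    Cases at horizon t are subjects with an observed event by t, each
    weighted by 1/G(T-); controls are subjects still under observation
    past t, weighted by 1/G(t), where G is the Kaplan–Meier estimate of
    the censoring distribution.  Grid points with no cases or no
    controls are flagged undefined rather than raising.
    """
    times, events = _check_surv(times, events)
    scores = np.asarray(scores, dtype=float)
    grid = np.asarray(grid_times, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise DomainError("grid_times must be strictly increasing")
    cens_km = km_estimate(times, 1 - events)
    auc = np.empty(grid.size)
    se = np.empty(grid.size)
    defined = np.empty(grid.size, dtype=bool)
    for k, t in enumerate(grid):
        auc[k], se[k], defined[k] = _ipcw_auc_at(scores, times, events, cens_km, t)
    return AUCCurve(grid, auc, se, defined, "ipcw_cumulative_dynamic",
                    scores, times, events)


def compare_auc(curve_a: AUCCurve, curve_b: AUCCurve, t: float,
                n_boot: int = 1000, seed: int = 0) -> float:
    """Two-sided paired-bootstrap p-value for AUC_a(t) != AUC_b(t).

    Both curves must have been computed on the identical cohort; the
    bootstrap resamples subjects, recomputing the censoring KM and both
    AUCs on each resample.  Identical scores give a difference that is
    identically zero and hence p = 1.
    """
    if curve_a._times is None or curve_b._times is None:
        raise DomainError("curves lack the underlying data needed to compare")
    if (curve_a._times.shape != curve_b._times.shape
            or not np.array_equal(curve_a._times, curve_b._times)
            or not np.array_equal(curve_a._events, curve_b._events)):
        raise DomainError("curves were not computed on the same cohort")
    times, events = curve_a._times, curve_a._events
    sa, sb = curve_a._scores, curve_b._scores
    rng = np.random.default_rng(seed)
    n = times.size
    diffs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        tb, eb = times[idx], events[idx]
        if eb.sum() == 0:
            continue
        ckm = km_estimate(tb, 1 - eb)
        a, _, ok_a = _ipcw_auc_at(sa[idx], tb, eb, ckm, t)
        b, _, ok_b = _ipcw_auc_at(sb[idx], tb, eb, ckm, t)
        if ok_a and ok_b:
            diffs.append(a - b)
    diffs = np.asarray(diffs)
    if diffs.size == 0:
        raise UndefinedResultError("AUC undefined in every bootstrap resample")
    p = 2.0 * min((diffs <= 0).mean(), (diffs >= 0).mean())
    return float(min(p, 1.0))
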