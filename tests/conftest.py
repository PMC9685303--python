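"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately re-derive every statistic from
its definition with plain loops; they never call the package's own
vectorised implementations.
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


# ---------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------
def km_oracle(times, events):
    """Product-limit estimate via an explicit loop over distinct times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out_t, out_s = [], []
    s = 1.0
    for t in sorted(set(times[events == 1])):
        at_risk = int((times >= t).sum())
        deaths = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - deaths / at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def logrank_oracle(labels, times, events):
    """Two-group log-rank chi-square via per-event-time O-E/V sums."""
    labels = np.asarray(labels)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = sorted(set(labels.tolist()), key=str)
    assert len(groups) == 2
    g1 = labels == groups[1]
    O = E = V = 0.0
    for t in sorted(set(times[events == 1])):
        n = (times >= t).sum()
        n1 = (g1 & (times >= t)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = (g1 & (times == t) & (events == 1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def trend_logrank_oracle(labels, times, events, scores):
    """Linear-trend statistic from per-group O-E and the full covariance."""
    labels = np.asarray(labels)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = sorted(set(labels.tolist()), key=str)
    G = len(groups)
    scores = np.asarray(scores, float)
    OE = np.zeros(G)
    V = np.zeros((G, G))
    for t in sorted(set(times[events == 1])):
        n = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        for gi, g in enumerate(groups):
            ng = ((labels == g) & (times >= t)).sum()
            dg = ((labels == g) & (times == t) & (events == 1)).sum()
            OE[gi] += dg - d * ng / n
        if n > 1:
            for gi, g in enumerate(groups):
                ng = ((labels == g) & (times >= t)).sum()
                for hi, h in enumerate(groups):
                    nh = ((labels == h) & (times >= t)).sum()
                    delta = 1.0 if gi == hi else 0.0
                    V[gi, hi] += (d * (n - d) / (n - 1)
                                  * (delta * ng * n - ng * nh) / n**2)
    U = scores @ OE
    return U**2 / (scores @ V @ scores)


def cox_partial_loglik_oracle(beta, x, times, events):
    """Explicit Breslow-free partial log-likelihood (untied data only)."""
    times = np.asarray(times, float)
    assert len(set(times.tolist())) == times.size, "oracle assumes no ties"
    ll = 0.0
    for i in np.flatnonzero(np.asarray(events) == 1):
        risk = np.flatnonzero(times >= times[i])
        ll += beta * x[i] - np.log(np.exp(beta * np.asarray(x)[risk]).sum())
    return ll


def harrell_c_oracle(scores, times, events):
    """Exhaustive double-loop pair enumeration."""
    n = len(times)
    conc = tied = comp = 0.0
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                comp += 1
                if scores[i] > scores[j]:
                    conc += 1
                elif scores[i] == scores[j]:
                    tied += 1
    return (conc + 0.5 * tied) / comp


# ---------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------
@pytest.fixture(scope="session")
def small_survival():
    """Fixed 18-subject mixed censoring fixture (untied times)."""
    rng = np.random.default_rng(2024)
    n = 18
    x = rng.integers(0, 2, n).astype(float)
    times = np.round(rng.exponential(30 * np.exp(-0.8 * x)) + 0.5, 3)
    times = times + np.arange(n) * 1e-3  # break any residual ties
    events = (rng.uniform(size=n) < 0.75).astype(int)
    events[:2] = 1  # guarantee events
    return x, times, events


@pytest.fixture(scope="session")
def default_cohort_2000():
    """One calibrated synthetic cohort at n=2000 (shared, read-only)."""
    from ypstage import default_config, generate_cohort

    return generate_cohort(default_config(n=2000, seed=11))
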