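"""Statistical analyses of the behavioral experiments, from first principles.

Three analyses mirror the study design:

* a fixed-effects logistic regression of the binary female response on
  stimulus category (fitted by iteratively reweighted least squares), with
  Bonferroni-adjusted all-pairs Wald contrasts as the post hoc;
* a Cox proportional-hazards model of response latency with right-censoring
  at the observation horizon, Breslow handling of ties, fitted by Newton
  iterations on the partial likelihood, with the 45% duty-cycle category as
  the reference so exponentiated coefficients are "female response rate
  ratios";
* exact contingency-table tests for the mate-choice outcomes: Fisher's 2x2
  test and its 2x3 Freeman-Halton extension, both by complete enumeration of
  the tables sharing the observed margins, two-sided by the
  minimum-likelihood convention (summing tables whose probability does not
  exceed the observed table's).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import numpy as np

from .behavior_sim import ChoiceTrial, PlaybackTrial

__all__ = [
    "GlmFit",
    "CoxFit",
    "ExactTestResult",
    "PairwiseResult",
    "fit_response_glm",
    "pairwise_category_tests",
    "fit_cox",
    "fisher_exact_2x2",
    "freeman_halton_2x3",
    "acceptance_rates",
]

_Z975 = 1.959963984540054

#: Relative slack when comparing table probabilities in the exact tests,
#: guarding against float ties in the minimum-likelihood criterion.
_EXACT_SLACK = 1e-7
_SLACK_DEN = 10_000_000  # integer form: wk <= obs * (1 + 1/_SLACK_DEN)


def _leq_with_slack(wk: int, obs: int) -> bool:
    """wk <= obs * (1 + _EXACT_SLACK), evaluated in exact integer arithmetic."""
    return wk * _SLACK_DEN <= obs * (_SLACK_DEN + 1)


@dataclass
class GlmFit:
    """Logistic-regression fit of response on stimulus category."""

    reference: str
    categories: tuple[str, ...]  # reference first
    coefficients: dict  # name -> log-odds ("(Intercept)" + non-reference categories)
    standard_errors: dict
    cov: np.ndarray  # coefficient covariance, order: intercept then categories
    fitted_probabilities: dict  # category -> fitted response probability
    converged: bool
    n_iter: int
    separation: bool  # some category observed with a single outcome only
    n_obs: int


@dataclass
class CoxFit:
    """Cox proportional-hazards fit of latency on stimulus category."""

    reference: str
    categories: tuple[str, ...]  # reference first
    log_hazard_ratios: dict  # non-reference category -> coefficient
    standard_errors: dict
    rate_ratios: dict  # category -> exp(coef); reference maps to 1.0
    conf_int: dict  # category -> (low, high) on the rate-ratio scale
    n_events: int
    n_censored: int
    converged: bool
    n_iter: int
    monotone: bool  # monotone-likelihood flag (coefficient diverging)


@dataclass(frozen=True)
class ExactTestResult:
    """Two-sided exact contingency-table test result."""

    p: float
    tables_enumerated: int
    method: str
    degenerate: bool = False


@dataclass(frozen=True)
class PairwiseResult:
    """One all-pairs Wald contrast between stimulus categories."""

    pair: tuple[str, str]
    z: float
    p_raw: float
    p_adjusted: float


# ---------------------------------------------------------------------------
# Logistic regression by IRLS
# ---------------------------------------------------------------------------

def _design(trials: Sequence[PlaybackTrial], reference: str):
    categories = sorted({t.category for t in trials})
    if reference not in categories:
        raise ValueError(f"reference {reference!r} not among categories {categories}")
    others = [c for c in categories if c != reference]
    n = len(trials)
    X = np.zeros((n, 1 + len(others)))
    X[:, 0] = 1.0
    col = {c: j + 1 for j, c in enumerate(others)}
    y = np.zeros(n)
    for i, t in enumerate(trials):
        y[i] = t.responded
        if t.category != reference:
            X[i, col[t.category]] = 1.0
    return X, y, (reference, *others)


def fit_response_glm(
    trials: Sequence[PlaybackTrial],
    reference: str = "silence",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> GlmFit:
    """Fit a binomial GLM (logit link) of response on stimulus category.

    Iteratively reweighted least squares on category indicator variables with
    ``reference`` absorbed into the intercept. In this saturated categorical
    model the fitted probabilities equal the observed per-category response
    proportions. Categories observed with only one outcome cause complete
    separation: flagged, with the corresponding estimates not finite-sample
    reliable.
    """
    X, y, categories = _design(trials, reference)
    if len(categories) < 2:
        raise ValueError("need >= 2 categories")
    if y.min() == y.max():
        raise ValueError("both outcomes must be present overall")

    separation = False
    for c in categories:
        yc = [t.responded for t in trials if t.category == c]
        if len(set(yc)) == 1:
            separation = True

    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        # Newton step via the weighted normal equations.
        XtW = X.T * w
        H = XtW @ X
        g = X.T @ (y - mu)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    cov = np.linalg.inv((X.T * w) @ X)
    se = np.sqrt(np.diag(cov))

    names = ["(Intercept)"] + list(categories[1:])
    fitted = {}
    for c in categories:
        j = categories.index(c)
        lp = beta[0] + (beta[j] if j > 0 else 0.0)
        fitted[c] = 1.0 / (1.0 + math.exp(-lp))
    return GlmFit(
        reference=reference,
        categories=categories,
        coefficients=dict(zip(names, beta)),
        standard_errors=dict(zip(names, se)),
        cov=cov,
        fitted_probabilities=fitted,
        converged=converged,
        n_iter=it,
        separation=separation,
        n_obs=len(trials),
    )


def pairwise_category_tests(fit: GlmFit, adjustment: str = "bonferroni") -> list[PairwiseResult]:
    """All-pairs Wald z tests on category coefficient differences.

    P-values are Bonferroni-adjusted (number of pairs) and capped at 1.
    """
    from scipy.stats import norm

    if not fit.converged:
        raise ValueError("cannot run contrasts on a non-converged fit")
    if adjustment != "bonferroni":
        raise ValueError(f"unsupported adjustment {adjustment!r}")
    cats = fit.categories
    # Coefficient vector index per category: reference -> None (zero).
    idx = {c: (None if c == fit.reference else cats[1:].index(c) + 1) for c in cats}
    pairs = list(itertools.combinations(cats, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        ia, ib = idx[a], idx[b]
        beta_a = 0.0 if ia is None else fit.coefficients[a]
        beta_b = 0.0 if ib is None else fit.coefficients[b]
        var = 0.0
        if ia is not None:
            var += fit.cov[ia, ia]
        if ib is not None:
            var += fit.cov[ib, ib]
        if ia is not None and ib is not None:
            var -= 2.0 * fit.cov[ia, ib]
        diff = beta_a - beta_b
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = diff / math.sqrt(var)
            p = 2.0 * float(norm.sf(abs(z)))
        out.append(PairwiseResult((a, b), z, min(p, 1.0), min(p * m, 1.0)))
    return out


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties)
# ---------------------------------------------------------------------------

def fit_cox(
    trials: Sequence[PlaybackTrial],
    reference: str = "dc45",
    tol: float = 1e-10,
    max_iter: int = 50,
) -> CoxFit:
    """Fit a Cox model of response latency on stimulus category.

    Maximizes the Breslow partial likelihood by Newton iterations; censored
    presentations contribute to risk sets only. Rate ratios are exp(coef)
    with Wald 95% CIs exp(coef +/- 1.96 SE) against the ``reference``
    category (fixed at ratio 1).
    """
    events = sum(t.responded for t in trials)
    if events == 0:
        raise ValueError("no events: every presentation is censored")
    cats_with_events = {t.category for t in trials if t.responded}
    if len({t.category for t in trials}) < 2 or len(cats_with_events) < 1:
        raise ValueError("need >= 2 categories with >= 1 event")

    X, d, categories = _design_cox(trials, reference)
    times = np.array([t.latency for t in trials])
    order = np.argsort(times, kind="stable")
    X, d, times = X[order], d[order], times[order]
    n, p = X.shape

    beta = np.zeros(p)
    converged = False
    monotone = False
    it = 0
    for it in range(1, max_iter + 1):
        g, H = _cox_score_hessian(beta, X, d, times)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            monotone = True
            break
        beta = beta + step
        if np.max(np.abs(beta)) > 15:
            monotone = True  # likelihood monotone in some coefficient
            break
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    _, H = _cox_score_hessian(beta, X, d, times)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, math.nan)

    others = list(categories[1:])
    log_hr = dict(zip(others, beta))
    ses = dict(zip(others, se))
    ratios = {reference: 1.0}
    cis = {reference: (1.0, 1.0)}
    for c in others:
        ratios[c] = math.exp(log_hr[c])
        lo = math.exp(log_hr[c] - _Z975 * ses[c])
        hi = math.exp(log_hr[c] + _Z975 * ses[c])
        cis[c] = (lo, hi)
    return CoxFit(
        reference=reference,
        categories=categories,
        log_hazard_ratios=log_hr,
        standard_errors=ses,
        rate_ratios=ratios,
        conf_int=cis,
        n_events=int(events),
        n_censored=int(len(trials) - events),
        converged=converged,
        n_iter=it,
        monotone=monotone,
    )


def _design_cox(trials: Sequence[PlaybackTrial], reference: str):
    categories = sorted({t.category for t in trials})
    if reference not in categories:
        raise ValueError(f"reference {reference!r} not among categories {categories}")
    others = [c for c in categories if c != reference]
    X = np.zeros((len(trials), len(others)))
    col = {c: j for j, c in enumerate(others)}
    d = np.zeros(len(trials))
    for i, t in enumerate(trials):
        d[i] = t.responded
        if t.category != reference:
            X[i, col[t.category]] = 1.0
    return X, d, (reference, *others)


def _cox_score_hessian(beta, X, d, times):
    """Breslow partial-likelihood score and negative Hessian.

    Rows must be sorted by time ascending. Risk-set sums are accumulated from
    the largest time downward; tied event times share one risk set.
    """
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    g = np.zeros(p)
    H = np.zeros((p, p))
    # Cumulative risk-set aggregates, built from the end (largest times).
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = n - 1
    while i >= 0:
        j = i
        while j >= 0 and times[j] == times[i]:
            s0 += w[j]
            s1 += w[j] * X[j]
            s2 += w[j] * np.outer(X[j], X[j])
            j -= 1
        for k in range(j + 1, i + 1):
            if d[k]:
                xbar = s1 / s0
                g += X[k] - xbar
                H += s2 / s0 - np.outer(xbar, xbar)
        i = j
    return g, H


# ---------------------------------------------------------------------------
# Exact contingency tests
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> ExactTestResult:
    """Two-sided Fisher exact test of a 2x2 count table.

    Enumerates every table with the observed margins; the p-value is the sum
    of hypergeometric probabilities of tables no more probable than the
    observed one (minimum-likelihood convention, with a small relative slack
    against float ties). Computed in exact integer arithmetic. An all-zero
    margin is degenerate with p = 1.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0 or any(x != int(x) for x in (a, b, c, d)):
        raise ValueError("table entries must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return ExactTestResult(1.0, 1, "fisher_2x2", degenerate=True)

    denom = math.comb(n, c1)
    # Integer weight of the table with top-left cell k.
    def weight(k: int) -> int:
        return math.comb(r1, k) * math.comb(r2, c1 - k)

    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    obs = weight(a)
    total = 0
    count = 0
    for k in range(k_min, k_max + 1):
        count += 1
        wk = weight(k)
        if _leq_with_slack(wk, obs):
            total += wk
    return ExactTestResult(float(Fraction(total, denom)), count, "fisher_2x2")


def freeman_halton_2x3(table: Sequence[Sequence[int]], budget: int = 10_000_000) -> ExactTestResult:
    """Two-sided Freeman-Halton exact test of a 2x3 count table.

    Enumerates every 2x3 table with the observed margins; the p-value sums
    the multivariate hypergeometric probabilities of tables no more probable
    than the observed one. Exact integer arithmetic; margins requiring more
    than ``budget`` tables are rejected.
    """
    row = [list(map(int, r)) for r in table]
    if len(row) != 2 or any(len(r) != 3 for r in row):
        raise ValueError("expected a 2x3 table")
    if min(min(r) for r in row) < 0:
        raise ValueError("table entries must be nonnegative integers")
    r1 = sum(row[0])
    r2 = sum(row[1])
    cols = [row[0][j] + row[1][j] for j in range(3)]
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or sum(c > 0 for c in cols) <= 1:
        return ExactTestResult(1.0, 1, "freeman_halton_2x3", degenerate=True)

    max_tables = (min(r1, cols[0]) + 1) * (min(r1, cols[1]) + 1)
    if max_tables > budget:
        raise ValueError(
            f"margins would enumerate up to {max_tables} tables, over the {budget} budget"
        )

    # Weight of a table is prod_j C(col_j, a_j); P = weight / C(n, r1).
    denom = math.comb(n, r1)

    def weight(a0: int, a1: int, a2: int) -> int:
        return math.comb(cols[0], a0) * math.comb(cols[1], a1) * math.comb(cols[2], a2)

    obs = weight(row[0][0], row[0][1], row[0][2])
    total = 0
    count = 0
    for a0 in range(max(0, r1 - cols[1] - cols[2]), min(r1, cols[0]) + 1):
        rem = r1 - a0
        for a1 in range(max(0, rem - cols[2]), min(rem, cols[1]) + 1):
            a2 = rem - a1
            count += 1
            wk = weight(a0, a1, a2)
            if _leq_with_slack(wk, obs):
                total += wk
    return ExactTestResult(float(Fraction(total, denom)), count, "freeman_halton_2x3")


# ---------------------------------------------------------------------------
# Mate-choice tabulation
# ---------------------------------------------------------------------------

def acceptance_rates(
    trials: Iterable[ChoiceTrial],
    conditions: Optional[Sequence[str]] = None,
) -> Optional[dict]:
    """Per-condition acceptance percentage among successful matings.

    For each condition, 100 x (matings choosing it) / (successful matings).
    Conditions never chosen report 0. Returns None (undefined) when no trial
    ended in a mating.
    """
    trials = list(trials)
    if conditions is None:
        seen: list[str] = []
        for t in trials:
            for c in t.conditions_offered:
                if c not in seen:
                    seen.append(c)
        conditions = seen
    successes = [t for t in trials if t.chosen is not None]
    if not successes:
        return None
    total = len(successes)
    return {
        c: 100.0 * sum(t.chosen == c for t in successes) / total for c in conditions
    }
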