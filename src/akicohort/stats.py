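"""Exact and classical inference for phase comparisons.

2x2 tables are compared with the two-sided Fisher exact test under the
minimum-likelihood ("minlike") ordering — the sum of hypergeometric outcome
probabilities no larger than the observed one — and the accompanying 95%
confidence interval for the odds ratio is the Fay *matched* interval: the
interval of odds-ratio values not rejected by that same two-sided exact
test, so that test and interval can never contradict each other.  The point
estimate is the conditional maximum-likelihood odds ratio (the root of the
noncentral-hypergeometric mean equation).  Families of pairwise comparisons
are adjusted by the Holm step-down procedure.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .config import FisherConvention

#: Relative slack when comparing outcome probabilities (floating-point ties).
TIE_SLACK = 1e-7
#: Root-finding tolerance on the log-odds-ratio scale for CI endpoints.
LOG_OR_TOL = 1e-8


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: row 1 = group 1 event/non-event, row 2 = group 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("cell counts must be non-negative integers")

    @classmethod
    def from_events(cls, k1: int, n1: int, k2: int, n2: int) -> "ContingencyTable2x2":
        """Build from events/totals per group (k events out of n)."""
        return cls(k1, n1 - k1, k2, n2 - k2)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def transpose(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.a, self.c, self.b, self.d)

    def swap_groups(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)

    @property
    def degenerate(self) -> bool:
        m1, m2, c1, c2 = self.margins
        return min(m1, m2) == 0 or min(c1, c2) == 0


@dataclass(frozen=True)
class ExactTestResult:
    p_two_sided: float
    or_cond_mle: float
    ci_low: float
    ci_high: float
    level: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_sided <= 1.0):
            raise ValueError("p-value out of [0, 1]")
        if math.isfinite(self.or_cond_mle):
            if not (self.ci_low <= self.or_cond_mle * (1 + 1e-9) and
                    self.or_cond_mle <= self.ci_high * (1 + 1e-9)):
                raise ValueError("estimate outside its confidence interval")


# ---------------------------------------------------------------------------
# noncentral hypergeometric machinery (conditional on both margins)

def _support(table: ContingencyTable2x2) -> np.ndarray:
    m1, _, c1, _ = table.margins
    lo = max(0, c1 - (table.n - m1))
    hi = min(m1, c1)
    return np.arange(lo, hi + 1)


def _log_weights(table: ContingencyTable2x2, xs: np.ndarray) -> np.ndarray:
    """log C(m1, x) + log C(m2, c1 - x) over the support."""
    m1, m2, c1, _ = table.margins
    return (
        gammaln(m1 + 1) - gammaln(xs + 1) - gammaln(m1 - xs + 1)
        + gammaln(m2 + 1) - gammaln(c1 - xs + 1) - gammaln(m2 - (c1 - xs) + 1)
    )


def _log_pmf(logw: np.ndarray, xs: np.ndarray, log_theta: float) -> np.ndarray:
    lp = logw + xs * log_theta
    return lp - logsumexp(lp)


def _minlike_p_at(table: ContingencyTable2x2, log_theta: float) -> float:
    xs = _support(table)
    lp = _log_pmf(_log_weights(table, xs), xs, log_theta)
    p_obs = lp[int(table.a - xs[0])]
    mask = lp <= p_obs + math.log1p(TIE_SLACK)
    return float(min(1.0, np.exp(logsumexp(lp[mask]))))


def fisher_exact_2x2(
    table: ContingencyTable2x2,
    convention: FisherConvention = FisherConvention.minlike,
) -> float:
    """Two-sided Fisher exact p-value.

    Degenerate margins (an empty row or column) carry no information about
    association; p = 1 is returned with a warning.
    """
    if table.degenerate:
        warnings.warn("degenerate 2x2 margins; returning p = 1", stacklevel=2)
        return 1.0
    if convention is FisherConvention.minlike:
        return _minlike_p_at(table, 0.0)
    xs = _support(table)
    pmf = np.exp(_log_pmf(_log_weights(table, xs), xs, 0.0))
    i = int(table.a - xs[0])
    lower = float(pmf[: i + 1].sum())
    upper = float(pmf[i:].sum())
    return min(1.0, 2.0 * min(lower, upper))


def or_conditional_mle(table: ContingencyTable2x2) -> float:
    """Conditional MLE of the odds ratio: the root of E_theta[X] = a.

    Returns 0.0 when the observed count sits at the lower support bound and
    +inf at the upper bound (zero-cell tables).
    """
    xs = _support(table)
    if len(xs) == 1:
        return 1.0 if table.degenerate else float("nan")
    if table.a == xs[0]:
        return 0.0
    if table.a == xs[-1]:
        return math.inf
    logw = _log_weights(table, xs)

    def mean_minus_a(log_theta: float) -> float:
        p = np.exp(_log_pmf(logw, xs, log_theta))
        return float((p * xs).sum() - table.a)

    lo, hi = -1.0, 1.0
    while mean_minus_a(lo) > 0:
        lo *= 2
    while mean_minus_a(hi) < 0:
        hi *= 2
    from scipy.optimize import brentq

    return float(math.exp(brentq(mean_minus_a, lo, hi, xtol=LOG_OR_TOL)))


def _acceptance_region_bounds(
    table: ContingencyTable2x2, alpha: float
) -> tuple[float, float]:
    """[inf, sup] of {log theta : minlike p(theta) > alpha} via grid + bisection."""
    xs = _support(table)
    logw = _log_weights(table, xs)
    grid = np.linspace(math.log(1e-10), math.log(1e10), 4001)
    # vectorized p(theta) over the grid
    lp = logw[:, None] + np.outer(xs, grid)
    lp -= logsumexp(lp, axis=0, keepdims=True)
    p_obs = lp[int(table.a - xs[0]), :]
    mask = lp <= p_obs[None, :] + math.log1p(TIE_SLACK)
    with np.errstate(divide="ignore"):
        ps = np.exp(
            logsumexp(np.where(mask, lp, -np.inf), axis=0)
        )
    inside = ps > alpha
    if not inside.any():  # cannot happen for proper tables: theta-hat is inside
        raise RuntimeError("empty acceptance region")
    i0 = int(np.argmax(inside))
    i1 = int(len(inside) - 1 - np.argmax(inside[::-1]))

    def p_at(lt: float) -> float:
        return _minlike_p_at(table, lt)

    def refine(lo: float, hi: float) -> float:
        # p(lo) and p(hi) straddle alpha; bisect to LOG_OR_TOL
        while hi - lo > LOG_OR_TOL:
            mid = 0.5 * (lo + hi)
            if (p_at(mid) > alpha) == (p_at(hi) > alpha):
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    lo_bound = -math.inf if i0 == 0 else refine(grid[i0 - 1], grid[i0])
    hi_bound = math.inf if i1 == len(grid) - 1 else refine(grid[i1], grid[i1 + 1])
    return lo_bound, hi_bound


def fay_or_ci(
    table: ContingencyTable2x2, level: float = 0.95
) -> tuple[float, float]:
    """Matched exact CI for the odds ratio (inversion of the minlike test).

    Endpoints are the infimum and supremum of odds-ratio values not rejected
    at ``1 - level``; zero cells yield 0 or +inf endpoints.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if table.degenerate:
        return (0.0, math.inf)
    alpha = 1.0 - level
    xs = _support(table)
    lo_edge = table.a == xs[0]
    hi_edge = table.a == xs[-1]
    if lo_edge and hi_edge:  # single-point support
        return (0.0, math.inf)
    lo, hi = _acceptance_region_bounds(table, alpha)
    ci_low = 0.0 if (lo_edge or lo == -math.inf) else math.exp(lo)
    ci_high = math.inf if (hi_edge or hi == math.inf) else math.exp(hi)
    return (ci_low, ci_high)


def exact_or_test(
    table: ContingencyTable2x2,
    level: float = 0.95,
    convention: FisherConvention = FisherConvention.minlike,
) -> ExactTestResult:
    """Bundle the two-sided p, conditional-MLE odds ratio and matched CI."""
    p = fisher_exact_2x2(table, convention)
    if table.degenerate:
        return ExactTestResult(p, 1.0, 0.0, math.inf, level, "degenerate")
    est = or_conditional_mle(table)
    lo, hi = fay_or_ci(table, level)
    return ExactTestResult(p, est, lo, hi, level, f"fisher-{convention.value}/fay")


def holm_adjust(p: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values, in the input order."""
    p = list(p)
    if any(not (0.0 <= x <= 1.0) for x in p):
        raise ValueError("p-values must lie in [0, 1]")
    if not p:
        return []
    return list(multipletests(p, method="holm")[1])


def continuous_tests(x: Sequence[float], y: Sequence[float]) -> dict[str, float]:
    """Two-sample location tests plus per-sample normality checks.

    Returns two-sided p-values: Welch-free pooled t test (``t_p``),
    Mann–Whitney U (``mwu_p``; exact for small untied samples, normal
    approximation with tie correction otherwise), and Kolmogorov–Smirnov
    statistics of each sample against a normal with its own mean/SD
    (``ks_p_x``, ``ks_p_y``).  With zero pooled variance the t test is
    undefined and ``t_p`` is NaN (with a warning); the rank test remains valid.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        warnings.warn("zero variance in both samples; t test undefined", stacklevel=2)
        t_p = math.nan
    else:
        t_p = float(sps.ttest_ind(x, y).pvalue)
    exact_ok = (
        max(len(x), len(y)) <= 20
        and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    )
    mwu = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact_ok else "asymptotic"
    )
    out = {"t_p": t_p, "mwu_p": float(mwu.pvalue)}
    for name, s in (("ks_p_x", x), ("ks_p_y", y)):
        sd = float(np.std(s, ddof=1))
        if sd == 0.0:
            out[name] = 0.0
        else:
            out[name] = float(sps.kstest(s, "norm", args=(float(np.mean(s)), sd)).pvalue)
    return out


def pairwise_exact(
    group_counts: Mapping[str, tuple[int, int]],
    level: float = 0.95,
    convention: FisherConvention = FisherConvention.minlike,
) -> pd.DataFrame:
    """All pairwise 2x2 exact tests over ``{group: (events, total)}``, with
    Holm adjustment across the pair family and deterministic pair order.

    Empty strata (total 0) are excluded with a warning; with exactly two
    groups the adjustment is the identity.
    """
    counts = {g: kn for g, kn in group_counts.items() if kn[1] > 0}
    dropped = set(group_counts) - set(counts)
    if dropped:
        warnings.warn(f"empty strata excluded: {sorted(dropped)}", stacklevel=2)
    groups = sorted(counts)
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    rows = []
    for g1, g2 in itertools.combinations(groups, 2):
        k1, n1 = counts[g1]
        k2, n2 = counts[g2]
        table = ContingencyTable2x2.from_events(k1, n1, k2, n2)
        res = exact_or_test(table, level, convention)
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "events1": k1,
                "total1": n1,
                "events2": k2,
                "total2": n2,
                "or_cond_mle": res.or_cond_mle,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_raw": res.p_two_sided,
            }
        )
    frame = pd.DataFrame(rows)
    frame["p_holm"] = holm_adjust(frame["p_raw"].tolist())
    return frame
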