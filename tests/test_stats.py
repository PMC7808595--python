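"""Exact 2x2 inference: Fisher minlike p, conditional-MLE OR, Fay matched CI,
Holm adjustment, continuous tests — each checked against an independent route."""
import itertools
import math
import warnings

import numpy as np
import pytest
from scipy import stats as sps

from akicohort.config import FisherConvention
from akicohort.stats import (
    ContingencyTable2x2,
    continuous_tests,
    exact_or_test,
    fay_or_ci,
    fisher_exact_2x2,
    holm_adjust,
    or_conditional_mle,
    pairwise_exact,
)


def _random_tables(rng, n, hi=40):
    out = []
    while len(out) < n:
        a, b, c, d = (int(x) for x in rng.integers(0, hi, 4))
        t = ContingencyTable2x2(a, b, c, d)
        if not t.degenerate:
            out.append(t)
    return out


# --- Fisher p ----------------------------------------------------------------

def test_fisher_examples():
    # enumeration over the 2-table support
    assert fisher_exact_2x2(ContingencyTable2x2(1, 0, 0, 1)) == pytest.approx(1.0)
    # extreme diagonal table: 2 / C(20, 10)
    p = fisher_exact_2x2(ContingencyTable2x2(10, 0, 0, 10))
    assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
    # published severe-AKI mortality table
    p = fisher_exact_2x2(ContingencyTable2x2(27, 108, 21, 157))
    assert round(p, 3) == 0.057


def test_fisher_agrees_with_scipy_on_random_tables():
    rng = np.random.default_rng(7)
    for t in _random_tables(rng, 300):
        ref = sps.fisher_exact([[t.a, t.b], [t.c, t.d]]).pvalue
        assert fisher_exact_2x2(t) == pytest.approx(ref, abs=1e-10)


def test_fisher_transposition_invariance():
    rng = np.random.default_rng(8)
    for t in _random_tables(rng, 100):
        assert fisher_exact_2x2(t) == pytest.approx(
            fisher_exact_2x2(t.transpose()), rel=1e-9
        )
        assert fisher_exact_2x2(t) == pytest.approx(
            fisher_exact_2x2(t.swap_groups()), rel=1e-9
        )


def test_degenerate_margins_give_p1_with_warning():
    with pytest.warns(UserWarning):
        assert fisher_exact_2x2(ContingencyTable2x2(0, 0, 3, 4)) == 1.0


def test_doubled_convention_is_larger_or_equal_for_these_tables():
    t = ContingencyTable2x2(714, 264, 874, 249)
    p_min = fisher_exact_2x2(t, FisherConvention.minlike)
    p_dbl = fisher_exact_2x2(t, FisherConvention.doubled)
    assert round(p_min, 3) == 0.011 and round(p_dbl, 3) == 0.012


# --- conditional MLE ---------------------------------------------------------

def test_cmle_examples():
    assert or_conditional_mle(ContingencyTable2x2(1, 1, 1, 1)) == pytest.approx(1.0)
    est = or_conditional_mle(ContingencyTable2x2(27, 108, 21, 157))
    assert 1.85 <= est <= 1.87
    assert or_conditional_mle(ContingencyTable2x2(0, 5, 3, 7)) == 0.0
    assert or_conditional_mle(ContingencyTable2x2(5, 0, 3, 7)) == math.inf


def test_cmle_solves_noncentral_hypergeometric_mean_equation():
    rng = np.random.default_rng(9)
    for t in _random_tables(rng, 50, hi=25):
        est = or_conditional_mle(t)
        if est in (0.0, math.inf):
            continue
        m1, m2, c1, _ = t.margins
        mean = sps.nchypergeom_fisher.mean(t.n, m1, c1, est)
        assert mean == pytest.approx(t.a, abs=1e-5)


# --- Fay matched CI ----------------------------------------------------------

def test_fay_ci_reproduces_published_intervals():
    lo, hi = fay_or_ci(ContingencyTable2x2(27, 108, 21, 157))
    assert (round(lo, 2), round(hi, 2)) == (0.98, 3.52)
    lo, hi = fay_or_ci(ContingencyTable2x2(714, 264, 874, 249))
    assert (round(lo, 2), round(hi, 2)) == (0.63, 0.94)


def test_fay_ci_zero_cell_boundaries():
    lo, hi = fay_or_ci(ContingencyTable2x2(1, 0, 0, 1))
    assert lo > 0 or lo == 0.0
    assert hi == math.inf
    lo, hi = fay_or_ci(ContingencyTable2x2(0, 5, 3, 7))
    assert lo == 0.0 and math.isfinite(hi)


def test_matching_property_on_random_tables():
    """1 inside the 95% CI exactly when the two-sided p exceeds 0.05."""
    rng = np.random.default_rng(10)
    for t in _random_tables(rng, 150):
        p = fisher_exact_2x2(t)
        lo, hi = fay_or_ci(t, 0.95)
        assert (lo <= 1.0 <= hi) == (p > 0.05), (t, p, lo, hi)


def test_ci_reciprocal_under_group_swap():
    rng = np.random.default_rng(11)
    for t in _random_tables(rng, 30, hi=25):
        lo, hi = fay_or_ci(t)
        lo2, hi2 = fay_or_ci(t.swap_groups())
        if lo > 0 and math.isfinite(hi):
            assert lo2 == pytest.approx(1 / hi, rel=1e-5)
            assert hi2 == pytest.approx(1 / lo, rel=1e-5)


def test_estimate_lies_inside_its_interval():
    rng = np.random.default_rng(12)
    for t in _random_tables(rng, 50):
        res = exact_or_test(t)
        if math.isfinite(res.or_cond_mle) and res.or_cond_mle > 0:
            assert res.ci_low <= res.or_cond_mle <= res.ci_high


# --- Holm --------------------------------------------------------------------

def test_holm_examples_and_properties():
    assert holm_adjust([0.02]) == [0.02]
    assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])
    assert holm_adjust([1.0, 1.0]) == [1.0, 1.0]
    rng = np.random.default_rng(13)
    p = rng.uniform(size=8).tolist()
    adj = holm_adjust(p)
    assert all(a >= r for a, r in zip(adj, p))
    # equal raw p-values reduce Holm to Bonferroni
    assert holm_adjust([0.01] * 5) == pytest.approx([0.05] * 5)


# --- continuous tests --------------------------------------------------------

def test_identical_samples_mwu_p_is_one():
    x = [1.0, 2.0, 3.0, 4.0]
    res = continuous_tests(x, x)
    assert res["mwu_p"] == pytest.approx(1.0)


def test_separated_samples_reject():
    rng = np.random.default_rng(14)
    x = rng.normal(0, 1, 50)
    y = rng.normal(10, 1, 50)
    res = continuous_tests(x, y)
    assert res["t_p"] < 1e-6 and res["mwu_p"] < 1e-6


def test_small_sample_mwu_matches_exhaustive_permutation():
    """For tiny untied samples the exact MWU p equals full enumeration."""
    x = [1.3, 2.9, 4.1]
    y = [2.0, 3.5, 5.7, 6.2]
    res = continuous_tests(x, y)
    pooled = x + y
    n = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    obs = u_stat(x, y)
    total = 0
    extreme = 0
    mu = len(x) * len(y) / 2
    for idx in itertools.combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - mu) >= abs(obs - mu) - 1e-12:
            extreme += 1
    assert res["mwu_p"] == pytest.approx(extreme / total, rel=1e-9)


def test_zero_variance_t_is_nan_with_warning():
    with pytest.warns(UserWarning):
        res = continuous_tests([2.0, 2.0, 2.0], [2.0, 2.0])
    assert math.isnan(res["t_p"]) and not math.isnan(res["mwu_p"])


def test_ks_normality_flags_heavy_tails():
    rng = np.random.default_rng(15)
    normal = rng.normal(size=300)
    skewed = rng.lognormal(size=300)
    res = continuous_tests(normal, skewed)
    assert res["ks_p_x"] > 0.01 and res["ks_p_y"] < 1e-4


# --- pairwise families -------------------------------------------------------

def test_two_groups_reduce_to_unadjusted_test():
    frame = pairwise_exact({"g1": (5, 20), "g2": (12, 20)})
    assert len(frame) == 1
    assert frame.loc[0, "p_holm"] == pytest.approx(frame.loc[0, "p_raw"])


def test_four_groups_make_six_adjusted_pairs():
    counts = {f"g{i}": (5 + i, 30) for i in range(4)}
    frame = pairwise_exact(counts)
    assert len(frame) == 6
    assert (frame["p_holm"] >= frame["p_raw"] - 1e-12).all()
    # deterministic ordering
    again = pairwise_exact(counts)
    assert frame.equals(again)


def test_empty_stratum_excluded_with_warning():
    with pytest.warns(UserWarning, match="empty strata"):
        frame = pairwise_exact({"a": (3, 10), "b": (4, 10), "c": (0, 0)})
    assert len(frame) == 1


def test_null_calibration_of_fisher_test():
    """Under a true null the exact test is valid (size <= nominal 5%)."""
    rng = np.random.default_rng(16)
    rejections = 0
    reps = 600
    for _ in range(reps):
        k1 = rng.binomial(40, 0.3)
        k2 = rng.binomial(40, 0.3)
        t = ContingencyTable2x2.from_events(int(k1), 40, int(k2), 40)
        if t.degenerate:
            continue
        if fisher_exact_2x2(t) < 0.05:
            rejections += 1
    assert rejections / reps <= 0.055
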