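"""Isoform totals, paired tests, solubility ratio and correlations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss

from digepipe.normalize import ExpressionMatrix
from digepipe.rollup import (
    aggregate_isoforms,
    classify_gliosis,
    correlate_fc_with_spike,
    fraction_ratio,
    kendall_exact,
    paired_total_test,
    pearson_p_from_r,
)
from digepipe.simulate import default_cohort


def tv_matrix(values, patients=("p1", "p2", "p3"), fraction="P1_nuclear"):
    cols = pd.MultiIndex.from_product([patients, ["high", "low"]],
                                      names=["patient", "condition"])
    data = pd.DataFrame(values, columns=cols,
                        index=[f"s{i}" for i in range(len(values))])
    return ExpressionMatrix(data=data, mode="total_volume", fraction=fraction)


def test_aggregate_sums_and_additivity():
    expr = tv_matrix([[1.0] * 6, [2.0] * 6, [3.0] * 6])
    total = aggregate_isoforms(expr, ["s0", "s1", "s2"], "GFAP")
    assert (total.totals == 6.0).all()
    part_a = aggregate_isoforms(expr, ["s0"], "GFAP")
    part_b = aggregate_isoforms(expr, ["s1", "s2"], "GFAP")
    pd.testing.assert_series_equal(total.totals, part_a.totals + part_b.totals)


def test_aggregate_requires_total_volume_mode():
    expr = tv_matrix([[1.0] * 6])
    expr.mode = "ratiometric"
    with pytest.raises(Exception, match="total-volume"):
        aggregate_isoforms(expr, ["s0"], "GFAP")
    with pytest.raises(Exception, match="empty"):
        aggregate_isoforms(tv_matrix([[1.0] * 6]), [], "GFAP")


def test_paired_total_test_against_scipy():
    rng = np.random.default_rng(0)
    low = rng.uniform(50, 150, 6)
    high = 2.0 * low * np.exp(rng.normal(0, 0.05, 6))
    values = np.column_stack(
        [v for pair in zip(high, low) for v in (pair[0], pair[1])]
    )
    expr = tv_matrix([values[0]], patients=[f"p{i}" for i in range(6)])
    total = aggregate_isoforms(expr, ["s0"], "X")
    res = paired_total_test(total)
    ref = ss.ttest_rel(np.log(high), np.log(low))
    assert res.p == pytest.approx(ref.pvalue)
    assert res.fc_hl == pytest.approx(
        float(np.exp(np.mean(np.log(high / low)))))
    assert 1.8 < res.fc_hl < 2.2 and res.p < 0.01


def test_paired_total_test_null_and_symmetry():
    expr = tv_matrix([[5.0] * 6])
    res = paired_total_test(aggregate_isoforms(expr, ["s0"], "X"))
    assert res.degenerate
    # sign flip: swapping high and low negates ln FC, p unchanged
    rng = np.random.default_rng(1)
    h = rng.uniform(1, 2, 3)
    l = rng.uniform(1, 2, 3)
    a = tv_matrix([np.column_stack([h, l]).ravel()])
    b = tv_matrix([np.column_stack([l, h]).ravel()])
    ra = paired_total_test(aggregate_isoforms(a, ["s0"], "X"))
    rb = paired_total_test(aggregate_isoforms(b, ["s0"], "X"))
    assert ra.p == pytest.approx(rb.p)
    assert ra.fc_hl == pytest.approx(rb.fc_lh)


def test_fraction_ratio_bands():
    cyt = aggregate_isoforms(tv_matrix([[25.0, 25.0, 100.0, 100.0, 50.0, 50.0]]),
                             ["s0"], "GFAP")
    nuc = aggregate_isoforms(
        tv_matrix([[100.0, 100.0, 100.0, 100.0, 100.0, 100.0]]), ["s0"], "GFAP")
    ratio = fraction_ratio(cyt, nuc)
    assert ratio.loc["p1", "high"] == pytest.approx(0.25)
    assert ratio.loc["p2", "high"] == pytest.approx(1.0)
    assert classify_gliosis(0.22) == "normal"
    assert classify_gliosis(1.0) == "pronounced"


def test_fraction_ratio_zero_nuclear_errors():
    cyt = aggregate_isoforms(tv_matrix([[1.0] * 6]), ["s0"], "GFAP")
    nuc_expr = tv_matrix([[1.0] * 6])
    nuc = aggregate_isoforms(nuc_expr, ["s0"], "GFAP")
    nuc.totals.iloc[0] = 0.0
    with pytest.raises(Exception, match="zero nuclear"):
        fraction_ratio(cyt, nuc)


def test_pearson_p_printed_values():
    """r = 0.96 at n = 6 gives the printed two-sided p of 0.002."""
    assert round(pearson_p_from_r(0.96, 6), 3) == 0.002
    assert pearson_p_from_r(0.0, 10) == pytest.approx(1.0)


def test_pearson_p_matches_quadrature():
    from scipy.integrate import quad

    r, n = 0.5, 100
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
    tail, _ = quad(lambda u: ss.t.pdf(u, n - 2), t, np.inf)
    assert pearson_p_from_r(r, n) == pytest.approx(2 * tail, rel=1e-8)


def test_pearson_p_monotone_in_r_and_n():
    ps = [pearson_p_from_r(r, 6) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
    assert all(a > b for a, b in zip(ps, ps[1:]))
    pn = [pearson_p_from_r(0.5, n) for n in (5, 10, 20, 50)]
    assert all(a > b for a, b in zip(pn, pn[1:]))


def test_pearson_p_limit_flagged():
    with pytest.warns(UserWarning, match="limit"):
        assert pearson_p_from_r(1.0, 6) == 0.0


def test_kendall_perfect_concordance_n6_is_printed_0_003():
    tau, p = kendall_exact([1, 2, 3, 4, 5, 6], [2, 4, 9, 16, 25, 36])
    assert tau == pytest.approx(1.0)
    assert p == pytest.approx(2 / 720)
    assert round(p, 3) == 0.003
    tau_d, p_d = kendall_exact([1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1])
    assert tau_d == pytest.approx(-1.0)
    assert p_d == pytest.approx(p)


def test_kendall_exact_matches_enumeration_and_scipy():
    rng = np.random.default_rng(4)
    for n in (3, 4, 5, 6):
        for _ in range(4):
            x = np.arange(n, dtype=float)
            y = rng.permutation(n).astype(float)
            tau, p = kendall_exact(x, y)
            ref = ss.kendalltau(x, y, method="exact")
            assert tau == pytest.approx(float(ref.statistic))
            assert p == pytest.approx(float(ref.pvalue))
            m = n * (n - 1) // 2

            def stat(perm):
                return sum(
                    np.sign(perm[b] - perm[a])
                    for a in range(n) for b in range(a + 1, n)
                ) / m

            obs = abs(stat(y))
            count = sum(
                abs(stat(np.array(perm))) >= obs - 1e-12
                for perm in itertools.permutations(range(n))
            )
            assert p == pytest.approx(count / math.factorial(n))


def test_kendall_ties_rejected_in_exact_mode():
    with pytest.raises(Exception, match="ties"):
        kendall_exact([1, 1, 2, 3], [1, 2, 3, 4])
    tau, p = kendall_exact([1, 1, 2, 3], [1, 2, 3, 4], exact=False)
    assert 0 < p <= 1


def test_kendall_large_n_falls_back():
    x = np.arange(12.0)
    with pytest.warns(UserWarning, match="normal approximation"):
        tau, p = kendall_exact(x, x + 1)
    assert tau == pytest.approx(1.0)


def test_correlate_fc_with_spike_identity_regression():
    """FC set equal to delta-spike: r = 1 limit, slope 1, intercept 0."""
    cohort = default_cohort()
    fc = cohort.delta_spike.astype(float)
    res = correlate_fc_with_spike(fc, cohort)
    assert res.r == pytest.approx(1.0)
    assert res.slope == pytest.approx(1.0)
    assert res.intercept == pytest.approx(0.0, abs=1e-9)
    assert res.tau == pytest.approx(1.0)
    reversed_res = correlate_fc_with_spike(-fc, cohort)
    assert reversed_res.tau == pytest.approx(-1.0)


def test_correlate_fc_with_spike_planted_relation(sim_default):
    res = correlate_fc_with_spike(sim_default.truth.gfap_fc_lh,
                                  sim_default.metadata)
    assert res.tau == pytest.approx(1.0)
    assert res.tau_p == pytest.approx(2 / 720)
    assert res.slope == pytest.approx(200.0)
    assert res.intercept == pytest.approx(-251.0)
    assert res.r == pytest.approx(1.0)
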