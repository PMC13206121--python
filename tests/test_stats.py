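"""Exact signed-rank test, Holm step-down, effect sizes, Friedman omnibus."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from slidemil.stats import (
    build_stat_report,
    cohens_d_paired,
    friedman_test,
    holm_adjust,
    wilcoxon_exact,
)


def _enumeration_oracle(d, alternative="greater"):
    """Independent brute force: all 2^m sign assignments of the ranks."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    m = len(d)
    ws = np.array([
        sum(ranks[i] for i in subset)
        for r in range(m + 1)
        for subset in itertools.combinations(range(m), r)
    ])
    pg = (ws >= w_obs - 1e-12).mean()
    pl = (ws <= w_obs + 1e-12).mean()
    if alternative == "greater":
        return pg
    if alternative == "less":
        return pl
    return min(1.0, 2 * min(pg, pl))


def test_wilcoxon_minimum_p_at_five_folds():
    res = wilcoxon_exact([0.9, 0.8, 0.85, 0.95, 0.7],
                         [0.1, 0.2, 0.15, 0.05, 0.3], alternative="greater")
    assert res.pvalue == pytest.approx(1 / 32)
    assert res.statistic == 15.0


def test_wilcoxon_symmetric_pair_two_sided():
    assert wilcoxon_exact([1.0, -1.0]).pvalue == pytest.approx(1.0)


def test_wilcoxon_all_zero_differences_rejected():
    with pytest.raises(ValueError):
        wilcoxon_exact([1.0, 2.0], [1.0, 2.0])


@pytest.mark.parametrize("alternative", ["greater", "less", "two-sided"])
def test_wilcoxon_matches_enumeration_oracle(alternative):
    rng = np.random.default_rng(12)
    for m in range(2, 11):
        for _ in range(3):
            d = rng.integers(-5, 6, size=m).astype(float)
            d[d == 0] = 1.0  # keep m nonzero pairs (ties in |d| remain)
            res = wilcoxon_exact(d, alternative=alternative)
            assert res.pvalue == pytest.approx(
                _enumeration_oracle(d, alternative), abs=1e-12)


def test_wilcoxon_matches_scipy_exact_without_ties():
    from scipy.stats import wilcoxon as scipy_wilcoxon

    rng = np.random.default_rng(3)
    for _ in range(5):
        d = rng.standard_normal(10)  # continuous: no ties, no zeros
        ours = wilcoxon_exact(d, alternative="greater")
        ref = scipy_wilcoxon(d, alternative="greater", mode="exact")
        assert ours.pvalue == pytest.approx(ref.pvalue, abs=1e-12)


def test_wilcoxon_large_sample_approximation_is_sane():
    rng = np.random.default_rng(4)
    x = rng.standard_normal(30) + 1.0
    res = wilcoxon_exact(x, np.zeros(30), alternative="greater")
    from scipy.stats import wilcoxon as scipy_wilcoxon

    ref = scipy_wilcoxon(x, alternative="greater", mode="approx", correction=True)
    assert res.pvalue == pytest.approx(ref.pvalue, rel=0.01)


def test_holm_examples_and_properties():
    # single p unchanged
    assert holm_adjust([0.2])[0] == pytest.approx(0.2)
    # five tied floor values all become 5 * 0.03125
    assert np.allclose(holm_adjust([0.03125] * 5), 0.15625)
    # adjusted >= raw, <= Bonferroni, <= 1, monotone in sorted order
    rng = np.random.default_rng(8)
    for _ in range(20):
        p = rng.random(6)
        adj = holm_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= np.minimum(1.0, len(p) * p) + 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
    with pytest.raises(ValueError):
        holm_adjust([0.5, 1.2])


def test_holm_agrees_with_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(9)
    p = rng.random(7)
    _, ref, _, _ = multipletests(p, method="holm")
    assert np.allclose(holm_adjust(p), ref)


def test_cohens_d_paired():
    assert cohens_d_paired([2, 3, 4], [1, 1, 1]).d == pytest.approx(2.0)
    assert cohens_d_paired([1, 2, 3], [1, 2, 3]).d == 0.0
    eff = cohens_d_paired([2, 3, 4], [1, 2, 3])  # constant differences
    assert np.isnan(eff.d) and eff.label == "undefined"
    assert cohens_d_paired([1.0, 1.9], [0.1, 0.2]).label in (
        "negligible", "small", "medium", "large")
    with pytest.raises(ValueError):
        cohens_d_paired([1], [2])


def test_friedman_identical_columns_and_textbook_example():
    chi2, p = friedman_test(np.ones((4, 3)))
    assert chi2 == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    # hand-computed: 4 blocks, 3 methods, strict ordering in every block
    m = np.array([[1.0, 2.0, 3.0]] * 4)
    # ranks all (1,2,3): chi2 = 12*4/(3*4) * ((1-2)^2+(2-2)^2+(3-2)^2) = 8
    chi2, p = friedman_test(m)
    assert chi2 == pytest.approx(8.0)
    # column permutation leaves the statistic unchanged
    chi2p, _ = friedman_test(m[:, [2, 0, 1]])
    assert chi2p == pytest.approx(chi2)
    with pytest.raises(ValueError):
        friedman_test(np.ones((1, 3)))


def test_friedman_agrees_with_scipy_without_ties():
    from scipy.stats import friedmanchisquare

    rng = np.random.default_rng(11)
    m = rng.standard_normal((6, 4))
    chi2, p = friedman_test(m)
    ref = friedmanchisquare(*[m[:, j] for j in range(4)])
    assert chi2 == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)


def test_tests_invariant_to_common_shift():
    rng = np.random.default_rng(13)
    x, y = rng.random(5), rng.random(5)
    r1 = wilcoxon_exact(x, y, "greater")
    r2 = wilcoxon_exact(x + 10, y + 10, "greater")
    assert r1 == r2
    assert cohens_d_paired(x, y).d == pytest.approx(cohens_d_paired(x + 3, y + 3).d)


def test_stat_report_layout():
    rng = np.random.default_rng(14)
    rows = []
    for method, mu in [("maxpool", 0.95), ("meanpool", 0.90), ("abmil", 0.92)]:
        for fold in range(5):
            rows.append({"method": method, "fold": fold,
                         "value": mu + 0.01 * rng.standard_normal()})
    report = build_stat_report(pd.DataFrame(rows), reference="maxpool",
                               alternative="greater")
    table = report["pairwise"]
    assert len(table) == 2
    assert {"comparison", "delta_mean", "raw_p", "holm_adj_p", "cohens_d",
            "effect"} <= set(table.columns)
    assert (table["holm_adj_p"] >= table["raw_p"] - 1e-15).all()
    assert 0 <= report["friedman_p"] <= 1
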