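"""Inference layer: t-tests, Type III ANOVA, post-hocs, mixed models,
correlations, chi-square."""

import numpy as np
import pandas as pd
import pytest

from nirspt.stats import (
    anova_2x2_type3,
    chisq_2x2,
    fit_rt_lmm,
    independent_t,
    nakagawa_r2,
    pearson_corr,
    posthoc_pairwise,
)

from conftest import type3_anova_oracle


# ---------------------------------------------------------------- t-test
def test_t_test_identical_samples():
    res = independent_t([1, 2, 3], [1, 2, 3])
    assert res.t == 0 and res.cohens_d == 0 and res.p == pytest.approx(1.0)


def test_t_test_hand_computed():
    """(1,2,3) vs (4,5,6): pooled sd 1, t = -3/sqrt(2/3), d = -3."""
    res = independent_t([1, 2, 3], [4, 5, 6])
    assert res.t == pytest.approx(-3.6742346, abs=1e-6)
    assert res.cohens_d == pytest.approx(-3.0, abs=1e-12)
    assert res.df == 4
    assert res.ci_95[0] < -3.0 < res.ci_95[1]


@pytest.mark.parametrize("c", [0.1, 2.0, 1000.0])
def test_t_test_scale_invariance(c):
    rng = np.random.default_rng(0)
    a, b = rng.standard_normal(10), rng.standard_normal(12) + 0.5
    r1, r2 = independent_t(a, b), independent_t(c * a, c * b)
    assert r1.t == pytest.approx(r2.t)
    assert r1.p == pytest.approx(r2.p)
    assert r1.cohens_d == pytest.approx(r2.cohens_d)


def test_t_test_guards():
    with pytest.raises(ValueError):
        independent_t([1.0], [1, 2, 3])
    with pytest.raises(ValueError):
        independent_t([1, 1], [1, 1])


def test_t_squared_equals_one_way_f():
    """For two groups, t^2 equals the one-way ANOVA F."""
    rng = np.random.default_rng(1)
    a, b = rng.standard_normal(15), rng.standard_normal(9) + 0.3
    from scipy.stats import f_oneway

    t = independent_t(a, b).t
    assert t**2 == pytest.approx(f_oneway(a, b).statistic, rel=1e-10)


# ---------------------------------------------------------------- ANOVA
def _unbalanced_data(rng, sizes=(64, 9, 31, 13)):
    cells = [("e", "c"), ("e", "i"), ("a", "c"), ("a", "i")]
    y, p, c = [], [], []
    for (pp, cc), n in zip(cells, sizes):
        y.extend(rng.standard_normal(n) + rng.normal())
        p.extend([pp] * n)
        c.extend([cc] * n)
    return np.asarray(y), p, c


def test_anova_error_df_at_study_cell_sizes():
    """With cells 64/9/31/13 every effect reports df (1, 113)."""
    y, p, c = _unbalanced_data(np.random.default_rng(2))
    res = anova_2x2_type3(y, p, c)
    for eff in res.effects().values():
        assert eff.df == (1.0, 113.0)
        assert 0 <= eff.partial_eta_sq <= 1


def test_anova_matches_model_comparison_oracle():
    """Type III F and SS agree with the brute-force full-vs-reduced OLS
    oracle to 1e-8 on random unbalanced datasets."""
    rng = np.random.default_rng(3)
    for _ in range(50):
        sizes = rng.integers(3, 40, size=4)
        y, p, c = _unbalanced_data(rng, sizes)
        res = anova_2x2_type3(y, p, c)
        oracle = type3_anova_oracle(y, p, c)
        for name, eff in res.effects().items():
            assert abs(eff.F - oracle[name]["F"]) < 1e-8
            assert abs(eff.ss - oracle[name]["ss"]) < 1e-8


def test_anova_type3_equals_sequential_when_balanced():
    """In a balanced design Type III and sequential SS coincide."""
    rng = np.random.default_rng(4)
    y, p, c = _unbalanced_data(rng, (20, 20, 20, 20))
    res = anova_2x2_type3(y, p, c)
    # sequential (Type I) via incremental RSS under sum-to-zero coding
    pv = np.where(np.asarray(p) == "a", 1.0, -1.0)
    cv = np.where(np.asarray(c) == "c", 1.0, -1.0)
    X = np.column_stack([np.ones_like(y), pv, cv, pv * cv])

    def rss(k):
        b, *_ = np.linalg.lstsq(X[:, :k], y, rcond=None)
        return float(((y - X[:, :k] @ b) ** 2).sum())

    seq = {
        "perspective": rss(1) - rss(2),
        "consistency": rss(2) - rss(3),
        "interaction": rss(3) - rss(4),
    }
    for name, eff in res.effects().items():
        assert eff.ss == pytest.approx(seq[name], abs=1e-8)


def test_anova_pure_interaction_construction():
    """Balanced +a/-a/-a/+a cell means load only the interaction."""
    a = 1.0
    n = 12
    y, p, c = [], [], []
    for (pp, cc), mu in zip(
        [("e", "c"), ("e", "i"), ("a", "c"), ("a", "i")], [a, -a, -a, a]
    ):
        base = np.linspace(-0.5, 0.5, n)  # zero-mean within-cell spread
        y.extend(mu + base)
        p.extend([pp] * n)
        c.extend([cc] * n)
    res = anova_2x2_type3(np.asarray(y), p, c)
    assert res.perspective.F <= 1e-10 * res.interaction.F
    assert res.consistency.F <= 1e-10 * res.interaction.F


def test_anova_rejects_empty_cell():
    y, p, c = _unbalanced_data(np.random.default_rng(5), (10, 0, 10, 10))
    with pytest.raises(ValueError, match="non-empty"):
        anova_2x2_type3(y, p, c)


# ------------------------------------------------------------- post-hoc
def test_posthoc_pairwise_counts_and_bonferroni():
    rng = np.random.default_rng(6)
    values = rng.standard_normal(40)
    labels = np.repeat(list("abcd"), 10)
    out = posthoc_pairwise(values, labels, correction="none")
    assert len(out) == 6  # k(k-1)/2
    bonf = posthoc_pairwise(values, labels, correction="bonferroni")
    for raw, corr in zip(out["p_raw"], bonf["p"]):
        assert corr == pytest.approx(min(raw * 6, 1.0))


def test_posthoc_flags_tiny_groups():
    values = [1.0, 2.0, 3.0, 4.0, 10.0]
    labels = ["a", "a", "b", "b", "c"]
    out = posthoc_pairwise(values, labels)
    assert not out.loc[(out.group_a == "a") & (out.group_b == "c"), "computed"].item()
    assert out.loc[(out.group_a == "a") & (out.group_b == "b"), "computed"].item()


# ------------------------------------------------------------------ LMM
def _lmm_cohort(rng, interaction=0.3, n_ego=9, n_alt=13, resid_sd=0.3):
    """Trial-level log-RT data with by-subject and by-trial random
    effects and a planted group x response interaction."""
    rows = []
    trial_eff = rng.normal(0, 0.05, 24)
    sid = 0
    for g, n_subj, inter in (
        ("altercentric-inconsistent", n_alt, 0.0),
        ("egocentric-inconsistent", n_ego, interaction),
    ):
        for _ in range(n_subj):
            sid += 1
            u0, u1 = rng.normal(0, 0.2), rng.normal(0, 0.1)
            for t in range(24):
                resp = "altercentric" if rng.random() < 0.5 else "egocentric"
                x = float(resp == "altercentric")
                mu = 7.8 + inter * x + u0 + u1 * x + trial_eff[t]
                rows.append(
                    {
                        "subject": f"s{sid}",
                        "trial": t + 1,
                        "group": g,
                        "response": resp,
                        "rt": float(np.exp(mu + rng.normal(0, resid_sd))),
                    }
                )
    return pd.DataFrame(rows)


def test_lmm_recovers_planted_interaction():
    """Mean interaction estimate over replicates is within 3 MC SE of the
    planted 0.3 log-ms effect."""
    rng = np.random.default_rng(7)
    ests = []
    for _ in range(40):
        res = fit_rt_lmm(_lmm_cohort(rng))
        term = [i for i in res.fixed_effects.index if ":" in i][0]
        ests.append(res.fixed_effects.loc[term, "estimate"])
    ests = np.asarray(ests)
    se = ests.std(ddof=1) / np.sqrt(len(ests))
    assert abs(ests.mean() - 0.3) < 3 * se


def test_lmm_type_one_behavior():
    """With no response effect, |t(response)| < 2 in >= 90% of replicates."""
    rng = np.random.default_rng(8)
    calm = 0
    n_rep = 100
    for _ in range(n_rep):
        res = fit_rt_lmm(_lmm_cohort(rng, interaction=0.0))
        t = abs(res.fixed_effects.loc["response[altercentric]", "t"])
        calm += t < 2
    assert calm >= 0.9 * n_rep


def test_lmm_r2_ordering_and_guards():
    rng = np.random.default_rng(9)
    res = fit_rt_lmm(_lmm_cohort(rng))
    assert 0 <= res.r2_marginal <= res.r2_conditional <= 1
    assert set(res.posthoc["group"]) == {
        "altercentric-inconsistent",
        "egocentric-inconsistent",
    }

    flat = _lmm_cohort(rng).assign(rt=1000.0)
    with pytest.raises(ValueError, match="zero RT variance"):
        fit_rt_lmm(flat)
    single = _lmm_cohort(rng)
    single = single[single["subject"] == "s1"]
    with pytest.raises(ValueError, match="2 subjects"):
        fit_rt_lmm(single)


def test_nakagawa_r2_formula():
    assert nakagawa_r2(1.0, 2.0, 1.0) == pytest.approx((0.25, 0.75))
    r2m, r2c = nakagawa_r2(1.0, 0.0, 3.0)
    assert r2m == r2c == pytest.approx(0.25)
    assert nakagawa_r2(0.0, 2.0, 2.0)[0] == 0.0


# --------------------------------------------------- correlation / chi2
def test_pearson_corr_cases():
    x = np.array([1.0, 2.0, 3.0])
    assert pearson_corr(x, x).r == pytest.approx(1.0)
    assert pearson_corr(x, -x).r == pytest.approx(-1.0)
    assert pearson_corr(x, [1, 2, 4]).r == pytest.approx(0.98198, abs=1e-5)
    with pytest.raises(ValueError):
        pearson_corr([1, 1, 1], [1, 2, 3])


def test_chisq_2x2_cases():
    assert chisq_2x2([[10, 90], [20, 180]]).chi_sq == pytest.approx(0.0)
    res = chisq_2x2([[10, 90], [20, 80]])
    assert res.chi_sq == pytest.approx(3.9216, abs=1e-4)
    assert res.df == 1
    scaled = chisq_2x2([[100, 900], [200, 800]])
    assert scaled.chi_sq == pytest.approx(10 * res.chi_sq, rel=1e-10)
    with pytest.raises(ValueError):
        chisq_2x2([[0, 0], [5, 5]])
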