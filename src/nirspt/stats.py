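"""Group-level inference: t-tests, unbalanced 2x2 Type III ANOVA,
post-hoc comparisons, log-RT mixed models, correlations, chi-square.

The factorial analyses treat perspective (egocentric vs altercentric) and
consistency (consistent vs inconsistent) as between-subject factors with
strongly unequal cell sizes, so sums of squares are Type III under
sum-to-zero contrasts: each effect is adjusted for all others, which is
the appropriate decomposition when the design is unbalanced.  Effect
sizes follow the field's conventions: Cohen's d for t-tests, partial η²
for ANOVA effects, and marginal/conditional R² for mixed models.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


@dataclass
class TTestResult:
    t: float
    p: float
    cohens_d: float
    ci_95: tuple[float, float]
    df: float
    mean_difference: float


@dataclass
class AnovaEffect:
    F: float
    p: float
    df: tuple[float, float]
    partial_eta_sq: float
    ss: float
    ms_error: float


@dataclass
class AnovaResult:
    perspective: AnovaEffect
    consistency: AnovaEffect
    interaction: AnovaEffect

    def effects(self) -> dict[str, AnovaEffect]:
        return {
            "perspective": self.perspective,
            "consistency": self.consistency,
            "interaction": self.interaction,
        }


@dataclass
class CorrResult:
    r: float
    p: float
    n: int


@dataclass
class ChisqResult:
    chi_sq: float
    df: int
    p: float


@dataclass
class LmmResult:
    fixed_effects: pd.DataFrame  # index: term; cols estimate, se, t, p
    variance_components: dict[str, float]
    r2_marginal: float
    r2_conditional: float
    posthoc: pd.DataFrame
    converged: bool


def independent_t(sample_a, sample_b) -> TTestResult:
    """Two-tailed independent-samples Student t-test (pooled variance).

    Cohen's d is the mean difference over the pooled SD; the 95% CI is on
    the mean difference.  Variance homogeneity is assumed (use Welch
    externally if it is not).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        raise ValueError("degenerate samples: pooled variance is zero")
    sp = np.sqrt(sp2)
    diff = a.mean() - b.mean()
    se = sp * np.sqrt(1.0 / na + 1.0 / nb)
    t = diff / se
    p = 2 * sstats.t.sf(abs(t), df)
    tcrit = sstats.t.ppf(0.975, df)
    return TTestResult(
        t=float(t),
        p=float(p),
        cohens_d=float(diff / sp),
        ci_95=(float(diff - tcrit * se), float(diff + tcrit * se)),
        df=float(df),
        mean_difference=float(diff),
    )


def anova_2x2_type3(
    values: Sequence[float],
    factor_perspective: Sequence[str],
    factor_consistency: Sequence[str],
) -> AnovaResult:
    """Unbalanced 2x2 between-subjects ANOVA with Type III sums of squares.

    Effects are estimated under sum-to-zero contrasts so that each main
    effect is the (unweighted) marginal contrast adjusted for the other
    effects; partial η² = SS_effect / (SS_effect + SS_error).  Error df is
    N - 4.
    """
    df_data = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "p": list(factor_perspective),
            "c": list(factor_consistency),
        }
    )
    cells = df_data.groupby(["p", "c"]).size()
    if len(cells) < 4 or (cells == 0).any():
        raise ValueError(f"all four cells must be non-empty; got\n{cells}")
    model = smf.ols("y ~ C(p, Sum) * C(c, Sum)", data=df_data).fit()
    table = anova_lm(model, typ=3)
    ss_err = float(table.loc["Residual", "sum_sq"])
    df_err = float(table.loc["Residual", "df"])
    ms_err = ss_err / df_err

    def effect(row: str) -> AnovaEffect:
        ss = float(table.loc[row, "sum_sq"])
        return AnovaEffect(
            F=float(table.loc[row, "F"]),
            p=float(table.loc[row, "PR(>F)"]),
            df=(float(table.loc[row, "df"]), df_err),
            partial_eta_sq=float(ss / (ss + ss_err)),
            ss=ss,
            ms_error=ms_err,
        )

    return AnovaResult(
        perspective=effect("C(p, Sum)"),
        consistency=effect("C(c, Sum)"),
        interaction=effect("C(p, Sum):C(c, Sum)"),
    )


def posthoc_pairwise(
    values: Sequence[float],
    group_labels: Sequence[str],
    correction: str = "none",
) -> pd.DataFrame:
    """All pairwise two-sample (pooled-variance) comparisons.

    ``correction="bonferroni"`` multiplies each p by the number of
    comparisons (capped at 1).  Pairs involving a group with n < 2 are
    flagged and left uncomputed.
    """
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = list(dict.fromkeys(labels))  # stable order of appearance
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    pairs = list(combinations(groups, 2))
    m = len(pairs)
    rows = []
    for ga, gb in pairs:
        a, b = values[labels == ga], values[labels == gb]
        if len(a) < 2 or len(b) < 2:
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "mean_diff": np.nan,
                    "t": np.nan,
                    "p_raw": np.nan,
                    "p": np.nan,
                    "computed": False,
                }
            )
            continue
        res = independent_t(a, b)
        p = res.p if correction == "none" else min(res.p * m, 1.0)
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "mean_diff": res.mean_difference,
                "t": res.t,
                "p_raw": res.p,
                "p": p,
                "computed": True,
            }
        )
    return pd.DataFrame(rows)


def nakagawa_r2(
    var_fixed: float, var_random: float, var_resid: float
) -> tuple[float, float]:
    """Marginal and conditional mixed-model R².

    R²m = σ²_f / (σ²_f + σ²_r + σ²_e): variance explained by the fixed
    effects alone; R²c adds the random-effect variance to the numerator.
    """
    total = var_fixed + var_random + var_resid
    if total <= 0:
        raise ValueError("total variance must be positive")
    return var_fixed / total, (var_fixed + var_random) / total


def fit_rt_lmm(trial_table: pd.DataFrame) -> LmmResult:
    """Trial-level log-RT mixed model for the inconsistent subgroups.

    Fixed effects: group (between subjects) x response (the trial's
    implied perspective, within subjects) on log RT.  Random effects:
    per-trial intercepts plus a by-subject random intercept and response
    slope.  Estimated by maximum likelihood (not REML).  Post-hoc
    response contrasts within each group are Bonferroni-corrected.

    ``trial_table`` needs columns subject, trial, group, response, rt.
    """
    required = {"subject", "trial", "group", "response", "rt"}
    missing = required - set(trial_table.columns)
    if missing:
        raise ValueError(f"trial table missing columns {sorted(missing)}")
    data = trial_table.copy()
    if data["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    if data["trial"].nunique() < 2:
        raise ValueError("need at least 2 trial levels")
    if np.any(data["rt"] <= 0):
        raise ValueError("RTs must be positive for the log transform")
    data["logrt"] = np.log(data["rt"].astype(float))
    if data["logrt"].var() == 0:
        raise ValueError("zero RT variance; model is degenerate")
    # indicator coding: reference = first level alphabetically
    data["resp_alt"] = (data["response"] == "altercentric").astype(float)
    group_levels = sorted(data["group"].unique())
    if len(group_levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {group_levels}")
    data["group_b"] = (data["group"] == group_levels[1]).astype(float)

    model = smf.mixedlm(
        "logrt ~ group_b * resp_alt",
        data=data,
        groups="subject",
        re_formula="~resp_alt",
        vc_formula={"trial": "0 + C(trial)"},
    )
    import warnings

    with warnings.catch_warnings():
        # boundary estimates (zero variance components) are expected and
        # handled; the retry path converges
        warnings.simplefilter("ignore")
        fit = model.fit(reml=False)

    fe = pd.DataFrame(
        {
            "estimate": fit.fe_params,
            "se": fit.bse_fe,
            "t": fit.tvalues[fit.fe_params.index],
            "p": fit.pvalues[fit.fe_params.index],
        }
    )
    fe.index = fe.index.str.replace("group_b", f"group[{group_levels[1]}]").str.replace(
        "resp_alt", "response[altercentric]"
    )

    # variance decomposition for Nakagawa R²
    X = pd.DataFrame(
        {
            "Intercept": 1.0,
            "group_b": data["group_b"],
            "resp_alt": data["resp_alt"],
            "group_b:resp_alt": data["group_b"] * data["resp_alt"],
        }
    )[fit.fe_params.index]
    var_fixed = float(np.var(X.values @ fit.fe_params.values))
    cov_re = fit.cov_re.values  # subject intercept/slope covariance
    x = data["resp_alt"].values
    var_subject = float(
        cov_re[0, 0] + 2 * cov_re[0, 1] * x.mean() + cov_re[1, 1] * np.mean(x**2)
    )
    var_trial = float(fit.vcomp[0]) if len(fit.vcomp) else 0.0
    var_resid = float(fit.scale)
    r2m, r2c = nakagawa_r2(var_fixed, var_subject + var_trial, var_resid)

    posthoc_rows = []
    n_tests = len(group_levels)
    for g in group_levels:
        sub = data[data["group"] == g]
        ego = sub.loc[sub["resp_alt"] == 0, "logrt"].values
        alt = sub.loc[sub["resp_alt"] == 1, "logrt"].values
        if len(ego) >= 2 and len(alt) >= 2:
            res = independent_t(alt, ego)
            posthoc_rows.append(
                {
                    "group": g,
                    "contrast": "altercentric - egocentric response",
                    "mean_diff_log": res.mean_difference,
                    "t": res.t,
                    "p_raw": res.p,
                    "p_bonferroni": min(res.p * n_tests, 1.0),
                }
            )

    return LmmResult(
        fixed_effects=fe,
        variance_components={
            "trial_intercept": var_trial,
            "subject": var_subject,
            "residual": var_resid,
        },
        r2_marginal=float(r2m),
        r2_conditional=float(r2c),
        posthoc=pd.DataFrame(posthoc_rows),
        converged=bool(fit.converged),
    )


def pearson_corr(x, y) -> CorrResult:
    """Pearson correlation with two-tailed t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y differ in length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = sstats.pearsonr(x, y)
    return CorrResult(r=float(r), p=float(p), n=len(x))


def chisq_2x2(table) -> ChisqResult:
    """Pearson chi-square on a 2x2 contingency table, no continuity
    correction (Yates available upstream via scipy if wanted)."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("all row and column margins must be positive")
    chi2, p, dof, _ = sstats.chi2_contingency(obs, correction=False)
    return ChisqResult(chi_sq=float(chi2), df=int(dof), p=float(p))
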