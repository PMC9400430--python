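"""Associations of the risk model with clinical variables and immune state.

Covers: chi-square (with Fisher fallback) of risk group vs categorical
clinical variables, rank-sum comparison of risk scores across clinical
strata, Cox independence models (risk + clinical covariates, uni- and
multivariate), Spearman correlation of risk with infiltration fractions,
and high-vs-low group rank-sum tests for cell fractions or checkpoint gene
expression. Significance stars follow the usual convention:
p<0.05 -> *, p<0.01 -> **, p<0.001 -> ***.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cox import cox_fit
from .screen import rank_sum_test
from .survival_eval import RiskStratification

logger = logging.getLogger("pairrisk")

ASSOC_COLUMNS = ["variable", "test", "statistic", "p", "effect", "stars"]


def stars(p: float) -> str:
    """Significance stars; a pure function of p."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _result(variable, test, statistic, p, effect=np.nan) -> dict:
    return {"variable": variable, "test": test, "statistic": statistic,
            "p": p, "effect": effect, "stars": stars(p)}


def _categorize(values: pd.Series, variable: str, age_cut: float | None):
    """Categorical view of a clinical column; age is dichotomized."""
    vals = pd.to_numeric(values, errors="coerce")
    if variable == "age":
        cut = float(np.nanmedian(vals)) if age_cut is None else age_cut
        return pd.Series(np.where(vals > cut, f">{cut:g}", f"<={cut:g}"),
                         index=values.index).where(vals.notna())
    return vals.astype("Int64").astype(str).where(vals.notna())


def chisq_group_vs_clinical(strat: RiskStratification, clinical: pd.DataFrame,
                            variable: str, age_cut: float | None = None
                            ) -> pd.Series:
    """Pearson chi-square (no Yates correction) of risk group vs a
    categorical clinical variable; Fisher's exact when a 2x2 table has an
    expected count below 5."""
    cat = _categorize(clinical[variable], variable, age_cut)
    ok = cat.notna()
    table = pd.crosstab(strat.assignments[ok], cat[ok])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(f"variable {variable!r} has a single level after "
                         "cross-tabulation")
    obs = table.to_numpy(float)
    expected = stats.contingency.expected_freq(obs)
    if (expected < 5).any() and obs.shape == (2, 2):
        logger.info("expected count < 5 for %s: Fisher's exact fallback", variable)
        _, p = stats.fisher_exact(obs)
        return pd.Series(_result(variable, "fisher_exact", np.nan, p))
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return pd.Series(_result(variable, "chi_square", chi2, p))


def riskscore_by_stratum(scores: pd.Series, clinical: pd.DataFrame,
                         variable: str, age_cut: float | None = None
                         ) -> pd.Series:
    """Rank-sum test of risk scores across the strata of one variable.

    Two strata get the unpaired Wilcoxon rank-sum test; more get
    Kruskal-Wallis. Effect is the median difference (two strata, ordered by
    level)."""
    cat = _categorize(clinical[variable], variable, age_cut)
    ok = cat.notna() & scores.reindex(cat.index).notna()
    cat, sc = cat[ok], scores.reindex(cat.index)[ok]
    levels = sorted(cat.unique())
    groups = [sc[cat == lv].to_numpy(float) for lv in levels]
    for lv, g in zip(levels, groups):
        if len(g) == 0:
            raise ValueError(f"empty stratum {lv!r} for variable {variable!r}")
    if len(levels) < 2:
        raise ValueError(f"variable {variable!r} has a single stratum")
    if len(levels) == 2:
        p = rank_sum_test(groups[0], groups[1])
        effect = float(np.median(groups[1]) - np.median(groups[0]))
        return pd.Series(_result(variable, "wilcoxon", np.nan, p, effect))
    h, p = stats.kruskal(*groups)
    return pd.Series(_result(variable, "kruskal_wallis", h, p))


def cox_independence(scores: pd.Series, clinical: pd.DataFrame,
                     covariates=("age", "grade", "stage"),
                     use_log_score: bool = True, ties: str = "breslow"
                     ) -> pd.DataFrame:
    """Uni- and multivariate Cox of survival on risk plus clinical terms.

    The risk score enters on the log scale by default (the Cox linear
    predictor itself); rows with any missing covariate are dropped for the
    multivariate fit. Returns one row per (model, term) with HR, CI and
    Wald p."""
    df = clinical.copy()
    sc = scores.reindex(df.index)
    df["risk"] = np.log(sc) if use_log_score else sc
    terms = ["risk"] + [c for c in covariates if c in df.columns]
    rows = []
    for term in terms:
        sub = df[["time", "event", term]].dropna()
        if sub[term].nunique() <= 1:
            logger.warning("skipping constant covariate %r", term)
            continue
        res = cox_fit(sub[[term]].astype(float), sub["time"], sub["event"],
                      ties=ties)
        t = res.table().iloc[0]
        rows.append({"model": "univariate", "term": term, "coef": t["Coef"],
                     "hr": t["HR"], "hr_ci_low": t["HR.95L"],
                     "hr_ci_high": t["HR.95H"], "p": t["p value"],
                     "stars": stars(t["p value"])})
    multi_terms = [t for t in terms if df[t].nunique(dropna=True) > 1]
    sub = df[["time", "event"] + multi_terms].dropna()
    res = cox_fit(sub[multi_terms].astype(float), sub["time"], sub["event"],
                  ties=ties)
    for term, t in res.table().iterrows():
        rows.append({"model": "multivariate", "term": term, "coef": t["Coef"],
                     "hr": t["HR"], "hr_ci_low": t["HR.95L"],
                     "hr_ci_high": t["HR.95H"], "p": t["p value"],
                     "stars": stars(t["p value"])})
    return pd.DataFrame(rows)


def immune_correlation(scores: pd.Series, infiltration: pd.DataFrame,
                       p_max: float = 0.05) -> pd.DataFrame:
    """Spearman correlation of risk score with each cell type's fraction.

    ``infiltration`` is cell types x samples. Constant rows have no defined
    rank correlation and are flagged/excluded. ``significant`` marks rows
    with p below ``p_max``."""
    common = [s for s in infiltration.columns if s in scores.index]
    if len(common) < 3:
        raise ValueError("need at least 3 shared samples for correlation")
    sc = scores.loc[common].to_numpy(float)
    rows = []
    for cell in infiltration.index:
        frac = infiltration.loc[cell, common].to_numpy(float)
        if np.ptp(frac) == 0 or np.ptp(sc) == 0:
            logger.warning("constant input for %r: Spearman undefined", cell)
            rows.append(_result(cell, "spearman", np.nan, np.nan))
            continue
        rho, p = stats.spearmanr(sc, frac)
        rows.append(_result(cell, "spearman", rho, p, effect=rho))
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < p_max
    return out


def group_difference_tests(values: pd.DataFrame, strat: RiskStratification
                           ) -> pd.DataFrame:
    """Rank-sum high-vs-low tests per row of a values table.

    ``values`` is features x samples (cell fractions or checkpoint gene
    expression). Direction is the sign of median(high) - median(low). A BH
    column is emitted alongside the raw p for transparency, but stars
    follow the raw p."""
    high = [s for s in values.columns if strat.assignments.get(s) == "high"]
    low = [s for s in values.columns if strat.assignments.get(s) == "low"]
    if not high or not low:
        raise ValueError("both risk groups must be represented in the values table")
    rows = []
    for feat in values.index:
        h = values.loc[feat, high].to_numpy(float)
        l = values.loc[feat, low].to_numpy(float)
        p = rank_sum_test(h, l)
        diff = float(np.median(h) - np.median(l))
        rec = _result(feat, "wilcoxon", np.nan, p, effect=diff)
        rec["direction"] = "higher_in_high" if diff > 0 else (
            "lower_in_high" if diff < 0 else "none")
        rec["low_information"] = bool((h != 0).sum() + (l != 0).sum() <= 1)
        rows.append(rec)
    out = pd.DataFrame(rows)
    _, fdr, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
    out["fdr_bh"] = fdr
    return out
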