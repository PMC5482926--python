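"""Statistics linking latent class membership to outcome and adherence.

Covers the downstream analyses of the early-change design: contingency
tables with Pearson standardized residuals, one-way ANOVAs with
Bonferroni-corrected pairwise contrasts, predictor-screening Pearson
correlations, hierarchical (blockwise) regression with single-shot
exclusion of non-significant entrants, and multinomial logistic
regression of class membership on intake characteristics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .reliable_change import pooled_sd_effect_size

__all__ = [
    "ContingencyResult",
    "AnovaResult",
    "RegressionSteps",
    "MultinomialFit",
    "contingency_analysis",
    "oneway_anova_bonferroni",
    "screen_predictors",
    "hierarchical_regression",
    "multinomial_class_prediction",
]


# ---------------------------------------------------------------------------
@dataclass
class ContingencyResult:
    observed: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    df: int
    p_value: float
    standardized_residuals: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
            "observed": self.observed.to_dict(),
            "expected": self.expected.round(4).to_dict(),
            "standardized_residuals": self.standardized_residuals.round(4).to_dict(),
        }


def contingency_analysis(table: pd.DataFrame | np.ndarray) -> ContingencyResult:
    """Pearson chi-square test with (O - E) / sqrt(E) cell residuals.

    The residual is the plain Pearson standardized residual, not the
    adjusted (Haberman) residual.
    """
    df_in = table if isinstance(table, pd.DataFrame) else pd.DataFrame(np.asarray(table))
    O = df_in.to_numpy(dtype=float)
    if O.shape[0] < 2 or O.shape[1] < 2:
        raise ValueError("contingency table needs at least 2 rows and 2 columns")
    if (O < 0).any():
        raise ValueError("counts must be non-negative")
    if (O.sum(axis=1) == 0).any() or (O.sum(axis=0) == 0).any():
        raise ValueError("zero marginal row or column")
    chi2, p, dof, E = stats.chi2_contingency(O, correction=False)
    resid = (O - E) / np.sqrt(E)
    return ContingencyResult(
        observed=df_in,
        expected=pd.DataFrame(E, index=df_in.index, columns=df_in.columns),
        chi2=float(chi2),
        df=int(dof),
        p_value=float(p),
        standardized_residuals=pd.DataFrame(resid, index=df_in.index, columns=df_in.columns),
    )


# ---------------------------------------------------------------------------
@dataclass
class AnovaResult:
    group_stats: pd.DataFrame  # mean, sd, n per group
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    pairwise: pd.DataFrame  # group1, group2, t, p_raw, p_bonferroni, d

    def to_dict(self) -> dict:
        return {
            "F": self.f_statistic,
            "df": [self.df_between, self.df_within],
            "p_value": self.p_value,
            "groups": self.group_stats.to_dict(orient="index"),
            "pairwise": self.pairwise.to_dict(orient="records"),
        }


def oneway_anova_bonferroni(values, group_labels) -> AnovaResult:
    """Classical one-way ANOVA with Bonferroni-corrected pooled-t contrasts.

    Pairwise contrasts use the equal-variance two-sample t test; adjusted
    p-values are min(1, raw p x number of pairwise comparisons).  Each
    pair's effect size is the pooled-SD Cohen's d.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    ok = ~np.isnan(values)
    values, group_labels = values[ok], group_labels[ok]
    groups = list(pd.unique(group_labels))
    if len(groups) < 2:
        raise ValueError("at least 2 groups required")
    per = {g: values[group_labels == g] for g in groups}
    if any(len(v) < 2 for v in per.values()):
        raise ValueError("every group needs at least 2 observations")

    grand = values.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in per.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in per.values())
    df_b = len(groups) - 1
    df_w = len(values) - len(groups)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    F = ms_b / ms_w if ms_w > 0 else 0.0
    p = float(stats.f.sf(F, df_b, df_w)) if ms_w > 0 else 1.0

    gstats = pd.DataFrame(
        {
            "mean": {g: per[g].mean() for g in groups},
            "sd": {g: per[g].std(ddof=1) for g in groups},
            "n": {g: len(per[g]) for g in groups},
        }
    )
    pairs = list(itertools.combinations(groups, 2))
    rows = []
    for g1, g2 in pairs:
        t, praw = stats.ttest_ind(per[g1], per[g2], equal_var=True)
        d = pooled_sd_effect_size(
            per[g1].mean(), per[g1].std(ddof=1), len(per[g1]),
            per[g2].mean(), per[g2].std(ddof=1), len(per[g2]),
        )
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "t": float(t),
                "p_raw": float(praw),
                "p_bonferroni": min(1.0, float(praw) * len(pairs)),
                "d": d,
            }
        )
    return AnovaResult(
        group_stats=gstats,
        f_statistic=float(F),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        pairwise=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
def screen_predictors(covariates: pd.DataFrame, outcome: np.ndarray) -> pd.DataFrame:
    """Pearson correlation of each covariate column with the outcome.

    Returns a frame with columns r, p and n (pairwise-complete cases).
    """
    outcome = np.asarray(outcome, dtype=float)
    rows = {}
    for col in covariates.columns:
        x = covariates[col].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(outcome))
        if ok.sum() < 3:
            raise ValueError(f"predictor {col!r}: fewer than 3 complete pairs")
        if np.std(x[ok]) == 0:
            raise ValueError(f"predictor {col!r} has zero variance")
        r, p = stats.pearsonr(x[ok], outcome[ok])
        rows[col] = {"r": float(r), "p": float(p), "n": int(ok.sum())}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
@dataclass
class RegressionSteps:
    steps: list  # per step: name, predictors, r2, delta_r2, f_change, p_change
    final_betas: pd.DataFrame  # standardized beta, t, p per retained predictor
    excluded: list  # (predictor, t, p) dropped at their entry step
    n: int

    def to_dict(self) -> dict:
        return {
            "steps": self.steps,
            "final_betas": self.final_betas.round(6).to_dict(orient="index"),
            "excluded": self.excluded,
            "n": self.n,
        }


def _ols(y: np.ndarray, X: pd.DataFrame):
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return model


def hierarchical_regression(
    outcome,
    blocks: Sequence[tuple[str, pd.DataFrame]],
    exclusion_alpha: float = 0.05,
) -> RegressionSteps:
    """Blockwise OLS with per-step R-squared change and entrant screening.

    Blocks enter cumulatively in the given order.  After a block enters,
    any of *its* predictors whose coefficient p-value exceeds
    ``exclusion_alpha`` is dropped before the next block enters; the
    exclusion t and p are reported.  The per-step R-squared and its F-test
    are computed on the model as entered (before exclusion).
    """
    y = np.asarray(outcome, dtype=float)
    n = y.size
    steps, excluded = [], []
    kept = pd.DataFrame(index=range(n))
    r2_prev = 0.0
    blocks = list(blocks)
    for bi, (name, block) in enumerate(blocks):
        block = block.reset_index(drop=True)
        design = pd.concat([kept, block], axis=1)
        if n <= design.shape[1] + 1:
            raise ValueError("more predictors than observations")
        fit = _ols(y, design)
        if np.linalg.matrix_rank(sm.add_constant(design).to_numpy()) < design.shape[1] + 1:
            raise ValueError(f"rank-deficient design at step {name!r}")
        r2 = float(fit.rsquared)
        q = block.shape[1]
        df_resid = n - design.shape[1] - 1
        if r2 < 1.0 and q > 0:
            f_change = ((r2 - r2_prev) / q) / ((1.0 - r2) / df_resid)
            p_change = float(stats.f.sf(f_change, q, df_resid))
        else:
            f_change, p_change = float("inf"), 0.0
        steps.append(
            {
                "name": name,
                "predictors": list(design.columns),
                "r2": r2,
                "delta_r2": r2 - r2_prev,
                "f_change": float(f_change),
                "p_change": p_change,
            }
        )
        # single-shot exclusion of this block's non-significant entrants
        # before the next block enters (the final block keeps all entrants)
        is_last = bi == len(blocks) - 1
        keep_cols = list(kept.columns)
        for col in block.columns:
            t, p = float(fit.tvalues[col]), float(fit.pvalues[col])
            if p > exclusion_alpha and not is_last:
                excluded.append({"predictor": col, "t": t, "p": p, "step": name})
            else:
                keep_cols.append(col)
        kept = design[keep_cols]
        r2_prev = r2

    final = _ols(y, kept)
    sd_y = np.std(y, ddof=1)
    betas = {}
    for col in kept.columns:
        b = float(final.params[col])
        betas[col] = {
            "beta": b * float(np.std(kept[col], ddof=1)) / sd_y,
            "b": b,
            "t": float(final.tvalues[col]),
            "p": float(final.pvalues[col]),
        }
    return RegressionSteps(
        steps=steps,
        final_betas=pd.DataFrame(betas).T,
        excluded=excluded,
        n=n,
    )


# ---------------------------------------------------------------------------
@dataclass
class MultinomialFit:
    reference_class: object
    coefficients: pd.DataFrame  # contrast, predictor, B, SE, p, OR, CI bounds
    model_chi2: float
    model_df: int
    model_p: float
    cox_snell_r2: float
    nagelkerke_r2: float
    log_likelihood: float
    null_log_likelihood: float
    separation_flag: bool = False

    def to_dict(self) -> dict:
        return {
            "reference_class": self.reference_class,
            "coefficients": self.coefficients.round(6).to_dict(orient="records"),
            "model_chi2": self.model_chi2,
            "model_df": self.model_df,
            "model_p": self.model_p,
            "cox_snell_r2": self.cox_snell_r2,
            "nagelkerke_r2": self.nagelkerke_r2,
            "separation_flag": self.separation_flag,
        }


def multinomial_class_prediction(
    design: pd.DataFrame,
    class_labels,
    reference_class=None,
) -> MultinomialFit:
    """Maximum-likelihood multinomial logit of class membership.

    Coefficients are reported per non-reference contrast with Wald
    standard errors, odds ratios exp(B) and 95% CI exp(B +- 1.96 SE).
    Cox & Snell R2 = 1 - exp((2/n)(LL0 - LL1)); Nagelkerke rescales it by
    its attainable maximum.  Apparent perfect separation (diverging
    coefficients) is flagged rather than raised.
    """
    labels = pd.Series(class_labels).reset_index(drop=True)
    cats = list(pd.unique(labels))
    if len(cats) < 2:
        raise ValueError("need at least 2 classes")
    if labels.value_counts().min() == 0:
        raise ValueError("empty class")
    if reference_class is None:
        reference_class = cats[0]
    others = [c for c in cats if c != reference_class]
    codes = labels.map({reference_class: 0, **{c: i + 1 for i, c in enumerate(others)}})

    X = sm.add_constant(design.reset_index(drop=True).astype(float))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    n = len(labels)
    model = sm.MNLogit(codes.to_numpy(), X)
    fit = model.fit(method="newton", disp=0, maxiter=200)
    ll1 = float(fit.llf)
    ll0 = float(fit.llnull)

    separation = bool(np.abs(fit.params.to_numpy()).max() > 50)

    rows = []
    params, bse, pvals = fit.params, fit.bse, fit.pvalues
    for j, cls in enumerate(others):
        for pred in X.columns:
            B = float(params.loc[pred, j])
            se = float(bse.loc[pred, j])
            rows.append(
                {
                    "contrast": f"{reference_class} vs {cls}",
                    "predictor": pred,
                    "B": B,
                    "SE": se,
                    "p": float(pvals.loc[pred, j]),
                    "odds_ratio": float(np.exp(B)),
                    "ci_lower": float(np.exp(B - 1.96 * se)),
                    "ci_upper": float(np.exp(B + 1.96 * se)),
                }
            )
    model_df = (X.shape[1] - 1) * len(others)
    chi2 = 2.0 * (ll1 - ll0)
    cox_snell = 1.0 - np.exp((2.0 / n) * (ll0 - ll1))
    nagelkerke = cox_snell / (1.0 - np.exp((2.0 / n) * ll0))
    return MultinomialFit(
        reference_class=reference_class,
        coefficients=pd.DataFrame(rows),
        model_chi2=float(chi2),
        model_df=model_df,
        model_p=float(stats.chi2.sf(chi2, model_df)) if model_df > 0 else 1.0,
        cox_snell_r2=float(cox_snell),
        nagelkerke_r2=float(nagelkerke),
        log_likelihood=ll1,
        null_log_likelihood=ll0,
        separation_flag=separation,
    )
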