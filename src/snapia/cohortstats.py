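"""Cohort-level statistics on per-subject IA records.

Works on the cohort table schema produced by the pipeline (one row per
subject: subject_id, status, variant, bilobar, areas, tissue means, eticv,
sex, age, group). Ambiguous (kissing) and excluded (discordant) subjects are
dropped from inference with a logged count; presence percentages are over
the included subjects, variant shares over present subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

__all__ = [
    "included_cohort",
    "prevalence_summary",
    "weighted_percentage",
    "chi2_independence",
    "logistic_presence",
    "area_model",
    "rank_compare",
    "normality_screen",
]

logger = logging.getLogger(__name__)

VARIANT_ORDER = ("simple", "broad", "double", "filiform")


def included_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Drop ambiguous/excluded rows (kissing thalami, rater discordance)."""
    keep = cohort["status"].isin(["present", "absent"])
    dropped = int((~keep).sum())
    if dropped:
        logger.info("excluded %d subject(s) from inference (ambiguous/discordant)", dropped)
    return cohort[keep].copy()


def weighted_percentage(ns: np.ndarray, percentages: np.ndarray) -> float:
    """Group-size-weighted mean of per-group percentages."""
    ns = np.asarray(ns, dtype=float)
    percentages = np.asarray(percentages, dtype=float)
    return float((ns * percentages).sum() / ns.sum())


def prevalence_summary(cohort: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Per-group n, % presence, variant shares and mean adjusted area, plus a
    TOTAL row weighted by group size. Bilobar-flagged subjects keep their
    threshold label but are excluded from the variant share denominators."""
    if cohort.empty:
        raise ValueError("empty cohort")
    df = included_cohort(cohort)
    if df.empty:
        raise ValueError("no included subjects")
    by = by or ["group"]

    def one(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        present = g[g["status"] == "present"]
        out = {"n": n, "pct_presence": 100.0 * len(present) / n}
        labeled = present if "bilobar" not in present else present[~present["bilobar"].fillna(False).astype(bool)]
        denom = max(len(labeled), 1)
        for v in VARIANT_ORDER:
            out[f"pct_{v}"] = 100.0 * (labeled["variant"] == v).sum() / denom
        out["mean_area_mm2"] = float(present["mean_adjusted_area_mm2"].mean())
        return pd.Series(out)

    rows = df.groupby(by, sort=True).apply(one, include_groups=False)
    total = {"n": int(rows["n"].sum())}
    for col in rows.columns:
        if col == "n":
            continue
        valid = rows[col].notna()
        total[col] = weighted_percentage(rows.loc[valid, "n"], rows.loc[valid, col])
    rows.loc["TOTAL"] = pd.Series(total)
    return rows


def chi2_independence(
    table: np.ndarray, continuity_correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r×c count table.

    Returns (statistic, degrees of freedom, p). Yates continuity correction
    (2×2 only) is off by default.
    """
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    res = stats.chi2_contingency(table, correction=continuity_correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


@dataclass
class ModelFit:
    params: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    extra: dict

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "conf_int": {k: list(v) for k, v in self.conf_int.iterrows()},
            "pvalues": self.pvalues.to_dict(),
            **self.extra,
        }


def _design(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    for cov in covariates:
        col = df[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.dropna().unique(), key=str)
            for lvl in levels[1:]:  # first level is the reference
                X[f"{cov}[{lvl}]"] = (col == lvl).astype(float)
        else:
            X[cov] = col.astype(float)
    X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design ({rank} < {X.shape[1]}): collinear columns among {list(X.columns)}"
        )
    return X


def logistic_presence(cohort: pd.DataFrame, covariates: list[str]) -> ModelFit:
    """Logistic regression of IA presence on covariates (IRLS via GLM).

    Reports coefficients, odds ratios with Wald CIs, AIC, and flags complete
    separation as an error with advice.
    """
    df = included_cohort(cohort)
    y = (df["status"] == "present").astype(float)
    if y.nunique() < 2:
        raise ValueError(
            "outcome has a single class (complete separation is trivial); "
            "presence regression needs both present and absent subjects"
        )
    X = _design(df, covariates)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        fit = model.fit()
    except Exception as exc:
        raise ValueError(f"logistic fit failed: {exc}") from exc
    fitted = fit.fittedvalues
    if np.max(np.abs(fit.params)) > 15 or fitted.min() < 1e-8 or fitted.max() > 1 - 1e-8:
        raise ValueError(
            "complete or quasi-complete separation detected: a covariate perfectly "
            "predicts presence; consider pooling categories or penalized regression"
        )
    ci = fit.conf_int()
    ci.columns = ["lo", "hi"]
    return ModelFit(
        params=fit.params,
        conf_int=ci,
        pvalues=fit.pvalues,
        extra={
            "odds_ratios": np.exp(fit.params).to_dict(),
            "odds_ratio_ci": {k: [float(np.exp(v["lo"])), float(np.exp(v["hi"]))] for k, v in ci.iterrows()},
            "aic": float(fit.aic),
            "n": int(len(y)),
        },
    )


def _omega_squared(fit, X: pd.DataFrame, y: np.ndarray) -> dict:
    """ω² per predictor from sequential-independent (type-III-like) SS."""
    resid_ss = float(np.sum(fit.resid**2))
    total_ss = float(np.sum((y - y.mean()) ** 2))
    df_resid = float(fit.df_resid)
    if df_resid <= 0:  # saturated model: effect sizes undefined
        return {col: float("nan") for col in X.columns if col != "const"}
    ms_err = resid_ss / df_resid
    omegas = {}
    for col in X.columns:
        if col == "const":
            continue
        X_red = X.drop(columns=[col])
        fit_red = sm.OLS(y, X_red).fit()
        ss_effect = float(np.sum(fit_red.resid**2)) - resid_ss
        omega = (ss_effect - 1 * ms_err) / (total_ss + ms_err)
        omegas[col] = float(max(omega, 0.0))
    return omegas


def area_model(cohort: pd.DataFrame, covariates: list[str]) -> ModelFit:
    """Linear covariance model of PVE-adjusted area on covariates.

    Returns slopes (e.g. mm² per year of age), categorical contrasts
    (e.g. sex), Wald CIs and ω² effect sizes.
    """
    df = included_cohort(cohort)
    df = df[(df["status"] == "present") & df["mean_adjusted_area_mm2"].notna()]
    if df.empty:
        raise ValueError("no present subject with a measured area")
    X = _design(df, covariates)
    y = df["mean_adjusted_area_mm2"].astype(float).values
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int()
    ci.columns = ["lo", "hi"]
    return ModelFit(
        params=fit.params,
        conf_int=ci,
        pvalues=fit.pvalues,
        extra={
            "omega_squared": _omega_squared(fit, X, y),
            "aic": float(fit.aic),
            "r_squared": float(fit.rsquared),
            "n": int(len(y)),
        },
    )


def normality_screen(values: np.ndarray, alpha: float = 0.05) -> bool:
    """Shapiro–Wilk screen: True when normality is not rejected at `alpha`."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        return True
    return bool(stats.shapiro(values).pvalue >= alpha)


def rank_compare(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Mann–Whitney U (two-sided) with tie correction.

    Exact null enumeration for samples of ≤ 8 per group without ties,
    normal approximation otherwise. Returns (U of the first group, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    small = len(a) <= 8 and len(b) <= 8
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
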