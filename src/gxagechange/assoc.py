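"""Per-variant regression layer.

Four ordinary-least-squares models are fitted per variant:

* marginal:     Y ~ 1 + G + AGE_c + C            (effect of G unconditioned
                                                  on the interaction)
* interaction:  Y ~ 1 + G + AGE_c + G*AGE_c + C  (genetic-by-age interaction;
                                                  AGE_c is age centered at
                                                  the analysis-sample mean)
* change:       (Y2-Y1)/(t2-t1) ~ 1 + G + C(baseline)
* G~Age:        AGE ~ 1 + G + C                  (sensitivity test for birth
                                                  cohort / selection /
                                                  survival effects)

The cohorts this package targets are unrelated individuals, so plain OLS with
principal-component covariates identifies the same estimands a mixed model
would; fits use closed-form linear algebra for speed and are cross-checked
against statsmodels in the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankDeficientError",
    "fit_gxage",
    "fit_change",
    "fit_g_age",
    "gwas",
    "genomic_control",
    "age_specific_effects",
    "one_sided_p",
]

# theoretical median of a 1-df chi-square
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))


class RankDeficientError(ValueError):
    """Design matrix is rank deficient (e.g., a monomorphic variant)."""


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Closed-form OLS: coefficients, standard errors, residual df."""
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than parameters ({k})")
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < k:
        raise RankDeficientError("rank-deficient design (constant column?)")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    return beta, se, df

def _wald_p(beta: float, se: float, df: int) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2.0 * stats.t.sf(abs(beta / se), df))


def _covariate_matrix(df: pd.DataFrame, covariates: list[str] | None) -> np.ndarray:
    if not covariates:
        return np.empty((len(df), 0))
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise KeyError(f"covariate columns not found: {missing}")
    return df[covariates].to_numpy(dtype=float)


def fit_gxage(
    df: pd.DataFrame,
    g: np.ndarray,
    covariates: list[str] | None = None,
    age_col: str = "age",
    y_col: str = "y",
    center_age: bool = True,
) -> dict:
    """Marginal and genetic-by-age interaction fits on cross-sectional data.

    The marginal effect comes from the model without the interaction term;
    the interaction model reports both the interaction slope (trait units per
    allele per year) and the genetic main effect at the centering age.
    """
    g = np.asarray(g, dtype=float)
    if len(g) != len(df):
        raise ValueError("dosage vector length must match the phenotype table")
    age = df[age_col].to_numpy(dtype=float)
    if np.unique(age).size < 2:
        raise ValueError("need at least two distinct ages")
    y = df[y_col].to_numpy(dtype=float)
    mean_age = float(age.mean()) if center_age else 0.0
    age_c = age - mean_age
    C = _covariate_matrix(df, covariates)
    ones = np.ones_like(y)

    X_marg = np.column_stack([ones, g, age_c, C])
    b_m, se_m, df_m = _ols(X_marg, y)
    X_int = np.column_stack([ones, g, age_c, g * age_c, C])
    b_i, se_i, df_i = _ols(X_int, y)

    return {
        "n": len(y),
        "eaf": float(g.mean() / 2.0),
        "mean_age": mean_age,
        "beta_marginal": float(b_m[1]),
        "se_marginal": float(se_m[1]),
        "p_marginal": _wald_p(b_m[1], se_m[1], df_m),
        "beta_g_at_mean": float(b_i[1]),
        "se_g_at_mean": float(se_i[1]),
        "beta_age": float(b_i[2]),
        "beta_gxage": float(b_i[3]),
        "se_gxage": float(se_i[3]),
        "p_gxage": _wald_p(b_i[3], se_i[3], df_i),
    }


def one_sided_p(p_two_sided: float, estimate_sign: float, ref_sign: float) -> float:
    """One-sided p in the direction ``ref_sign``; p/2 when direction-consistent."""
    if ref_sign == 0:
        return p_two_sided
    if np.sign(estimate_sign) == np.sign(ref_sign):
        return p_two_sided / 2.0
    return 1.0 - p_two_sided / 2.0


def fit_change(
    long_df: pd.DataFrame,
    g: np.ndarray,
    covariates: list[str] | None = None,
    change_col: str = "annual_change",
    ref_sign: float = 0.0,
) -> dict:
    """Annual-change association in the longitudinal subset.

    The outcome is per-person annual change; covariates are taken at
    baseline. ``ref_sign`` sets the alternative's direction for the one-sided
    p value (typically the sign of the interaction effect being validated).
    """
    g = np.asarray(g, dtype=float)
    if long_df.empty:
        raise ValueError("no longitudinal subset: no individual has two visits")
    if len(g) != len(long_df):
        raise ValueError("dosage vector length must match the longitudinal table")
    y = long_df[change_col].to_numpy(dtype=float)
    C = _covariate_matrix(long_df, covariates)
    X = np.column_stack([np.ones_like(y), g, C])
    b, se, df = _ols(X, y)
    p2 = _wald_p(b[1], se[1], df)
    return {
        "n": len(y),
        "eaf": float(g.mean() / 2.0),
        "beta_change": float(b[1]),
        "se_change": float(se[1]),
        "p_change": p2,
        "p_change_1sided": one_sided_p(p2, b[1], ref_sign),
    }


def fit_g_age(
    df: pd.DataFrame,
    g: np.ndarray,
    covariates: list[str] | None = None,
    age_col: str = "age",
) -> dict:
    """Variant association with age itself (birth cohort/selection/survival)."""
    g = np.asarray(g, dtype=float)
    age = df[age_col].to_numpy(dtype=float)
    C = _covariate_matrix(df, covariates)
    X = np.column_stack([np.ones_like(age), g, C])
    b, se, dof = _ols(X, age)
    return {
        "n": len(age),
        "beta_g_age": float(b[1]),
        "se_g_age": float(se[1]),
        "p_g_age": _wald_p(b[1], se[1], dof),
    }


def gwas(
    df: pd.DataFrame,
    genotypes: np.ndarray,
    variants: pd.DataFrame,
    model: str = "gxage",
    covariates: list[str] | None = None,
    long_df: pd.DataFrame | None = None,
    maf_min: float = 1e-4,
) -> pd.DataFrame:
    """Per-variant summary statistics over a dosage matrix.

    ``model="gxage"`` fits the marginal and interaction models on ``df``;
    ``model="change"`` fits the annual-change model on ``df`` (which must
    carry an ``annual_change`` column). Variants below the minor-allele
    frequency floor, or yielding a rank-deficient design, are skipped with a
    ``skip_reason`` row retained for provenance.
    """
    rows = []
    for j, var in enumerate(variants.itertuples(index=False)):
        g = genotypes[:, j]
        eaf = float(np.nanmean(g) / 2.0)
        if np.isnan(g).any():  # mean-impute missing dosages per variant
            g = np.where(np.isnan(g), 2 * eaf, g)
        base = {
            "variant": var.variant,
            "chrom": str(var.chrom),
            "pos": int(var.pos),
            "ea": var.ea,
            "oa": var.oa,
            "eaf": eaf,
        }
        if min(eaf, 1 - eaf) < maf_min:
            rows.append({**base, "skip_reason": "maf_below_floor"})
            continue
        try:
            if model == "gxage":
                rec = fit_gxage(df, g, covariates=covariates)
            elif model == "change":
                rec = fit_change(df, g, covariates=covariates)
            else:
                raise ValueError(f"unknown model {model!r}")
        except RankDeficientError:
            rows.append({**base, "skip_reason": "rank_deficient"})
            continue
        rec.pop("eaf", None)
        rows.append({**base, "skip_reason": None, **rec})
    return pd.DataFrame(rows)


def genomic_control(
    records: pd.DataFrame,
    beta_col: str,
    se_col: str,
    p_col: str,
    sig_marginal_p: str = "p_marginal",
    alpha_gws: float = 5e-8,
    null_distance: float = 5e6,
) -> tuple[pd.DataFrame, float]:
    """Genomic-control correction of one model's test statistics.

    The inflation factor lambda is the median 1-df chi-square of "null"
    variants — those farther than ``null_distance`` from every genome-wide
    significant marginally associated variant — divided by the theoretical
    median (chi-square 0.455 quantile). Statistics are deflated only when
    lambda exceeds 1 (standard GWAS convention); corrected p values replace
    ``p_col`` and the raw values are kept in ``<p_col>_raw``.
    """
    out = records.copy()
    chi2 = (out[beta_col] / out[se_col]) ** 2
    sig = out[sig_marginal_p] < alpha_gws if sig_marginal_p in out else pd.Series(False, index=out.index)
    null_mask = pd.Series(True, index=out.index)
    for chrom, sub in out[sig].groupby("chrom"):
        same = out["chrom"] == chrom
        pos = out.loc[same, "pos"].to_numpy()
        near = np.zeros(len(pos), dtype=bool)
        for sp in sub["pos"].to_numpy():
            near |= np.abs(pos - sp) <= null_distance
        null_mask.loc[same] &= ~near
    null_chi2 = chi2[null_mask].dropna()
    if null_chi2.empty:
        lam = 1.0
    else:
        lam = float(np.median(null_chi2) / CHI2_MEDIAN_1DF)
    correction = max(lam, 1.0)
    out[p_col + "_raw"] = out[p_col]
    if correction > 1.0:
        out[p_col] = stats.chi2.sf(chi2 / correction, df=1)
        out[se_col] = out[se_col] * np.sqrt(correction)
    return out, lam


def age_specific_effects(
    beta_g_at_mean: float,
    beta_gxage: float,
    mean_age: float,
    ages: tuple[float, ...] = (40.0, 55.0, 70.0),
) -> dict[float, float]:
    """Project the interaction model to per-age genetic effects.

    ``effect(age) = beta_g_at_mean + beta_gxage * (age - mean_age)``.
    """
    return {a: beta_g_at_mean + beta_gxage * (a - mean_age) for a in ages}
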