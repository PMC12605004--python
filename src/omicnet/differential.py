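"""Covariate-adjusted per-feature association testing with effect-size gating.

Each omic feature is regressed on a study-group indicator plus confounders
(sex, age, BMI, smoking history, prednisone, bDMARD and csDMARD use) by
ordinary least squares; the group coefficient's two-sided t-test p-value is
paired with an unadjusted Cohen's d between the two raw groups. A feature is
called differentially abundant when p < 0.01 and |d| > 0.5 (strict), or
p < 0.05 and |d| > 0.5 (relaxed, used to feed pathway analysis). Samples with
unknown smoking history are excluded from adjusted models. No multiple-testing
correction gates the calls; Benjamini–Hochberg q-values are reported alongside
for transparency.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import MED_FLAGS, OmicsMatrix, SampleMetadata, SmokingMode, encode_design

COMPARISONS = {
    "ACPA_NEG_vs_CTRL": ("ACPA_NEG", "CONTROL"),
    "ACPA_POS_vs_CTRL": ("ACPA_POS", "CONTROL"),
}

DEFAULT_COVARIATES = ("sex", "age", "bmi", "smoking", "meds")


def cohens_d(a, b) -> float:
    """Standardized mean difference (pooled-SD convention).

    d = (mean(a) - mean(b)) / s_p with
    s_p = sqrt(((n_a-1)s_a^2 + (n_b-1)s_b^2) / (n_a+n_b-2)).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("degenerate feature: pooled SD is zero")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def _check_rank(X: np.ndarray, columns) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # name the offending columns: those nearly reproduced by the others
    collinear = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        coef, res, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        pred = others @ coef
        ss = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        if ss == 0 or np.sum((X[:, j] - pred) ** 2) < 1e-10 * max(ss, 1.0):
            collinear.append(str(columns[j]))
    raise ValueError(f"rank-deficient design; collinear columns: {collinear}")


def _ols_t_tests(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of every column of Y on the shared design X.

    Returns (beta, se, p) arrays of shape (k_features, k_coeffs). Vectorized:
    the pseudo-inverse and (X'X)^-1 diagonal are computed once.
    """
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = Y.T @ (X @ XtX_inv.T)  # (features, k)
    resid = Y - X @ beta.T
    dof = n - k
    if dof <= 0:
        raise ValueError("not enough samples for the requested design")
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.outer(sigma2, np.diag(XtX_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    return beta, se, p


def fit_adjusted_lm(
    y, design: pd.DataFrame, phenotype_column: str
) -> tuple[float, float]:
    """OLS fit of one feature on the design; returns the phenotype
    coefficient and its two-sided t-test p-value."""
    if phenotype_column not in design.columns:
        raise ValueError(f"phenotype column {phenotype_column!r} not in design")
    X = design.to_numpy(dtype=float)
    _check_rank(X, design.columns)
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    beta, _, p = _ols_t_tests(X, y)
    j = list(design.columns).index(phenotype_column)
    return float(beta[0, j]), float(p[0, j])


def _drop_constant_columns(design: pd.DataFrame) -> pd.DataFrame:
    keep = [c for c in design.columns
            if c == "const" or design[c].nunique() > 1]
    return design[keep]


def differential_features(
    data: OmicsMatrix,
    meta: SampleMetadata,
    comparison: str,
    p_thr: float = 0.01,
    d_thr: float = 0.5,
    relaxed_p_thr: float = 0.05,
    covariates=DEFAULT_COVARIATES,
    adjusted_d: bool = False,
) -> pd.DataFrame:
    """Adjusted association test for every feature in one group comparison.

    Returns one row per feature with the phenotype coefficient, its p-value,
    unadjusted Cohen's d (positive = higher in the RA subgroup), the strict
    and relaxed calls, and a BH q-value column. Covariate columns that are
    constant in the analyzed subset (e.g. medication flags in a
    treatment-naïve rerun) are dropped automatically.
    """
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    ra_group, ctrl_group = COMPARISONS[comparison]
    sub = meta.frame[meta.frame["group"].isin([ra_group, ctrl_group])]
    sub_meta = SampleMetadata(sub)

    design = encode_design(sub_meta, include=set(covariates),
                           smoking_mode=SmokingMode.DROP_UNKNOWN)
    pheno_col = f"group_{ra_group}"
    kept = design.index
    design[pheno_col] = (sub.loc[kept, "group"] == ra_group).astype(float)
    design = _drop_constant_columns(design)

    counts = sub.loc[kept, "group"].value_counts()
    if counts.get(ra_group, 0) < 3 or counts.get(ctrl_group, 0) < 3:
        raise ValueError(
            f"fewer than 3 samples per group after exclusions: {counts.to_dict()}"
        )

    X = design.to_numpy(dtype=float)
    _check_rank(X, design.columns)
    Y = data.values.loc[kept].to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("abundance matrix contains missing values; impute first")
    beta, _, pvals = _ols_t_tests(X, Y)
    j = list(design.columns).index(pheno_col)
    beta_ph, p_ph = beta[:, j], pvals[:, j]

    # effect size on the raw (possibly log-transformed) group values
    if adjusted_d:
        # residualize on the non-phenotype covariates first
        X_cov = np.delete(X, j, axis=1)
        H = X_cov @ np.linalg.pinv(X_cov)
        vals = Y - H @ Y
        grp = sub.loc[kept, "group"].to_numpy()
        a_rows, b_rows = grp == ra_group, grp == ctrl_group
    else:
        in_a = meta.frame["group"] == ra_group
        in_b = meta.frame["group"] == ctrl_group
        vals = data.values.to_numpy(dtype=float)
        a_rows, b_rows = in_a.to_numpy(), in_b.to_numpy()
    d = np.array([cohens_d(vals[a_rows, f], vals[b_rows, f])
                  for f in range(vals.shape[1])])

    q = _bh_qvalues(p_ph)
    strict = (p_ph < p_thr) & (np.abs(d) > d_thr)
    relaxed = (p_ph < relaxed_p_thr) & (np.abs(d) > d_thr)
    return pd.DataFrame({
        "feature_id": data.feature_ids,
        "comparison": comparison,
        "beta": beta_ph,
        "p": p_ph,
        "q": q,
        "d": d,
        "direction": np.where(d >= 0, "up", "down"),
        "passes_strict": strict,
        "passes_relaxed": relaxed,
        "n_used": len(kept),
    })


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def subset_treatment_naive(meta: SampleMetadata) -> list[str]:
    """Sample IDs with no MTX, prednisone, bDMARD or csDMARD exposure.

    Controls carry all-false flags, so they are always included.
    """
    f = meta.frame
    naive = ~f[list(MED_FLAGS)].any(axis=1)
    return list(f.index[naive])
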