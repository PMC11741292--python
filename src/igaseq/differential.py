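"""Per-ASV differential abundance and prevalence between study groups.

Abundance contrasts operate on the centred log-ratio (clr) scale: relative
abundances have zeros replaced by a small pseudocount (1.2e-5; values that
are genuinely non-zero are never touched) and each sample is mapped to
``clr_i = ln x_i - mean_j ln x_j``, removing the unit-sum constraint of
compositional data. Cross-sectional contrasts fit an ordinary least-squares
model per ASV, adjusted for age, sex, BMI and steroid use, and test the
group coefficient two-sided. Paired (baseline vs month-6) contrasts use a
subject-level random-intercept formulation which, for complete balanced
pairs, is fitted exactly through its conditional form: ordinary regression
of within-subject differences on centred between-subject covariates, so the
no-covariate case reproduces the classical paired t-test exactly.

Prevalence contrasts are two-sided Fisher exact tests on the 2x2 detection
table, and all per-family p-values may be converted to Benjamini-Hochberg
q-values. Display fold changes are reported as the log2 ratio of arithmetic
mean relative abundances — a descriptive quantity distinct from the tested
clr coefficient.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

CLR_PSEUDOCOUNT = 1.2e-5

DEFAULT_COVARIATES = ("age", "sex", "bmi", "steroid")


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Coefficient of interest from a per-ASV regression."""

    estimate: float
    std_error: float
    statistic: float
    p_value: float
    df_resid: float
    n: int


@dataclasses.dataclass(frozen=True)
class PrevalenceContrast:
    """2x2 detection table and its exact test."""

    table: np.ndarray  # rows: detected / undetected; cols: group1 / group0
    odds_ratio: float
    p_value: float


def clr_transform(ra: pd.DataFrame, pseudocount: float = CLR_PSEUDOCOUNT) -> pd.DataFrame:
    """Centred log-ratio transform per sample (column).

    Zeros are replaced by ``pseudocount`` before taking logs; non-zero
    values, including any smaller than the pseudocount, are left untouched.
    Each output column sums to zero.
    """
    if not pseudocount > 0:
        raise ValueError("pseudocount must be > 0")
    vals = ra.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("relative abundances must be non-negative")
    x = np.where(vals == 0.0, pseudocount, vals)
    logs = np.log(x)
    clr = logs - logs.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=ra.index, columns=ra.columns)


def _design_matrix(meta: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric covariate columns: sex -> male indicator, steroid -> 0/1."""
    cols = {}
    for cov in covariates:
        if cov == "sex":
            cols["sex_male"] = (meta["sex"] == "male").astype(float)
        elif cov == "steroid":
            cols["steroid"] = meta["steroid"].astype(float)
        else:
            cols[cov] = meta[cov].astype(float)
    return pd.DataFrame(cols, index=meta.index)


def _check_full_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the columns implicated in the deficiency via QR pivoting
        _, r = np.linalg.qr(X.to_numpy())
        small = np.abs(np.diag(r)) < 1e-10 * max(1.0, np.abs(np.diag(r)).max())
        bad = [c for c, flag in zip(X.columns, small) if flag] or list(X.columns)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _ols_coefficient(y: np.ndarray, X: pd.DataFrame, term: str) -> FitResult:
    if len(y) <= X.shape[1]:
        raise ValueError(
            f"need more observations ({len(y)}) than model terms ({X.shape[1]})"
        )
    _check_full_rank(X)
    if np.ptp(y) == 0.0:
        # degenerate constant response: no information about any effect
        return FitResult(0.0, float("nan"), float("nan"), float("nan"),
                         len(y) - X.shape[1], len(y))
    fit = sm.OLS(y, X).fit()
    i = list(X.columns).index(term)
    return FitResult(
        estimate=float(fit.params.iloc[i]),
        std_error=float(fit.bse.iloc[i]),
        statistic=float(fit.tvalues.iloc[i]),
        p_value=float(fit.pvalues.iloc[i]),
        df_resid=float(fit.df_resid),
        n=len(y),
    )


def fit_group_model(
    y: pd.Series,
    meta: pd.DataFrame,
    contrast: tuple[str, str] = ("ms_baseline", "control"),
    covariates=DEFAULT_COVARIATES,
) -> FitResult:
    """OLS of a per-sample response on group, adjusted for covariates.

    ``y`` is indexed by sample_id (e.g. one ASV's clr values). The group
    coefficient contrasts ``contrast[0]`` against reference ``contrast[1]``;
    its two-sided t-test uses residual degrees of freedom.
    """
    keep = meta.index[meta["group"].isin(contrast)].intersection(y.index)
    sub = meta.loc[keep]
    X = _design_matrix(sub, covariates)
    X.insert(0, "group", (sub["group"] == contrast[0]).astype(float))
    X.insert(0, "const", 1.0)
    if sub["group"].nunique() < 2:
        raise ValueError(f"contrast {contrast} needs samples from both groups")
    return _ols_coefficient(y.loc[keep].to_numpy(dtype=float), X, "group")


def fit_paired_model(
    y_baseline: pd.Series,
    y_month6: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> FitResult:
    """Timepoint effect from paired per-subject responses.

    Both series are indexed by subject; only complete pairs are used and at
    least 3 are required. Fits the random-intercept-per-subject model through
    its conditional form — OLS of the within-subject differences
    ``d_i = y6_i - y0_i`` on an intercept plus mean-centred between-subject
    covariates — so with no covariates the estimate is the mean difference
    and the p-value equals the paired t-test exactly.
    """
    subjects = y_baseline.index.intersection(y_month6.index)
    subjects = subjects[
        ~(y_baseline[subjects].isna() | y_month6[subjects].isna())
    ]
    if len(subjects) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(subjects)}")
    d = (y_month6[subjects] - y_baseline[subjects]).to_numpy(dtype=float)
    X = pd.DataFrame({"timepoint": np.ones(len(subjects))}, index=subjects)
    if covariates is not None and covariates.shape[1] > 0:
        Z = covariates.loc[subjects].astype(float)
        X = pd.concat([X, Z - Z.mean(axis=0)], axis=1)
    return _ols_coefficient(d, X, "timepoint")


def prevalence_contrast(
    detected: tuple[int, int], totals: tuple[int, int]
) -> PrevalenceContrast:
    """Two-sided Fisher exact test on a 2x2 detection-by-group table.

    ``detected[k]`` strains detected out of ``totals[k]`` samples in group k.
    The p-value sums hypergeometric probabilities no larger than the observed
    table's.
    """
    d = np.asarray(detected, dtype=int)
    t = np.asarray(totals, dtype=int)
    if (d < 0).any() or (t < 0).any() or (d > t).any():
        raise ValueError("need 0 <= detected <= total in each group")
    table = np.array([[d[0], d[1]], [t[0] - d[0], t[1] - d[1]]])
    odds, p = scipy.stats.fisher_exact(table, alternative="two-sided")
    return PrevalenceContrast(table=table, odds_ratio=float(odds), p_value=float(p))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def display_fold_change(
    ra: pd.DataFrame, samples1, samples0, pseudocount: float = CLR_PSEUDOCOUNT
) -> pd.Series:
    """log2 ratio of arithmetic mean relative abundances (group1 / group0).

    A descriptive effect size for plots and tables; the pseudocount guards
    the ratio when a mean is exactly zero.
    """
    m1 = ra[list(samples1)].mean(axis=1)
    m0 = ra[list(samples0)].mean(axis=1)
    return np.log2((m1 + pseudocount) / (m0 + pseudocount))


def compare_flow_proportions(
    flow: pd.DataFrame,
    value: str = "pct_iga_coated",
    contrast: tuple[str, str] = ("ms_baseline", "control"),
    covariates: pd.DataFrame | None = None,
) -> FitResult:
    """Adjusted group contrast of a per-subject flow/ELISA scalar.

    ``flow`` has one row per subject-timepoint with ``subject_id``, ``group``
    and the scalar columns; ``covariates`` (optional) is indexed by
    subject_id with numeric columns to adjust for.
    """
    sub = flow[flow["group"].isin(contrast)].set_index("subject_id")
    if sub["group"].nunique() < 2:
        raise ValueError(f"contrast {contrast} needs subjects from both groups")
    X = pd.DataFrame(index=sub.index)
    X["const"] = 1.0
    X["group"] = (sub["group"] == contrast[0]).astype(float)
    if covariates is not None and covariates.shape[1] > 0:
        X = pd.concat([X, covariates.loc[sub.index].astype(float)], axis=1)
    return _ols_coefficient(sub[value].to_numpy(dtype=float), X, "group")
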