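"""Community-level diversity and composition tests.

Alpha diversity is the Shannon index on relative abundances (natural log).
Beta diversity is the Bray-Curtis dissimilarity computed on arcsine
square-root transformed relative abundances — the variance-stabilising
transform for proportions — and group effects on the resulting distance
matrix are tested with a covariate-adjusted PERMANOVA: sums of squares of
the Gower-centred distance matrix are partitioned sequentially, covariates
entered before the study-group term, and the group pseudo-F is referred to
its permutation distribution under unrestricted row permutation.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from .differential import _design_matrix

PERM_TIE_TOL = 1e-12


def shannon_index(p) -> float:
    """Shannon diversity H = -sum p_i ln p_i over positive proportions."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"proportions must sum to 1, got {total}")
    pos = p[p > 0]
    return float(-(pos * np.log(pos)).sum())


def shannon_per_sample(ra: pd.DataFrame) -> pd.Series:
    """Shannon index for each sample column of a relative-abundance matrix."""
    return pd.Series(
        {s: shannon_index(ra[s].to_numpy()) for s in ra.columns}, name="shannon"
    )


def arcsine_sqrt(ra: pd.DataFrame) -> pd.DataFrame:
    """Variance-stabilising transform arcsin(sqrt(p)) for proportions."""
    vals = ra.to_numpy(dtype=float)
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("relative abundances must lie in [0, 1]")
    return pd.DataFrame(np.arcsin(np.sqrt(vals)), index=ra.index, columns=ra.columns)


def bray_curtis_matrix(ra: pd.DataFrame, transform: str = "arcsine_sqrt") -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples.

    ``transform="arcsine_sqrt"`` (default) applies arcsin(sqrt(p)) per entry
    first; ``transform="none"`` uses the proportions as-is. A pair of
    all-zero samples has no defined dissimilarity and raises an error naming
    the pair.
    """
    if transform == "arcsine_sqrt":
        mat = arcsine_sqrt(ra)
    elif transform == "none":
        mat = ra
    else:
        raise ValueError(f"unknown transform {transform!r}")
    X = mat.to_numpy(dtype=float).T  # samples in rows
    zero = X.sum(axis=1) == 0.0
    if zero.sum() >= 2:
        pair = list(np.asarray(mat.columns)[zero][:2])
        raise ValueError(f"all-zero sample pair has undefined distance: {pair}")
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(d, ids=list(map(str, mat.columns)))


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(X: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(X)
    return q @ q.T


def permanova(
    dm: DistanceMatrix,
    meta: pd.DataFrame,
    covariates=("age", "sex", "bmi", "steroid"),
    group_col: str = "group",
    n_permutations: int = 999,
    seed=None,
) -> pd.DataFrame:
    """Covariate-adjusted PERMANOVA of a distance matrix.

    Sequential (order-of-entry) partition of the Gower-centred matrix:
    covariate terms first, the group term last, then the residual. The
    pseudo-F of the group term is tested against ``n_permutations``
    unrestricted permutations of the distance-matrix rows, with
    p = (b + 1) / (B + 1).

    Returns a frame with one row per term plus ``Residual`` and ``Total``,
    and columns ``df``, ``SS``, ``R2``, ``F``, ``p_value``; permutation p is
    reported for the group term only.
    """
    ids = list(dm.ids)
    missing = [s for s in ids if s not in meta.index]
    if missing:
        raise ValueError(f"distance matrix samples missing from metadata: {missing}")
    sub = meta.loc[ids]
    if sub[group_col].nunique() < 2:
        raise ValueError(f"group column {group_col!r} is constant")
    cov_X = _design_matrix(sub, covariates) if covariates else pd.DataFrame(index=sub.index)
    if cov_X.isna().any().any():
        bad = cov_X.columns[cov_X.isna().any()].tolist()
        raise ValueError(f"missing covariate values in: {bad}")
    groups = pd.get_dummies(sub[group_col], drop_first=True).astype(float)

    n = len(ids)
    g = _gower_center(np.asarray(dm.data, dtype=float))
    ss_total = float(np.trace(g))

    # cumulative hat matrices: intercept, +each covariate, +group
    terms = [(name, cov_X[[name]].to_numpy()) for name in cov_X.columns]
    terms.append((group_col, groups.to_numpy()))
    X = np.ones((n, 1))
    hats = [_hat(X)]
    dfs = []
    for _, cols in terms:
        X = np.hstack([X, cols])
        hats.append(_hat(X))
        dfs.append(cols.shape[1])
    df_resid = n - X.shape[1]
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    def partition(gmat):
        tr = [float((h * gmat).sum()) for h in hats]
        ss = np.diff(tr)
        ss_res = float(np.trace(gmat)) - tr[-1]
        return ss, ss_res

    ss_terms, ss_res = partition(g)
    ss_group = ss_terms[-1]
    f_group = (ss_group / dfs[-1]) / (ss_res / df_resid) if ss_res > 0 else np.inf

    if seed is None:
        raise ValueError("permanova requires a seed for its permutations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ssp, ssp_res = partition(gp)
        fp = (ssp[-1] / dfs[-1]) / (ssp_res / df_resid) if ssp_res > 0 else np.inf
        if fp >= f_group - PERM_TIE_TOL:
            b += 1
    p = (b + 1) / (n_permutations + 1)

    rows = []
    for (name, _), df_k, ss_k in zip(terms, dfs, ss_terms):
        rows.append(
            {
                "term": name,
                "df": df_k,
                "SS": ss_k,
                "R2": ss_k / ss_total,
                "F": f_group if name == group_col else np.nan,
                "p_value": p if name == group_col else np.nan,
                "n_permutations": n_permutations if name == group_col else np.nan,
            }
        )
    rows.append(
        {"term": "Residual", "df": df_resid, "SS": ss_res, "R2": ss_res / ss_total,
         "F": np.nan, "p_value": np.nan, "n_permutations": np.nan}
    )
    rows.append(
        {"term": "Total", "df": n - 1, "SS": ss_total, "R2": 1.0,
         "F": np.nan, "p_value": np.nan, "n_permutations": np.nan}
    )
    return pd.DataFrame(rows)
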