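"""Prevalence-based immune coating score with permutation inference.

The immune coating score (ICS) of a strain-level ASV within a study group is

    ICS = log2( (p_plus + c) / (p_minus + c) )

where ``p_plus`` and ``p_minus`` are the strain's prevalences (proportion of
subjects in whom it is detected) in the IgA-coated and IgA-uncoated sorted
fractions, and ``c`` is a small pseudocount (default 1.0e-5) guarding against
division by zero. Positive scores mark strains preferentially bound by host
IgA; prevalence rather than mean relative abundance is used because presence/
absence is robust to the sparsity and compositional distortion of amplicon
data.

Inference is a class-label permutation test: under the null of no coating
preference a subject's (IgA+, IgA-) detection pair is exchangeable, so the
null distribution is generated by independently swapping each subject's pair
with probability 1/2. The test is one-sided for positive coating by default;
strains whose score is negative are never flagged significant. For small
numbers of subjects all 2^n swap patterns are enumerated exactly; otherwise
a seeded Monte-Carlo sample of patterns is used with the add-one-permutation
correction p = (b + 1) / (B + 1).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .differential import bh_adjust
from .profiles import FilterPolicy
from .synthetic import substream

logger = logging.getLogger(__name__)

#: tie tolerance when comparing permuted scores with the observed score
TIE_TOL = 1e-12

#: exhaustive enumeration is auto-selected when 2**n_subjects <= this
MAX_EXHAUSTIVE_PATTERNS = 4096


def compute_ics(p_plus, p_minus, c: float = 1.0e-5):
    """log2 ratio of pseudocount-shifted prevalences (vectorised).

    Antisymmetric in its two prevalence arguments, strictly increasing in
    ``p_plus`` and strictly decreasing in ``p_minus``; zero iff the two
    prevalences are equal.
    """
    if not c > 0:
        raise ValueError(f"pseudocount c must be > 0, got {c}")
    p_plus = np.asarray(p_plus, dtype=float)
    p_minus = np.asarray(p_minus, dtype=float)
    if ((p_plus < 0) | (p_plus > 1)).any() or ((p_minus < 0) | (p_minus > 1)).any():
        raise ValueError("prevalences must lie in [0, 1]")
    out = np.log2((p_plus + c) / (p_minus + c))
    return float(out) if out.ndim == 0 else out


def _swap_patterns_exhaustive(n: int) -> np.ndarray:
    """All 2**n boolean swap patterns, one row per pattern."""
    idx = np.arange(2**n, dtype=np.uint32)
    return (idx[:, None] >> np.arange(n)[None, :]) & 1 == 1


def _permuted_ics(det_plus, det_minus, swaps, c):
    """ICS under each swap pattern (rows of ``swaps``)."""
    plus = np.where(swaps, det_minus[None, :], det_plus[None, :])
    minus = np.where(swaps, det_plus[None, :], det_minus[None, :])
    return compute_ics(plus.mean(axis=1), minus.mean(axis=1), c)


def ics_permutation_test(
    det_plus,
    det_minus,
    c: float = 1.0e-5,
    n_permutations: int = 999,
    seed=None,
    mode: str = "auto",
    alternative: str = "greater",
) -> float:
    """Permutation p-value for a single strain's coating score.

    Parameters
    ----------
    det_plus, det_minus:
        Boolean detection indicators per subject in the IgA+ and IgA-
        fraction; element ``i`` of each refers to the same subject.
    mode:
        ``"exhaustive"`` enumerates all 2**n swap patterns; ``"monte_carlo"``
        samples ``n_permutations`` patterns (seed required); ``"auto"``
        enumerates when 2**n <= 4096 and samples otherwise.
    alternative:
        ``"greater"`` (positive coating, the default) or ``"two-sided"``.
    """
    det_plus = np.asarray(det_plus, dtype=float)
    det_minus = np.asarray(det_minus, dtype=float)
    if det_plus.shape != det_minus.shape or det_plus.ndim != 1:
        raise ValueError("detection vectors must be 1-D and equally long")
    n = det_plus.size
    if n < 2:
        raise ValueError(f"need >= 2 paired subjects, got {n}")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if mode not in ("auto", "exhaustive", "monte_carlo"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = "exhaustive" if 2**n <= MAX_EXHAUSTIVE_PATTERNS else "monte_carlo"

    observed = compute_ics(det_plus.mean(), det_minus.mean(), c)

    def tail(perm):
        if alternative == "greater":
            return perm >= observed - TIE_TOL
        return np.abs(perm) >= abs(observed) - TIE_TOL

    if mode == "exhaustive":
        perm = _permuted_ics(det_plus, det_minus, _swap_patterns_exhaustive(n), c)
        return float(tail(perm).mean())
    if n_permutations < 99:
        raise ValueError("monte_carlo requires n_permutations >= 99")
    if seed is None:
        raise ValueError("monte_carlo mode requires a seed")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    swaps = rng.random((n_permutations, n)) < 0.5
    perm = _permuted_ics(det_plus, det_minus, swaps, c)
    b = int(tail(perm).sum())
    return (b + 1) / (n_permutations + 1)


def paired_detection(
    ra: pd.DataFrame,
    meta: pd.DataFrame,
    group: str,
    detection_threshold: float = 1.0e-5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject detection indicators in the two sorted fractions.

    Returns two boolean frames (ASV x subject) for the IgA+ and IgA-
    fractions, restricted to subjects of ``group`` with both fraction samples
    present in ``ra``. Subjects missing a fraction are dropped with a logged
    count; if none remain an error is raised.
    """
    sub = meta[(meta["group"] == group) & meta.index.isin(ra.columns)]
    plus = sub[sub["fraction"] == "iga_pos"].set_index("subject_id")["sample_id"]
    minus = sub[sub["fraction"] == "iga_neg"].set_index("subject_id")["sample_id"]
    subjects = plus.index.intersection(minus.index)
    n_total = len(plus.index.union(minus.index))
    if len(subjects) < n_total:
        logger.info(
            "group %s: dropped %d subject(s) missing one sorted fraction",
            group,
            n_total - len(subjects),
        )
    if len(subjects) == 0:
        raise ValueError(f"group {group!r} has no subjects with both IgA+/IgA- samples")
    det_plus = ra[plus[subjects]] > detection_threshold
    det_plus.columns = subjects
    det_minus = ra[minus[subjects]] > detection_threshold
    det_minus.columns = subjects
    return det_plus, det_minus


def ics_table(
    ra: pd.DataFrame,
    meta: pd.DataFrame,
    group: str,
    policy: FilterPolicy | None = None,
    c: float = 1.0e-5,
    n_permutations: int = 999,
    seed=None,
    alpha: float = 0.05,
    mode: str = "auto",
) -> pd.DataFrame:
    """Coating scores and permutation inference for every ASV in one group.

    ``ra`` should already be restricted to analysis ASVs (prevalence filter
    over all study samples). Returns one row per ASV with columns ``asv_id``,
    ``group``, ``p_plus``, ``p_minus``, ``ics``, ``p_value``, ``q_value``
    (Benjamini-Hochberg across the group's ASVs) and ``significant``
    (one-sided p < ``alpha`` AND a strictly positive score — strains with
    negative scores are never flagged).
    """
    policy = policy or FilterPolicy()
    det_plus, det_minus = paired_detection(
        ra, meta, group, policy.detection_threshold
    )
    n = det_plus.shape[1]
    use_exhaustive = mode == "exhaustive" or (
        mode == "auto" and 2**n <= MAX_EXHAUSTIVE_PATTERNS
    )
    rng = None
    if not use_exhaustive:
        if seed is None:
            raise ValueError("Monte-Carlo permutations require a seed")
        rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "ics")

    rows = []
    for asv in ra.index:
        dp = det_plus.loc[asv].to_numpy(dtype=float)
        dm = det_minus.loc[asv].to_numpy(dtype=float)
        score = compute_ics(dp.mean(), dm.mean(), c)
        p = ics_permutation_test(
            dp,
            dm,
            c=c,
            n_permutations=n_permutations,
            seed=rng,
            mode="exhaustive" if use_exhaustive else "monte_carlo",
        )
        rows.append((asv, group, dp.mean(), dm.mean(), score, p))
    out = pd.DataFrame(
        rows, columns=["asv_id", "group", "p_plus", "p_minus", "ics", "p_value"]
    )
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = (out["p_value"] < alpha) & (out["ics"] > 0)
    return out
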