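"""Multi-fraction ASV count tables: validation, relative abundance, detection, prevalence.

IgA-seq cohorts sequence three bacterial fractions per stool sample — the
total community (presort), the IgA-coated sort (iga_pos) and the IgA-uncoated
sort (iga_neg) — and summarise each as a strain-level ASV count table. This
module holds the data model for those tables and the bookkeeping every
downstream statistic relies on:

* relative abundance (per-sample closure of the counts),
* detection (relative abundance strictly above a small threshold),
* prevalence (fraction of samples in a stratum where a strain is detected),
* the standard quality filters: a minimum per-sample sequencing depth and a
  minimum prevalence for a strain to enter an analysis.

Filter conventions
------------------
``min_sample_depth`` is exclusive ("exceeding 2,474" reads): a sample is kept
when its total count is strictly greater than the threshold.
``detection_threshold`` is exclusive: a strain is present in a sample when its
relative abundance is strictly above 1.0e-5. ``min_prevalence`` is inclusive
("at least 10%"). Prevalence may be assessed over all study samples (used for
coating scores) or within each bacterial fraction separately (used for
differential abundance); ``FilterPolicy.prevalence_scope`` selects which.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("control", "ms_baseline", "ms_6mo")
FRACTIONS = ("presort", "iga_pos", "iga_neg")
TIMEPOINTS = ("baseline", "month6")
SEXES = ("female", "male")
STEROID_LEVELS = ("none", "within_1mo", "within_2_3mo")

#: required columns of a sample metadata table, in canonical order
METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "group",
    "fraction",
    "timepoint",
    "age",
    "sex",
    "bmi",
    "steroid_use",
)


@dataclasses.dataclass(frozen=True)
class FilterPolicy:
    """Thresholds governing sample and strain inclusion.

    Parameters
    ----------
    min_sample_depth:
        Total-count threshold; samples with depth strictly greater are kept.
    detection_threshold:
        Relative abundance a strain must strictly exceed to count as present.
    min_prevalence:
        Minimum (inclusive) fraction of samples in which a strain must be
        detected to enter an analysis.
    prevalence_scope:
        ``"all_samples"`` — prevalence over every retained study sample;
        ``"per_fraction"`` — the strain must reach ``min_prevalence`` within
        every bacterial fraction separately.
    """

    min_sample_depth: int = 2474
    detection_threshold: float = 1.0e-5
    min_prevalence: float = 0.10
    prevalence_scope: str = "all_samples"

    def __post_init__(self) -> None:
        if self.min_sample_depth < 0:
            raise ValueError("min_sample_depth must be non-negative")
        if not self.detection_threshold > 0:
            raise ValueError("detection_threshold must be strictly positive")
        if not 0 < self.min_prevalence < 1:
            raise ValueError("min_prevalence must lie in (0, 1)")
        if self.prevalence_scope not in ("all_samples", "per_fraction"):
            raise ValueError(
                "prevalence_scope must be 'all_samples' or 'per_fraction', "
                f"got {self.prevalence_scope!r}"
            )


class AsvCountTable:
    """Immutable integer count matrix, ASVs in rows, samples in columns.

    Wraps a :class:`pandas.DataFrame` whose index holds unique ASV
    identifiers and whose columns hold unique sample identifiers; all cells
    are non-negative integers.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated asv_id(s): {dups}")
        if counts.columns.duplicated().any():
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample_id(s): {dups}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric integers")
        if np.isnan(values.astype(float)).any():
            raise ValueError("counts contain missing values")
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.array_equal(values, np.round(values)):
            raise ValueError("counts must be integers")
        self._counts = counts.astype(np.int64)
        self._counts.index.name = "asv_id"

    @property
    def counts(self) -> pd.DataFrame:
        """Count matrix (treat as read-only)."""
        return self._counts

    @property
    def asv_ids(self) -> list[str]:
        return list(self._counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._counts.shape

    def depths(self) -> pd.Series:
        """Total count (sequencing depth) per sample."""
        return self._counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "AsvCountTable":
        return AsvCountTable(self._counts[list(sample_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, AsvCountTable) and self._counts.equals(other._counts)

    def __repr__(self) -> str:
        n_asv, n_samp = self._counts.shape
        return f"AsvCountTable({n_asv} ASVs x {n_samp} samples)"


def validate_sample_metadata(
    meta: pd.DataFrame, sample_ids=None
) -> pd.DataFrame:
    """Validate a sample metadata table and return a normalised copy.

    The returned frame is indexed by ``sample_id`` and carries a derived
    boolean ``steroid`` column (any high-dose steroid use within 3 months).

    Raises ``ValueError`` on missing columns, unknown category labels,
    duplicated ``sample_id`` or duplicated (subject, fraction, timepoint)
    triples, controls observed outside baseline, or samples lacking a
    metadata record.
    """
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required column(s): {missing}")
    meta = meta.copy()
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicated sample_id(s) in metadata: {dups}")
    for col, allowed in (
        ("group", GROUPS),
        ("fraction", FRACTIONS),
        ("timepoint", TIMEPOINTS),
        ("sex", SEXES),
        ("steroid_use", STEROID_LEVELS),
    ):
        bad = sorted(set(meta[col]) - set(allowed))
        if bad:
            raise ValueError(
                f"unknown {col} label(s) {bad}; allowed values: {list(allowed)}"
            )
    key = meta[["subject_id", "fraction", "timepoint"]]
    if key.duplicated().any():
        dups = key[key.duplicated()].to_records(index=False).tolist()
        raise ValueError(
            f"duplicated (subject_id, fraction, timepoint) record(s): {dups}"
        )
    ctrl = meta[meta["group"] == "control"]
    if (ctrl["timepoint"] != "baseline").any():
        bad = ctrl.loc[ctrl["timepoint"] != "baseline", "sample_id"].tolist()
        raise ValueError(f"control samples must be baseline only; offending: {bad}")
    if sample_ids is not None:
        uncovered = sorted(set(sample_ids) - set(meta["sample_id"]))
        if uncovered:
            raise ValueError(f"samples lacking a metadata record: {uncovered}")
    meta["steroid"] = meta["steroid_use"] != "none"
    return meta.set_index("sample_id", drop=False)


def compute_relative_abundance(table: AsvCountTable) -> pd.DataFrame:
    """Close each sample's counts to proportions summing to one.

    Zeros are preserved exactly. Samples with zero depth are an error (depth
    filtering must happen first) and are named in the message.
    """
    depths = table.depths()
    zero = depths.index[depths == 0].tolist()
    if zero:
        raise ValueError(f"zero-depth sample(s), filter before closure: {zero}")
    return table.counts / depths


def filter_samples_by_depth(
    table: AsvCountTable, policy: FilterPolicy
) -> tuple[AsvCountTable, pd.DataFrame]:
    """Drop samples whose depth does not strictly exceed ``min_sample_depth``.

    Returns the filtered table and a report frame with columns
    ``sample_id`` and ``depth`` for every removed sample. Removing every
    sample is an error.
    """
    depths = table.depths()
    keep = depths > policy.min_sample_depth
    removed = pd.DataFrame(
        {"sample_id": depths.index[~keep], "depth": depths[~keep].to_numpy()}
    ).reset_index(drop=True)
    if not keep.any():
        raise ValueError(
            f"depth filter (> {policy.min_sample_depth}) removed all "
            f"{len(depths)} samples"
        )
    if len(removed):
        logger.info(
            "depth filter removed %d of %d samples", len(removed), len(depths)
        )
    return table.subset_samples(depths.index[keep]), removed


def _select_stratum(
    meta: pd.DataFrame, group=None, fraction=None, timepoint=None
) -> pd.Index:
    mask = pd.Series(True, index=meta.index)
    if group is not None:
        mask &= meta["group"] == group
    if fraction is not None:
        mask &= meta["fraction"] == fraction
    if timepoint is not None:
        mask &= meta["timepoint"] == timepoint
    return meta.index[mask]


def compute_prevalence(
    ra: pd.DataFrame,
    meta: pd.DataFrame,
    group=None,
    fraction=None,
    timepoint=None,
    detection_threshold: float = 1.0e-5,
) -> pd.DataFrame:
    """Per-ASV prevalence within a stratum of samples.

    A strain is detected in a sample when its relative abundance is strictly
    above ``detection_threshold``. The stratum is the intersection of the
    given ``group`` / ``fraction`` / ``timepoint`` restrictions (each
    optional) with the samples present in ``ra``.

    Returns a frame indexed by ``asv_id`` with columns ``n_detected``,
    ``n_samples`` and ``prevalence``.
    """
    samples = _select_stratum(meta, group, fraction, timepoint)
    samples = samples.intersection(ra.columns)
    if len(samples) == 0:
        raise ValueError(
            f"empty stratum (group={group!r}, fraction={fraction!r}, "
            f"timepoint={timepoint!r})"
        )
    detected = (ra[samples] > detection_threshold).sum(axis=1)
    n = len(samples)
    return pd.DataFrame(
        {
            "n_detected": detected.astype(int),
            "n_samples": n,
            "prevalence": detected / n,
        }
    )


def filter_asvs_by_prevalence(
    ra: pd.DataFrame, meta: pd.DataFrame, policy: FilterPolicy
) -> pd.Index:
    """ASVs whose prevalence meets ``min_prevalence`` in the configured scope.

    ``all_samples``: prevalence over every sample in ``ra``;
    ``per_fraction``: the bar must be met within each bacterial fraction.
    Returns the retained ``asv_id`` index (possibly empty), order preserved.
    """
    if policy.prevalence_scope == "all_samples":
        prev = compute_prevalence(
            ra, meta, detection_threshold=policy.detection_threshold
        )["prevalence"]
        keep = prev >= policy.min_prevalence
    else:
        keep = pd.Series(True, index=ra.index)
        present = meta.loc[meta.index.intersection(ra.columns), "fraction"]
        for frac in sorted(present.unique()):
            prev = compute_prevalence(
                ra,
                meta,
                fraction=frac,
                detection_threshold=policy.detection_threshold,
            )["prevalence"]
            keep &= prev >= policy.min_prevalence
    return ra.index[keep]
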