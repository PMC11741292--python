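"""End-to-end orchestration of the IgA-seq analysis graph.

Stage order mirrors the analysis of a sorted-fraction amplicon cohort:
depth filter -> relative abundance -> prevalence filters -> per-sample
diversity and per-fraction PERMANOVA -> coating scores per study group ->
differential abundance / prevalence per fraction (cross-sectional and
paired). Every stage draws randomness from a named substream of the single
configured seed, so toggling one stage never changes another's results, and
a machine-readable manifest records inputs, thresholds and the seed.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import bray_curtis_matrix, permanova, shannon_per_sample
from .differential import (
    bh_adjust,
    clr_transform,
    compare_flow_proportions,
    display_fold_change,
    fit_group_model,
    fit_paired_model,
    prevalence_contrast,
)
from .ics import ics_table
from .io import read_count_table, read_flow, read_metadata, write_results
from .profiles import (
    FRACTIONS,
    GROUPS,
    AsvCountTable,
    FilterPolicy,
    compute_prevalence,
    compute_relative_abundance,
    filter_asvs_by_prevalence,
    filter_samples_by_depth,
)
from .synthetic import substream

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Paths, thresholds and toggles for one pipeline run.

    A seed is mandatory: permutation stages refuse to run without one so
    every reported p-value is reproducible.
    """

    out_dir: str
    seed: int
    counts_path: str | None = None
    metadata_path: str | None = None
    flow_path: str | None = None
    policy: FilterPolicy = dataclasses.field(default_factory=FilterPolicy)
    n_permutations: int = 999
    alpha: float = 0.05
    bh_threshold: float = 0.10
    run_diversity: bool = True
    run_permanova: bool = True
    run_ics: bool = True
    run_differential: bool = True
    run_paired: bool = True
    run_flow: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required for permutation stages")


def _per_subject_covariates(meta: pd.DataFrame, timepoint: str = "baseline"):
    sub = meta[meta["timepoint"] == timepoint].drop_duplicates("subject_id")
    sub = sub.set_index("subject_id")
    return pd.DataFrame(
        {
            "age": sub["age"].astype(float),
            "sex_male": (sub["sex"] == "male").astype(float),
            "bmi": sub["bmi"].astype(float),
            "steroid": sub["steroid"].astype(float),
        }
    )


def _differential_abundance(clr, ra, meta, asvs, fraction, alpha):
    samples = meta.index[
        (meta["fraction"] == fraction)
        & (meta["timepoint"] == "baseline")
        & meta["group"].isin(("control", "ms_baseline"))
        & meta.index.isin(clr.columns)
    ]
    sub = meta.loc[samples]
    ms = sub.index[sub["group"] == "ms_baseline"]
    ctrl = sub.index[sub["group"] == "control"]
    lfc = display_fold_change(ra, ms, ctrl)
    rows = []
    for asv in asvs:
        fit = fit_group_model(clr.loc[asv, samples], sub)
        rows.append(
            (asv, fraction, "ms_baseline_vs_control", fit.estimate, fit.std_error,
             fit.statistic, fit.p_value, lfc[asv])
        )
    out = pd.DataFrame(
        rows,
        columns=["asv_id", "fraction", "contrast", "estimate", "se", "stat",
                 "p_value", "log2fc_display"],
    )
    finite = out["p_value"].notna()
    out["q_value"] = np.nan
    out.loc[finite, "q_value"] = bh_adjust(out.loc[finite, "p_value"].to_numpy())
    out["flag"] = _flags(out, alpha)
    return out


def _flags(out, alpha, bh_threshold=0.10):
    star = (out["p_value"] < alpha).fillna(False)
    hash_ = (out["q_value"] < bh_threshold).fillna(False)
    return np.where(hash_, "#", np.where(star, "*", ""))


def _paired_abundance(clr, ra, meta, asvs, fraction, alpha):
    sub = meta[(meta["fraction"] == fraction) & meta.index.isin(clr.columns)]
    base = sub[sub["timepoint"] == "baseline"].set_index("subject_id")["sample_id"]
    month6 = sub[sub["timepoint"] == "month6"].set_index("subject_id")["sample_id"]
    subjects = base.index.intersection(month6.index)
    cov = _per_subject_covariates(meta)[["steroid"]]
    lfc = display_fold_change(ra, month6[subjects], base[subjects])
    rows = []
    for asv in asvs:
        y0 = pd.Series(
            clr.loc[asv, base[subjects]].to_numpy(), index=subjects
        )
        y6 = pd.Series(
            clr.loc[asv, month6[subjects]].to_numpy(), index=subjects
        )
        fit = fit_paired_model(y0, y6, covariates=cov)
        rows.append(
            (asv, fraction, "month6_vs_baseline", fit.estimate, fit.std_error,
             fit.statistic, fit.p_value, lfc[asv])
        )
    out = pd.DataFrame(
        rows,
        columns=["asv_id", "fraction", "contrast", "estimate", "se", "stat",
                 "p_value", "log2fc_display"],
    )
    finite = out["p_value"].notna()
    out["q_value"] = np.nan
    out.loc[finite, "q_value"] = bh_adjust(out.loc[finite, "p_value"].to_numpy())
    out["flag"] = _flags(out, alpha)
    return out


def _differential_prevalence(ra, meta, asvs, fraction, policy, alpha,
                             strata=(("ms_baseline", None), ("control", None))):
    (g1, t1), (g0, t0) = strata
    prev1 = compute_prevalence(ra.loc[asvs], meta, group=g1, fraction=fraction,
                               timepoint=t1,
                               detection_threshold=policy.detection_threshold)
    prev0 = compute_prevalence(ra.loc[asvs], meta, group=g0, fraction=fraction,
                               timepoint=t0,
                               detection_threshold=policy.detection_threshold)
    rows = []
    for asv in asvs:
        res = prevalence_contrast(
            (int(prev1.loc[asv, "n_detected"]), int(prev0.loc[asv, "n_detected"])),
            (int(prev1.loc[asv, "n_samples"]), int(prev0.loc[asv, "n_samples"])),
        )
        rows.append(
            (asv, fraction, f"{g1}_vs_{g0}",
             prev1.loc[asv, "prevalence"], prev0.loc[asv, "prevalence"],
             res.odds_ratio, res.p_value)
        )
    out = pd.DataFrame(
        rows, columns=["asv_id", "fraction", "contrast", "prevalence_1",
                       "prevalence_0", "odds_ratio", "p_value"]
    )
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["flag"] = _flags(out, alpha)
    return out


def run_pipeline(
    config: PipelineConfig,
    table: AsvCountTable | None = None,
    meta: pd.DataFrame | None = None,
    flow: pd.DataFrame | None = None,
) -> dict:
    """Run every enabled stage, write TSV outputs + manifest, return results.

    Inputs may be given as in-memory objects or via the configured paths.
    Raises with a stage-named message on the first failing stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    current = {"stage": "setup"}

    def stage(name):
        current["stage"] = name
        logger.info("stage: %s", name)

    try:
        stage("read-inputs")
        if table is None:
            table = read_count_table(config.counts_path)
        if meta is None:
            meta = read_metadata(config.metadata_path)
        if flow is None and config.flow_path:
            flow = read_flow(config.flow_path)

        stage("depth-filter")
        table, removed = filter_samples_by_depth(table, config.policy)
        meta = meta.loc[meta.index.intersection(table.sample_ids)]
        write_results(removed, out_dir / "qc_removed_samples.tsv")
        results["qc_removed_samples"] = removed

        stage("relative-abundance")
        ra = compute_relative_abundance(table)

        stage("prevalence-filter")
        policy_all = dataclasses.replace(config.policy, prevalence_scope="all_samples")
        ics_asvs = filter_asvs_by_prevalence(ra, meta, policy_all)
        policy_frac = dataclasses.replace(config.policy, prevalence_scope="per_fraction")
        diff_asvs = filter_asvs_by_prevalence(ra, meta, policy_frac)

        if config.run_diversity:
            stage("diversity")
            shannon = shannon_per_sample(ra).rename("shannon").to_frame()
            shannon.insert(0, "sample_id", shannon.index)
            shannon["group"] = meta.loc[shannon.index, "group"].to_numpy()
            shannon["fraction"] = meta.loc[shannon.index, "fraction"].to_numpy()
            write_results(shannon, out_dir / "diversity.tsv")
            results["diversity"] = shannon

        if config.run_permanova:
            for frac in FRACTIONS:
                stage(f"permanova:{frac}")
                samples = meta.index[
                    (meta["fraction"] == frac)
                    & (meta["timepoint"] == "baseline")
                    & meta.index.isin(ra.columns)
                ]
                dm = bray_curtis_matrix(ra[samples])
                res = permanova(
                    dm, meta, n_permutations=config.n_permutations,
                    seed=substream(config.seed, f"permanova:{frac}"),
                )
                write_results(res, out_dir / f"permanova_{frac}.tsv")
                results[f"permanova_{frac}"] = res

        if config.run_ics:
            for group in GROUPS:
                stage(f"ics:{group}")
                res = ics_table(
                    ra.loc[ics_asvs], meta, group,
                    policy=config.policy,
                    n_permutations=config.n_permutations,
                    seed=substream(config.seed, f"ics:{group}"),
                    alpha=config.alpha,
                )
                write_results(res, out_dir / f"ics_{group}.tsv")
                results[f"ics_{group}"] = res

        clr = clr_transform(ra) if (config.run_differential or config.run_paired) else None

        if config.run_differential:
            for frac in FRACTIONS:
                stage(f"diff-abundance:{frac}")
                res = _differential_abundance(clr, ra, meta, diff_asvs, frac,
                                              config.alpha)
                write_results(res, out_dir / f"diff_abundance_{frac}.tsv")
                results[f"diff_abundance_{frac}"] = res

                stage(f"diff-prevalence:{frac}")
                res = _differential_prevalence(ra, meta, diff_asvs, frac,
                                               config.policy, config.alpha)
                write_results(res, out_dir / f"diff_prevalence_{frac}.tsv")
                results[f"diff_prevalence_{frac}"] = res

        if config.run_paired and (meta["timepoint"] == "month6").any():
            for frac in FRACTIONS:
                stage(f"paired:{frac}")
                res = _paired_abundance(clr, ra, meta, diff_asvs, frac, config.alpha)
                write_results(res, out_dir / f"paired_{frac}.tsv")
                results[f"paired_{frac}"] = res

                stage(f"paired-prevalence:{frac}")
                res = _differential_prevalence(
                    ra, meta, diff_asvs, frac, config.policy, config.alpha,
                    strata=(("ms_6mo", "month6"), ("ms_baseline", "baseline")),
                )
                write_results(res, out_dir / f"paired_prevalence_{frac}.tsv")
                results[f"paired_prevalence_{frac}"] = res

        if config.run_flow and flow is not None:
            stage("flow-compare")
            cov = _per_subject_covariates(meta)
            rows = []
            for value in ("pct_iga_coated", "pct_igm_coated", "free_iga"):
                if value not in flow.columns:
                    continue
                fit = compare_flow_proportions(
                    flow[flow["timepoint"] == "baseline"], value=value,
                    covariates=cov,
                )
                rows.append((value, "ms_baseline_vs_control", fit.estimate,
                             fit.std_error, fit.statistic, fit.p_value, fit.n))
            res = pd.DataFrame(
                rows, columns=["measure", "contrast", "estimate", "se", "stat",
                               "p_value", "n"]
            )
            write_results(res, out_dir / "flow_compare.tsv")
            results["flow_compare"] = res

        stage("manifest")
        manifest = {
            "igaseq_version": __version__,
            "seed": config.seed,
            "n_permutations": config.n_permutations,
            "alpha": config.alpha,
            "bh_threshold": config.bh_threshold,
            "filter_policy": dataclasses.asdict(config.policy),
            "inputs": {
                "counts": str(config.counts_path),
                "metadata": str(config.metadata_path),
                "flow": str(config.flow_path),
            },
            "n_samples_retained": len(table.sample_ids),
            "n_samples_removed": int(len(removed)),
            "n_asvs": len(table.asv_ids),
            "n_asvs_ics": int(len(ics_asvs)),
            "n_asvs_differential": int(len(diff_asvs)),
            "outputs": sorted(results.keys()),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        results["manifest"] = manifest
    except Exception as exc:  # re-raise with the failing stage named
        raise RuntimeError(
            f"pipeline failed at stage {current['stage']!r}: {exc}"
        ) from exc
    return results
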