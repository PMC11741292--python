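"""Synthetic IgA-seq cohorts with planted, known effects.

Emulates the post-denoising output of an IgA-seq study of newly diagnosed
multiple sclerosis: two study groups (healthy controls and untreated MS at
baseline), three sequenced bacterial fractions per subject-timepoint
(presort, IgA+, IgA-), and a paired subset of MS subjects re-sampled six
months after starting B-cell depletion. Default sizes are 42 controls, 43 MS
and 19 paired follow-ups, i.e. (42 + 43 + 19) x 3 = 312 samples.

Generative model
----------------
Counts are zero-inflated and compositional by construction:

* each ASV ``j`` has a baseline log-intensity ``mu_j ~ Normal(0, sigma_a)``
  and a baseline detection probability ``pi_j ~ Beta(a, b)`` (the sparsity
  field of the configuration);
* each subject draws per-ASV Gamma intensities
  ``lambda_ij ~ Gamma(k, exp(mu_j + planted group log-fold)/k)`` shared by
  that subject's three fractions (and, up to planted treatment effects, by
  the month-6 re-sample — this is the within-subject dependence);
* each sample switches ASVs on independently with a fraction-specific
  detection probability: planted coating effects split a detection-probability
  offset as +offset/2 in IgA+ and -offset/2 in IgA-, planted prevalence
  effects shift all three fractions of a group; probabilities are clipped to
  [0, 1] with a logged count of clipped entries;
* the switched-on intensities are closed to proportions and counts are drawn
  multinomially at a log-normal sequencing depth (median 20,000 by default).

The sign of a planted coating offset is the ground truth for the immune
coating score; the planted log-fold change is the ground truth for the
compositional differential-abundance model.

Covariates (age, sex, BMI, steroid use) mirror the study's demographics and
are causally inert by default — they influence nothing unless the
confounding switch is enabled, so adjusted and unadjusted analyses estimate
the same planted effects.
"""
from __future__ import annotations

import dataclasses
import logging
import zlib

import numpy as np
import pandas as pd

from .profiles import AsvCountTable, validate_sample_metadata

logger = logging.getLogger(__name__)

GROUP_LABELS = ("control", "ms_baseline", "ms_6mo")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent RNG substream derived from one master seed.

    Streams are keyed by a CRC32 hash of the stage name, so enabling or
    re-ordering one stage never perturbs another stage's draws.
    """
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


@dataclasses.dataclass(frozen=True)
class PlantedEffect:
    """One planted ground-truth effect on a single ASV within one group.

    ``size`` is interpreted per effect kind: a natural-log fold change on
    subject intensities for abundance effects, a detection-probability gap
    between IgA+ and IgA- for coating effects, and a detection-probability
    offset applied to every fraction for prevalence effects.
    """

    asv_index: int
    group: str
    size: float

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValueError(f"unknown group {self.group!r}")


@dataclasses.dataclass(frozen=True)
class SyntheticCohortConfig:
    """Parameters of the synthetic cohort; defaults follow the study design."""

    n_controls: int = 42
    n_ms: int = 43
    n_paired: int = 19
    n_asvs: int = 300
    # sequencing depth: log-normal, parameterised by its median and log-sd
    depth_median: float = 20_000.0
    depth_log_sd: float = 0.35
    # per-ASV baseline detection probability ~ Beta(a, b)
    sparsity_alpha: float = 0.8
    sparsity_beta: float = 1.6
    # per-ASV baseline log-intensity spread and subject-level Gamma shape
    abundance_log_sd: float = 1.5
    gamma_shape: float = 0.8
    planted_abundance_effects: tuple[PlantedEffect, ...] = ()
    planted_coating_effects: tuple[PlantedEffect, ...] = ()
    planted_prevalence_effects: tuple[PlantedEffect, ...] = ()
    # covariate model (inert unless confound_strength > 0)
    age_mean: float = 38.0
    age_sd: float = 11.0
    bmi_mean: float = 27.0
    bmi_sd: float = 7.0
    p_female: float = 0.70
    p_steroid_ms: float = 0.55
    confound_strength: float = 0.0
    # fraction of non-presort samples lost at random (missingness emulation)
    dropout_rate: float = 0.0
    # flow-cytometry / ELISA summaries
    flow_iga_mean: float = 0.30
    flow_iga_shift_ms: float = -0.08
    flow_igm_mean: float = 0.10
    flow_concentration: float = 40.0
    free_iga_log_mean: float = 0.0
    free_iga_log_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 1 or self.n_ms < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0 <= self.n_paired <= self.n_ms:
            raise ValueError("n_paired must lie in [0, n_ms]")
        if self.n_asvs < 2:
            raise ValueError("need at least 2 ASVs")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        for eff in self.all_effects():
            if not 0 <= eff.asv_index < self.n_asvs:
                raise ValueError(
                    f"planted effect references ASV index {eff.asv_index}, "
                    f"outside [0, {self.n_asvs})"
                )

    def all_effects(self):
        return (
            tuple(self.planted_abundance_effects)
            + tuple(self.planted_coating_effects)
            + tuple(self.planted_prevalence_effects)
        )


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth planted into a synthetic cohort.

    ``abundance_lfc`` — natural-log fold change on intensities, ASV x group;
    ``coating_offset`` / ``prevalence_offset`` — detection-probability shifts,
    ASV x group; ``detection_prob`` — realised per-stratum detection
    probability after clipping, columns ``(group, fraction)``;
    ``positive_coating`` — per group, the set of ASV ids planted with a
    positive coating offset.
    """

    abundance_lfc: pd.DataFrame
    coating_offset: pd.DataFrame
    prevalence_offset: pd.DataFrame
    detection_prob: pd.DataFrame
    positive_coating: dict[str, set[str]]


def _asv_ids(n: int) -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"ASV{str(i).zfill(width)}" for i in range(n)]


def _effect_matrix(n_asvs, asv_ids, effects) -> pd.DataFrame:
    mat = pd.DataFrame(0.0, index=asv_ids, columns=list(GROUP_LABELS))
    for eff in effects:
        mat.iloc[eff.asv_index, mat.columns.get_loc(eff.group)] += eff.size
    return mat


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[AsvCountTable, pd.DataFrame, SyntheticTruth]:
    """Draw one cohort: counts, validated metadata and the planted truth.

    Identical configurations (including the seed) yield byte-identical
    outputs; all randomness flows from ``config.seed`` through a dedicated
    substream.
    """
    rng = substream(config.seed, "cohort")
    asv_ids = _asv_ids(config.n_asvs)

    mu = rng.normal(0.0, config.abundance_log_sd, config.n_asvs)
    pi = rng.beta(config.sparsity_alpha, config.sparsity_beta, config.n_asvs)

    abund = _effect_matrix(config.n_asvs, asv_ids, config.planted_abundance_effects)
    coat = _effect_matrix(config.n_asvs, asv_ids, config.planted_coating_effects)
    prev = _effect_matrix(config.n_asvs, asv_ids, config.planted_prevalence_effects)

    subjects = [("C%03d" % (i + 1), "control") for i in range(config.n_controls)]
    subjects += [("M%03d" % (i + 1), "ms") for i in range(config.n_ms)]

    # realised (clipped) detection probability per (group, fraction)
    frac_sign = {"presort": 0.0, "iga_pos": 0.5, "iga_neg": -0.5}
    det_cols = {}
    n_clipped = 0
    for grp in GROUP_LABELS:
        for frac, sign in frac_sign.items():
            q = pi + prev[grp].to_numpy() + sign * coat[grp].to_numpy()
            n_clipped += int(((q < 0) | (q > 1)).sum())
            det_cols[(grp, frac)] = np.clip(q, 0.0, 1.0)
    if n_clipped:
        logger.info("clipped %d detection probabilities to [0, 1]", n_clipped)
    detection_prob = pd.DataFrame(det_cols, index=asv_ids)

    meta_rows = []
    count_cols = {}

    def draw_sample(sample_id, lam, grp, frac):
        q = detection_prob[(grp, frac)].to_numpy()
        z = rng.random(config.n_asvs) < q
        w = lam * z
        if w.sum() == 0.0:
            # pathological all-off draw: keep the strongest intensity on
            w = lam * (np.arange(config.n_asvs) == int(np.argmax(lam)))
        p = w / w.sum()
        depth = int(
            np.round(rng.lognormal(np.log(config.depth_median), config.depth_log_sd))
        )
        count_cols[sample_id] = rng.multinomial(max(depth, 1), p)

    for i, (subj, cohort) in enumerate(subjects):
        age = rng.normal(config.age_mean, config.age_sd)
        bmi = rng.normal(config.bmi_mean, config.bmi_sd)
        sex = "female" if rng.random() < config.p_female else "male"
        if cohort == "ms" and rng.random() < config.p_steroid_ms:
            steroid = "within_1mo" if rng.random() < 0.9 else "within_2_3mo"
        else:
            steroid = "none"
        grp0 = "control" if cohort == "control" else "ms_baseline"
        # optional confounding: covariates tilt the subject's intensities
        conf = 0.0
        if config.confound_strength:
            conf = config.confound_strength * (age - config.age_mean) / config.age_sd
        lam = rng.gamma(
            config.gamma_shape,
            np.exp(mu + abund[grp0].to_numpy() + conf) / config.gamma_shape,
        )
        timepoints = [("baseline", grp0)]
        paired = cohort == "ms" and (i - config.n_controls) < config.n_paired
        if paired:
            timepoints.append(("month6", "ms_6mo"))
        for tp, grp in timepoints:
            lam_tp = lam
            if tp == "month6":
                lam_tp = lam * np.exp(abund["ms_6mo"].to_numpy())
            for frac in ("presort", "iga_pos", "iga_neg"):
                sid = f"{subj}_{tp}_{frac}"
                draw_sample(sid, lam_tp, grp, frac)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "subject_id": subj,
                        "group": grp,
                        "fraction": frac,
                        "timepoint": tp,
                        "age": round(age, 2),
                        "sex": sex,
                        "bmi": round(bmi, 2),
                        "steroid_use": steroid,
                    }
                )

    meta = pd.DataFrame(meta_rows)
    if config.dropout_rate > 0:
        droppable = meta.index[meta["fraction"] != "presort"]
        drop = droppable[rng.random(len(droppable)) < config.dropout_rate]
        if len(drop):
            logger.info("dropout removed %d of %d samples", len(drop), len(meta))
            dropped_ids = set(meta.loc[drop, "sample_id"])
            meta = meta.drop(index=drop).reset_index(drop=True)
            for sid in dropped_ids:
                del count_cols[sid]

    counts = pd.DataFrame(count_cols, index=asv_ids)
    counts = counts[meta["sample_id"].tolist()]
    table = AsvCountTable(counts)
    meta = validate_sample_metadata(meta, table.sample_ids)

    positive = {
        grp: set(coat.index[coat[grp] > 0]) for grp in GROUP_LABELS
    }
    truth = SyntheticTruth(
        abundance_lfc=abund,
        coating_offset=coat,
        prevalence_offset=prev,
        detection_prob=detection_prob,
        positive_coating=positive,
    )
    return table, meta, truth


def generate_flow_summaries(
    config: SyntheticCohortConfig, meta: pd.DataFrame
) -> pd.DataFrame:
    """Per subject-timepoint flow/ELISA scalars.

    ``pct_iga_coated`` and ``pct_igm_coated`` are Beta-distributed
    proportions; the MS group's IgA-coated mean is shifted by
    ``flow_iga_shift_ms`` (negative by default: untreated MS shows reduced
    IgA coating), with no shift on IgM or on free fecal IgA. Month-6 samples
    keep the MS mean (coating does not rebound by default). Uses its own
    substream of ``config.seed``.
    """
    rng = substream(config.seed, "flow")
    kappa = config.flow_concentration

    def beta_draw(mean):
        mean = min(max(mean, 1e-3), 1 - 1e-3)
        return rng.beta(mean * kappa, (1 - mean) * kappa)

    rows = []
    per_subject = meta.drop_duplicates(["subject_id", "timepoint"])
    for _, rec in per_subject.iterrows():
        iga_mean = config.flow_iga_mean
        if rec["group"] in ("ms_baseline", "ms_6mo"):
            iga_mean += config.flow_iga_shift_ms
        rows.append(
            {
                "subject_id": rec["subject_id"],
                "timepoint": rec["timepoint"],
                "group": rec["group"],
                "pct_iga_coated": beta_draw(iga_mean),
                "pct_igm_coated": beta_draw(config.flow_igm_mean),
                "free_iga": rng.lognormal(
                    config.free_iga_log_mean, config.free_iga_log_sd
                ),
            }
        )
    return pd.DataFrame(rows)
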