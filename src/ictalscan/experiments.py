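"""Cross-over training designs and group comparisons on synthetic cohorts.

Two experiment families mirror the study's designs:

* **Seizure cross-over** — detectors trained on restricted seizure subsets
  (early-only, late-only, or all) are applied to every subject, and the
  per-interval detection durations are compared across training condition
  and test latency class by two-way ANOVA.  If early and late seizures
  share a spectro-temporal phenotype, training condition should show no
  main effect, while early detections stay shorter simply because early
  seizures are shorter.
* **SWD group comparison** — an SWD detector trained on all subjects'
  SWDs, or only on SWDs of subjects with PTE, is applied across the four
  treatment groups (injury × pre-injury stress); per-subject mean
  detection durations are summarized as mean ± SEM per group and compared
  by two-way ANOVA and two-sample t tests.  With identical SWD generators
  everywhere the tests should reject only at the nominal α — the null
  calibration harness measures exactly that over replicate cohorts using
  ground-truth (classifier-free) detections.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .classify import (
    ClassifierModel,
    SegmentPrediction,
    build_training_set,
    classify_segments,
    oracle_predictions,
    subject_features,
    train,
    training_set_from_features,
)
from .scalogram import FeatureConfig
from .synthetic import (
    EARLY_LATE_BOUNDARY_DAYS,
    Cohort,
    CohortConfig,
    SubjectData,
    gen_cohort,
    seizure_events,
)
from .stats import GroupSummary, TwoWayAnovaResult, anova_two_way, group_summary, t_two_sample
from .timeline import build_timeline, classify_latency, pte_status

__all__ = [
    "CROSSOVER_CONDITIONS",
    "detect_subject",
    "crossover_experiment",
    "crossover_replicates",
    "swd_group_experiment",
    "swd_null_calibration",
    "incidence_report",
    "cohort_pte_status",
]

logger = logging.getLogger(__name__)

CROSSOVER_CONDITIONS = ("early_only", "late_only", "all")

# ---------------------------------------------------------------------------
# canonical scaled study designs
#
# These are the package's default experiment scales: large enough for the
# statistical properties they probe, small enough that each full experiment
# runs in minutes on one CPU.  The full-cohort design (61 subjects over
# months) is reachable by raising the sizes in a custom CohortConfig.
# ---------------------------------------------------------------------------

#: Cross-over training design: one injured+stressed group in which half the
#: subjects carry early seizures and half carry late ones, with enough
#: seizures per subject that every training subset has a usable exemplar
#: pool.
CROSSOVER_CONFIG = CohortConfig(
    group_sizes={"FPI_Stress": 6}, n_days=8, intervals_per_day=1,
    pte_fraction=0.5, early_prob=1.0, n_early_mean=5.0, n_late_mean=5.0)

#: Four-group null design for SWD calibration: identical SWD generators in
#: every group, no seizures.
SWD_NULL_CONFIG = CohortConfig(
    group_sizes={g: 3 for g in ("FPI_Stress", "FPI_noStress",
                                "Sham_Stress", "Sham_noStress")},
    n_days=4, intervals_per_day=2, pte_fraction=0.0)

#: Small mixed cohort with a known PTE fraction for incidence recovery.
PTE_RECOVERY_CONFIG = CohortConfig(
    group_sizes={"FPI_Stress": 4, "FPI_noStress": 2, "Sham_noStress": 2},
    n_days=9, intervals_per_day=1, pte_fraction=0.25, early_prob=0.75,
    n_early_mean=2.0, n_late_mean=3.0)

_LATENCY_FILTERS = {
    "early_only": lambda s: s / 86400.0 <= EARLY_LATE_BOUNDARY_DAYS,
    "late_only": lambda s: s / 86400.0 > EARLY_LATE_BOUNDARY_DAYS,
    "all": None,
}


def detect_subject(subject: SubjectData, model: ClassifierModel,
                   interval_indices: list[int] | None = None,
                   features=None) -> list[SegmentPrediction]:
    """Classify every epoch of a subject's (selected) intervals."""
    if features is None:
        features = subject_features(subject, model.feature_config,
                                    interval_indices)
    preds: list[SegmentPrediction] = []
    for idx in sorted(features):
        epochs, X = features[idx]
        preds.extend(classify_segments(model, epochs, features=X))
    return preds


def _event_interval_indices(subject: SubjectData, kind: str) -> list[int]:
    if kind == "seizure":
        ivs = {iv for _sid, iv, _s, _e in seizure_events(subject.annotations)}
    else:
        ivs = {a.interval_index for a in subject.annotations
               if a.klass == kind}
    return sorted(ivs & set(subject.records))


# --------------------------------------------------------------------------
# seizure cross-over
# --------------------------------------------------------------------------

def crossover_experiment(cohort: Cohort, seed: int = 0,
                         conditions=CROSSOVER_CONDITIONS,
                         cfg: FeatureConfig = FeatureConfig(),
                         backbone: str = "mlp",
                         threshold: float = 0.99,
                         classify_all_intervals: bool = False,
                         ) -> pd.DataFrame:
    """Detection durations by (training condition, test latency class).

    For each training condition a seizure detector is trained on that
    subset of the cohort's seizures (plus background), then applied to
    every subject.  Rows are per-interval detection totals with the test
    class given by the interval's post-implant latency.  Intervals without
    seizures are skipped unless ``classify_all_intervals`` is set (they
    contribute no duration rows either way).  Conditions whose training
    cell is empty are skipped with a log message.
    """
    subjects = [cohort.subjects[sid] for sid in sorted(cohort.subjects)]
    feature_cache = {
        s.subject_id: subject_features(
            s, cfg,
            None if classify_all_intervals
            else _event_interval_indices(s, "seizure"))
        for s in subjects
    }

    rows = []
    for cond in conditions:
        filt = _LATENCY_FILTERS[cond]
        try:
            ts = training_set_from_features(subjects, feature_cache,
                                            "seizure", seed=seed,
                                            event_filter=filt)
        except ValueError:
            logger.warning("skipping condition %r: empty training cell", cond)
            continue
        model = train(ts, backbone=backbone, threshold=threshold, seed=seed,
                      cfg=cfg)
        for subj in subjects:
            preds = detect_subject(subj, model,
                                   features=feature_cache[subj.subject_id])
            tl = build_timeline(preds, subj.latency_map, "seizure")
            for e in tl.entries:
                rows.append({
                    "training": cond,
                    "test_class": classify_latency(e.latency_days),
                    "subject_id": subj.subject_id,
                    "interval_index": e.interval_index,
                    "duration_s": e.total_detected_s,
                })
    return pd.DataFrame(rows, columns=["training", "test_class",
                                       "subject_id", "interval_index",
                                       "duration_s"])


def crossover_replicates(config: CohortConfig, n_replicates: int,
                         seed: int = 0,
                         cfg: FeatureConfig = FeatureConfig(),
                         backbone: str = "mlp",
                         ) -> tuple[pd.DataFrame, TwoWayAnovaResult]:
    """Pooled cross-over tables over replicate cohorts plus the ANOVA.

    Each replicate draws a fresh cohort from ``config``; the pooled
    per-interval durations are analysed by two-way ANOVA with factors
    training condition and test latency class.
    """
    frames = []
    ss = np.random.SeedSequence([int(seed), 77])
    child_seeds = ss.generate_state(n_replicates) % (2 ** 31)
    for r, s in enumerate(child_seeds):
        cohort = gen_cohort(config, int(s), waveforms="seizure")
        df = crossover_experiment(cohort, seed=int(s), cfg=cfg,
                                  backbone=backbone)
        df["replicate"] = r
        frames.append(df)
    pooled = pd.concat(frames, ignore_index=True)
    result = anova_two_way(pooled["duration_s"], pooled["training"],
                           pooled["test_class"])
    return pooled, result


# --------------------------------------------------------------------------
# SWD group comparison
# --------------------------------------------------------------------------

def _injury(group: str) -> str:
    return "FPI" if group.startswith("FPI") else "Sham"


def _stress(group: str) -> str:
    return "Stress" if group.endswith("_Stress") else "noStress"


def _subject_mean_swd_s(subject: SubjectData,
                        preds: list[SegmentPrediction]) -> float | None:
    tl = build_timeline(preds, subject.latency_map, "swd")
    if not tl.entries:
        return None
    return float(np.mean([e.total_detected_s for e in tl.entries]))


def swd_group_experiment(cohort: Cohort, regime: str = "all_swd",
                         mode: str = "oracle", seed: int = 0,
                         cfg: FeatureConfig = FeatureConfig(),
                         backbone: str = "mlp",
                         threshold: float = 0.99) -> dict:
    """Per-group SWD detection-duration summaries under one training regime.

    ``regime`` is ``"all_swd"`` (train on every subject's SWDs) or
    ``"pte_swd_only"`` (train only on SWDs of subjects with late
    seizures); ``mode="oracle"`` bypasses the classifier and scores
    ground-truth detections (the fast path for calibration studies).
    Returns group summaries, the observation table, and the injury/stress
    tests; returns ``None`` if the PTE regime has no PTE subjects.
    """
    subjects = [cohort.subjects[sid] for sid in sorted(cohort.subjects)]

    if mode == "oracle":
        model = None
    else:
        if regime == "pte_swd_only":
            pool = [s for s in subjects if s.profile.has_late]
            if not pool:
                logger.warning("no PTE subjects; skipping pte_swd_only regime")
                return None
        elif regime == "all_swd":
            pool = subjects
        else:
            raise ValueError(f"unknown regime {regime!r}")
        ts = build_training_set(pool, "swd", cfg, seed=seed)
        model = train(ts, backbone=backbone, threshold=threshold, seed=seed,
                      cfg=cfg)

    rows = []
    for subj in subjects:
        if model is None:
            preds = oracle_predictions(subj, "swd")
        else:
            idx = _event_interval_indices(subj, "swd")
            preds = detect_subject(subj, model, interval_indices=idx)
        mean_s = _subject_mean_swd_s(subj, preds)
        if mean_s is None:
            continue
        g = subj.profile.group
        rows.append({"subject_id": subj.subject_id, "group": g,
                     "injury": _injury(g), "stress": _stress(g),
                     "mean_swd_s": mean_s})
    obs = pd.DataFrame(rows)

    summaries: dict[str, GroupSummary] = {}
    for g, sub in obs.groupby("group"):
        summaries[g] = group_summary(g, sub["mean_swd_s"])

    tests = {}
    cells = set(zip(obs["injury"], obs["stress"]))
    if len(cells) == 4:
        tests["anova"] = anova_two_way(obs["mean_swd_s"], obs["injury"],
                                       obs["stress"])
        fpi = obs.loc[obs["injury"] == "FPI", "mean_swd_s"]
        sham = obs.loc[obs["injury"] == "Sham", "mean_swd_s"]
        if len(fpi) >= 2 and len(sham) >= 2:
            tests["t_injury"] = t_two_sample(fpi, sham)
        st = obs.loc[obs["stress"] == "Stress", "mean_swd_s"]
        ns = obs.loc[obs["stress"] == "noStress", "mean_swd_s"]
        if len(st) >= 2 and len(ns) >= 2:
            tests["t_stress"] = t_two_sample(st, ns)
    return {"regime": regime, "mode": mode, "summaries": summaries,
            "observations": obs, "tests": tests}


def swd_null_calibration(config: CohortConfig, n_replicates: int = 200,
                         seed: int = 0, alpha: float = 0.05,
                         factor: str = "injury") -> dict:
    """Rejection rate of the group-difference test under the generator null.

    Every group shares the same SWD parameters, so the injury (or stress)
    main effect is null by construction; over replicate cohorts the
    two-way ANOVA should reject at ≈ ``alpha``.  Uses ground-truth
    detections (no classifier) so hundreds of replicates run in seconds.
    """
    ss = np.random.SeedSequence([int(seed), 101])
    child_seeds = ss.generate_state(n_replicates) % (2 ** 31)
    p_values = []
    for s in child_seeds:
        cohort = gen_cohort(config, int(s), waveforms=False)
        res = swd_group_experiment(cohort, regime="all_swd", mode="oracle")
        a = res["tests"]["anova"]
        p = a.factor_a.p if factor == "injury" else a.factor_b.p
        p_values.append(p)
    p_values = np.asarray(p_values)
    return {
        "n_replicates": int(n_replicates),
        "alpha": float(alpha),
        "rejection_rate": float(np.mean(p_values < alpha)),
        "p_values": p_values,
    }


# --------------------------------------------------------------------------
# incidence
# --------------------------------------------------------------------------

def cohort_pte_status(cohort: Cohort, mode: str = "ground_truth",
                      model: ClassifierModel | None = None,
                      threshold_late: int = 1) -> dict[str, bool]:
    """PTE flag per subject from ground truth or from detections."""
    out = {}
    for sid in sorted(cohort.subjects):
        subj = cohort.subjects[sid]
        if mode == "ground_truth":
            preds = oracle_predictions(subj, "seizure")
        elif mode == "detections":
            if model is None:
                raise ValueError("detections mode requires a trained model")
            idx = sorted(subj.records)
            preds = detect_subject(subj, model, interval_indices=idx)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        tl = build_timeline(preds, subj.latency_map, "seizure")
        out[sid] = pte_status(tl, threshold_late=threshold_late)
    return out


def incidence_report(pte_by_subject: dict[str, bool],
                     any_seizure_by_subject: dict[str, bool] | None = None,
                     ) -> dict:
    """Cohort-level proportions: PTE incidence and any-seizure fraction.

    Percentages are reported to one decimal place alongside the raw
    counts.
    """
    if not pte_by_subject:
        raise ValueError("empty cohort")
    n = len(pte_by_subject)
    n_pte = sum(pte_by_subject.values())
    rep = {
        "n_subjects": n,
        "n_pte": int(n_pte),
        "pte_incidence": n_pte / n,
        "pte_incidence_pct": round(100.0 * n_pte / n, 1),
    }
    if any_seizure_by_subject is not None:
        n_sz = sum(any_seizure_by_subject.values())
        rep["n_with_seizures"] = int(n_sz)
        rep["seizure_fraction"] = n_sz / n
    return rep
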