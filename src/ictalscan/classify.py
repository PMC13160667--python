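"""Event-vs-background classification of scalogram epochs.

The detector is a binary image classifier over scalogram features with the
fixed-confidence decision rule used throughout the analysis: an epoch is
flagged as an event **iff** the posterior probability of the event class
strictly exceeds the detection threshold (default 0.99).  Two independent
binary detectors are trained in practice — seizure-vs-background and
SWD-vs-background — and applied to the same records.

The default backbone is a small multilayer perceptron over the reduced
scalogram grid (see :class:`~ictalscan.scalogram.FeatureConfig`); a
logistic-regression backbone is available for quick runs.  Training is
seeded and single-threaded, so identical data and seed give identical
fitted weights.  The correction loop mirrors long-term monitoring
practice: confirmed false positives are appended to the background pool,
missed events to the event pool, and the model is retrained from the
updated pools.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from .scalogram import EPOCH_S, Epoch, FeatureConfig, epoch_features, segment_record
from .synthetic import (
    EventAnnotation,
    SubjectData,
    seizure_events,
)

__all__ = [
    "TrainingSet",
    "ClassifierModel",
    "SegmentPrediction",
    "EvalMetrics",
    "build_training_set",
    "split_train_val",
    "train",
    "classify_segments",
    "retrain_with_corrections",
    "evaluate",
    "oracle_predictions",
    "subject_features",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

EVENT, BACKGROUND = "event", "background"


@dataclass
class TrainingSet:
    """Labeled scalogram-feature pool for one binary detection task."""

    features: np.ndarray         # (n_items, n_features) float32
    labels: np.ndarray           # strings: "event" | "background"
    event_kind: str              # "seizure" | "swd"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float32)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D array")
        if self.features.shape[0] != self.labels.size:
            raise ValueError("features and labels must align")

    @property
    def n_event(self) -> int:
        return int(np.sum(self.labels == EVENT))

    @property
    def n_background(self) -> int:
        return int(np.sum(self.labels == BACKGROUND))


@dataclass(frozen=True)
class SegmentPrediction:
    """Per-epoch decision: event iff confidence > the model threshold."""

    subject_id: str
    interval_index: int
    epoch_index: int
    start_s: float
    label: str
    confidence: float           # posterior of the event class


@dataclass
class ClassifierModel:
    """A trained detector plus its training pools and metadata."""

    estimator: object
    event_kind: str
    threshold: float = 0.99
    backbone: str = "mlp"
    feature_config: FeatureConfig = FeatureConfig()
    pools: TrainingSet | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.5 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0.5, 1)")

    def event_posterior(self, X: np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(X)
        j = list(self.estimator.classes_).index(EVENT)
        return proba[:, j]


# --------------------------------------------------------------------------
# training-pool construction
# --------------------------------------------------------------------------

def _event_spans(annotations: list[EventAnnotation],
                 kind: str, spiking_only: bool = False,
                 ) -> list[tuple[str, float, float]]:
    """(subject, start_s, end_s) spans of detectable event content.

    For seizures the span covers the ictal phases (onset/mid/end);
    ``spiking_only`` restricts to the spiking phases, excluding mid-ictal
    depression — a depressed-EEG epoch carries no ictal signature under
    per-image normalization and is not an event exemplar.
    """
    if kind == "seizure":
        if spiking_only:
            return [(a.subject_id, a.start_s, a.end_s)
                    for a in annotations
                    if a.klass == "seizure" and a.phase in ("sz_onset",
                                                            "sz_end")]
        return [(sid, s, e) for sid, _iv, s, e in seizure_events(annotations)]
    return [(a.subject_id, a.start_s, a.end_s)
            for a in annotations if a.klass == kind]


def _overlaps(e_start: float, e_end: float,
              spans: list[tuple[float, float]]) -> bool:
    return any(e_start < b and e_end > a for a, b in spans)


def subject_features(subject: SubjectData,
                     cfg: FeatureConfig = FeatureConfig(),
                     interval_indices: list[int] | None = None,
                     ) -> dict[int, tuple[list[Epoch], np.ndarray]]:
    """Epochs and feature matrices per interval, computed once per subject."""
    out: dict[int, tuple[list[Epoch], np.ndarray]] = {}
    indices = sorted(subject.records) if interval_indices is None \
        else interval_indices
    for idx in indices:
        epochs = segment_record(subject.records[idx], interval_index=idx)
        X = np.stack([epoch_features(ep, cfg) for ep in epochs])
        out[idx] = (epochs, X)
    return out


def _overlap_s(e_start: float, e_end: float,
               spans: list[tuple[float, float]]) -> float:
    return sum(max(0.0, min(e_end, b) - max(e_start, a)) for a, b in spans)


def _pools_from_epochs(subjects, epoch_iter, event_kind, rng,
                       background_per_event, min_overlap_s, event_filter):
    """Shared pool-building core over an (subject, epoch, feature) stream.

    Event exemplars carry ≥ ``min_overlap_s`` seconds of a (filtered)
    target-kind spiking span.  Background exemplars are epochs free of any
    target-kind content; epochs holding *other*-kind events (e.g. SWDs for
    a seizure detector) are deliberately kept in the background pool — the
    detector must learn that they are not its event — and all of them are
    included (up to the event-pool size) before pure background is sampled
    to reach ``background_per_event`` per event item.
    """
    feats_ev, feats_other, feats_pure, prov = [], [], [], []
    for subj, epochs_with_rows in epoch_iter:
        spans = [(s, e) for sid, s, e in
                 _event_spans(subj.annotations, event_kind,
                              spiking_only=True)
                 if event_filter is None or event_filter(s)]
        target_spans = [(a.start_s, a.end_s) for a in subj.annotations
                        if a.klass == event_kind]
        other_spans = [(a.start_s, a.end_s) for a in subj.annotations
                       if a.klass != event_kind]
        for ep, row in epochs_with_rows:
            if _overlap_s(ep.start_s, ep.end_s, spans) >= min_overlap_s:
                feats_ev.append(row)
                prov.append(f"{subj.subject_id}/{ep.interval_index}/"
                            f"{ep.epoch_index}")
            elif not _overlaps(ep.start_s, ep.end_s, target_spans):
                if _overlaps(ep.start_s, ep.end_s, other_spans):
                    feats_other.append(row)
                else:
                    feats_pure.append(row)
    if not feats_ev:
        raise ValueError(f"no {event_kind} epochs found in training subjects")
    n_other = min(len(feats_other), len(feats_ev))
    other_idx = (rng.choice(len(feats_other), size=n_other, replace=False)
                 if n_other else np.array([], dtype=int))
    n_bg_total = max(2, int(round(background_per_event * len(feats_ev))))
    n_pure = min(len(feats_pure), max(n_bg_total - n_other, 2))
    pure_idx = rng.choice(len(feats_pure), size=n_pure, replace=False)
    bg = [feats_other[i] for i in other_idx] + [feats_pure[i] for i in pure_idx]
    X = np.stack(feats_ev + bg)
    y = np.array([EVENT] * len(feats_ev) + [BACKGROUND] * len(bg))
    return TrainingSet(X, y, event_kind, provenance=prov)


def build_training_set(subjects: list[SubjectData], event_kind: str,
                       cfg: FeatureConfig = FeatureConfig(),
                       seed: int = 0,
                       background_per_event: float = 1.5,
                       min_overlap_s: float = 3.0,
                       event_filter=None) -> TrainingSet:
    """Extract labeled feature pools from annotated synthetic subjects.

    Epochs carrying at least ``min_overlap_s`` seconds of an event span of
    ``event_kind`` become event items — training exemplars are clear event
    epochs, as in a visually curated sample set, while boundary slivers
    are left out (detection of partial epochs is still exercised at test
    time).  ``event_filter(start_s) -> bool`` can restrict events to a
    subset, e.g. by post-implant latency.  The background pool mixes
    epochs holding non-target events with pure background (see
    :func:`_pools_from_epochs`), at ``background_per_event`` items per
    event item.
    """
    rng = np.random.default_rng(seed)

    def it():
        for subj in subjects:
            rows = []
            for idx in sorted(subj.records):
                for ep in segment_record(subj.records[idx],
                                         interval_index=idx):
                    rows.append((ep, epoch_features(ep, cfg)))
            yield subj, rows

    return _pools_from_epochs(subjects, it(), event_kind, rng,
                              background_per_event, min_overlap_s,
                              event_filter)


def training_set_from_features(
        subjects: list[SubjectData],
        features_by_subject: dict[str, dict[int, tuple[list[Epoch], np.ndarray]]],
        event_kind: str, seed: int = 0,
        background_per_event: float = 1.5,
        min_overlap_s: float = 3.0,
        event_filter=None) -> TrainingSet:
    """As :func:`build_training_set`, but over precomputed epoch features.

    ``features_by_subject`` maps subject id → interval → (epochs, feature
    matrix), as produced by :func:`subject_features`; no CWT work is
    redone, so several training subsets can be drawn from one cohort pass.
    """
    rng = np.random.default_rng(seed)

    def it():
        for subj in subjects:
            cached = features_by_subject.get(subj.subject_id, {})
            rows = []
            for idx in sorted(cached):
                epochs, X = cached[idx]
                rows.extend(zip(epochs, X))
            yield subj, rows

    return _pools_from_epochs(subjects, it(), event_kind, rng,
                              background_per_event, min_overlap_s,
                              event_filter)


def split_train_val(items: TrainingSet, fraction: float = 0.5,
                    seed: int = 0) -> tuple[TrainingSet, TrainingSet]:
    """Stratified random split into train/validation pools.

    ``fraction`` is the share used for training (the study used half for
    training and half for validation).  ``fraction=1.0`` yields an empty
    validation set with a warning.
    """
    rng = np.random.default_rng(seed)
    tr_idx, va_idx = [], []
    for lab in (EVENT, BACKGROUND):
        idx = np.flatnonzero(items.labels == lab)
        if idx.size < 2:
            raise ValueError(f"need at least 2 items of class {lab!r}, "
                             f"got {idx.size}")
        idx = rng.permutation(idx)
        k = int(round(fraction * idx.size))
        tr_idx.extend(idx[:k])
        va_idx.extend(idx[k:])
    if not va_idx:
        warnings.warn("fraction=1.0 leaves an empty validation set")
    tr_idx, va_idx = sorted(tr_idx), sorted(va_idx)
    mk = lambda ix: TrainingSet(items.features[ix], items.labels[ix],
                                items.event_kind)
    return mk(tr_idx), mk(va_idx)


# --------------------------------------------------------------------------
# training / inference
# --------------------------------------------------------------------------

def _make_estimator(backbone: str, seed: int):
    if backbone == "mlp":
        # run the optimizer to (near) zero training loss: the fixed 0.99
        # detection threshold needs saturated posteriors on clear events,
        # independent of training-pool size
        return MLPClassifier(hidden_layer_sizes=(32,), alpha=1e-5,
                             max_iter=3000, tol=1e-7, n_iter_no_change=50,
                             random_state=seed, solver="adam",
                             early_stopping=False)
    if backbone == "logreg":
        return LogisticRegression(C=10.0, max_iter=2000, random_state=seed)
    raise ValueError(f"unknown backbone {backbone!r}")


def train(train_set: TrainingSet, backbone: str = "mlp",
          threshold: float = 0.99, seed: int = 0,
          val_fraction: float = 0.5,
          cfg: FeatureConfig = FeatureConfig()) -> ClassifierModel:
    """Fit a detector on a labeled pool.

    The background pool is subsampled to the event-pool size per run (the
    class ratio is otherwise unconstrained), a stratified half of the data
    is held out for validation accuracy, and the final model is refit on
    the training half.  A validation accuracy below 0.6 is flagged in
    metadata rather than raised.
    """
    rng = np.random.default_rng(seed)
    ev = np.flatnonzero(train_set.labels == EVENT)
    bg = np.flatnonzero(train_set.labels == BACKGROUND)
    if bg.size > ev.size:
        bg = rng.choice(bg, size=ev.size, replace=False)
    keep = np.sort(np.concatenate([ev, bg]))
    balanced = TrainingSet(train_set.features[keep], train_set.labels[keep],
                           train_set.event_kind)

    if val_fraction:
        tr, va = split_train_val(balanced, fraction=1.0 - val_fraction,
                                 seed=seed)
    else:
        tr, va = balanced, None
    est = _make_estimator(backbone, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter
        est.fit(tr.features, tr.labels)
    val_acc = float(np.mean(est.predict(va.features) == va.labels)) \
        if va is not None and va.labels.size else None

    meta = {
        "seed": seed,
        "backbone": backbone,
        "val_accuracy": val_acc,
        "n_event": balanced.n_event,
        "n_background": balanced.n_background,
        "correction_iteration": 0,
        "converged": val_acc is None or val_acc >= 0.6,
    }
    if val_acc is not None and val_acc < 0.6:
        logger.warning("detector validation accuracy %.2f < 0.6", val_acc)
    return ClassifierModel(est, train_set.event_kind, threshold=threshold,
                           backbone=backbone, feature_config=cfg,
                           pools=train_set, metadata=meta)


def classify_segments(model: ClassifierModel,
                      epochs: list[Epoch],
                      features: np.ndarray | None = None,
                      ) -> list[SegmentPrediction]:
    """Order-preserving per-epoch predictions under the threshold rule.

    ``features`` may carry precomputed feature rows for the same epochs;
    otherwise features are extracted with the model's feature config.
    """
    if not epochs:
        return []
    if features is None:
        features = np.stack([epoch_features(ep, model.feature_config)
                             for ep in epochs])
    if features.shape[1] != model.feature_config.n_features:
        raise ValueError(
            f"feature size {features.shape[1]} does not match the model's "
            f"expected {model.feature_config.n_features}")
    conf = model.event_posterior(features)
    return [
        SegmentPrediction(ep.subject_id, ep.interval_index, ep.epoch_index,
                          ep.start_s,
                          EVENT if c > model.threshold else BACKGROUND,
                          float(c))
        for ep, c in zip(epochs, conf)
    ]


def retrain_with_corrections(model: ClassifierModel,
                             false_positive_features: np.ndarray | None,
                             missed_event_features: np.ndarray | None,
                             seed: int | None = None) -> ClassifierModel:
    """Append review corrections to the class pools and retrain.

    False positives join the background pool, missed events the event
    pool.  Empty corrections return the input model unchanged.
    """
    n_fp = 0 if false_positive_features is None else len(false_positive_features)
    n_miss = 0 if missed_event_features is None else len(missed_event_features)
    if n_fp == 0 and n_miss == 0:
        return model
    if model.pools is None:
        raise ValueError("model carries no training pools to extend")
    X = [model.pools.features]
    y = [model.pools.labels]
    if n_fp:
        X.append(np.asarray(false_positive_features, dtype=np.float32))
        y.append(np.array([BACKGROUND] * n_fp))
    if n_miss:
        X.append(np.asarray(missed_event_features, dtype=np.float32))
        y.append(np.array([EVENT] * n_miss))
    pools = TrainingSet(np.concatenate(X), np.concatenate(y),
                        model.pools.event_kind,
                        provenance=list(model.pools.provenance))
    new = train(pools, backbone=model.backbone, threshold=model.threshold,
                seed=model.metadata.get("seed", 0) if seed is None else seed,
                cfg=model.feature_config)
    new.metadata["correction_iteration"] = \
        model.metadata.get("correction_iteration", 0) + 1
    return new


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalMetrics:
    sensitivity: float           # detected events / annotated events
    specificity: float           # correctly-background epochs / background epochs
    fp_count: int                # event-labeled epochs overlapping nothing
    n_events: int
    n_detected: int


def evaluate(predictions: list[SegmentPrediction],
             annotations: list[EventAnnotation],
             event_kind: str,
             tolerance: float = 0.0) -> EvalMetrics:
    """Event-level sensitivity and segment-level specificity.

    An annotated event counts as detected iff at least one epoch
    overlapping its span is labeled event.  A false positive is an
    event-labeled epoch overlapping no annotation of any class (padded by
    ``tolerance`` seconds).  Raises if predictions and annotations name
    disjoint subjects.
    """
    pred_subjects = {p.subject_id for p in predictions}
    ann_subjects = {a.subject_id for a in annotations}
    if annotations and predictions and not (pred_subjects & ann_subjects):
        raise ValueError(
            f"predictions cover subjects {sorted(pred_subjects)} but "
            f"annotations cover {sorted(ann_subjects)}")

    events = [(sid, s, e) for sid, s, e in _event_spans(annotations, event_kind)]
    any_spans: dict[str, list[tuple[float, float]]] = {}
    for a in annotations:
        any_spans.setdefault(a.subject_id, []).append(
            (a.start_s - tolerance, a.end_s + tolerance))

    detected = 0
    for sid, s, e in events:
        hit = any(p.label == EVENT and p.subject_id == sid
                  and p.start_s < e and p.start_s + EPOCH_S > s
                  for p in predictions)
        detected += bool(hit)

    fp = 0
    n_bg = 0
    bg_correct = 0
    for p in predictions:
        spans = any_spans.get(p.subject_id, [])
        is_bg_epoch = not _overlaps(p.start_s, p.start_s + EPOCH_S, spans)
        if is_bg_epoch:
            n_bg += 1
            if p.label == BACKGROUND:
                bg_correct += 1
            else:
                fp += 1
    return EvalMetrics(
        sensitivity=detected / len(events) if events else float("nan"),
        specificity=bg_correct / n_bg if n_bg else float("nan"),
        fp_count=fp, n_events=len(events), n_detected=detected)


def oracle_predictions(subject: SubjectData, event_kind: str,
                       epoch_s: float = EPOCH_S) -> list[SegmentPrediction]:
    """Perfect ground-truth detections, one per epoch of every interval.

    The classifier-free fast path used by statistics-only experiments: an
    epoch is labeled event iff it overlaps an annotated event span of the
    requested kind.
    """
    spans = [(s, e) for sid, s, e in
             _event_spans(subject.annotations, event_kind)]
    preds: list[SegmentPrediction] = []
    n_per_interval = int(round(1800.0 / epoch_s))
    for iv in subject.intervals:
        for k in range(n_per_interval):
            start = iv.start_s + k * epoch_s
            hit = _overlaps(start, start + epoch_s, spans)
            preds.append(SegmentPrediction(
                subject.subject_id, iv.index, k, start,
                EVENT if hit else BACKGROUND, 1.0 if hit else 0.0))
    return preds


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------

def save_model(model: ClassifierModel, path: str | Path) -> None:
    """Checkpoint the estimator with a JSON metadata sidecar."""
    path = Path(path)
    joblib.dump({"estimator": model.estimator, "pools": model.pools,
                 "feature_config": model.feature_config}, path)
    sidecar = {
        "event_kind": model.event_kind,
        "threshold": model.threshold,
        "backbone": model.backbone,
        **model.metadata,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> ClassifierModel:
    path = Path(path)
    blob = joblib.load(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ClassifierModel(
        blob["estimator"], meta.pop("event_kind"),
        threshold=meta.pop("threshold"), backbone=meta.pop("backbone"),
        feature_config=blob["feature_config"], pools=blob["pools"],
        metadata=meta)
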