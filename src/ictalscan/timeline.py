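"""Aggregation of per-epoch detections into post-implant timelines.

Detected event time is epoch-granular: every event-labeled 10 s epoch
contributes its full 10 s, so an interval's total detected duration is a
multiple of 10 with a ceiling of 1800 s (180 epochs per 0.5 h interval).
Maximal consecutive blocks of event-labeled epochs are *runs*; an interval
with several separated runs held several events (or one event split by a
mid-ictal depression epoch the detector rightly left unlabeled — an
optional merge across single-epoch gaps covers that reading).

Timelines index interval totals by post-implant latency in days.  Events
at latency ≤ 5 d are "early"; later events are "late", and at least one
late detection (by default) classifies a subject as having developed
post-traumatic epilepsy (PTE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import EVENT, SegmentPrediction
from .synthetic import EARLY_LATE_BOUNDARY_DAYS, INTERVAL_S

__all__ = [
    "DetectionRun",
    "TimelineEntry",
    "DetectionTimeline",
    "DurationSummary",
    "aggregate_interval",
    "build_timeline",
    "classify_latency",
    "summarize_detection_durations",
    "pte_status",
    "plot_timeline",
    "timeline_to_frame",
]

EPOCH_S = 10.0


@dataclass(frozen=True)
class DetectionRun:
    """A maximal block of consecutive event-labeled epochs."""

    interval_index: int
    first_epoch: int
    last_epoch: int

    @property
    def n_epochs(self) -> int:
        return self.last_epoch - self.first_epoch + 1

    @property
    def duration_s(self) -> float:
        return self.n_epochs * EPOCH_S


@dataclass(frozen=True)
class TimelineEntry:
    interval_index: int
    latency_days: float
    total_detected_s: float
    n_runs: int


@dataclass
class DetectionTimeline:
    subject_id: str
    event_kind: str
    entries: list[TimelineEntry] = field(default_factory=list)

    @property
    def total_s(self) -> float:
        return sum(e.total_detected_s for e in self.entries)

    def late_entries(self) -> list[TimelineEntry]:
        return [e for e in self.entries
                if classify_latency(e.latency_days) == "late"]


def aggregate_interval(predictions: list[SegmentPrediction],
                       merge_gap_epochs: int = 0,
                       ) -> tuple[float, list[DetectionRun]]:
    """Total detected seconds and detection runs for one interval.

    ``total = 10 s × (number of event-labeled epochs)``.  With
    ``merge_gap_epochs > 0`` runs separated by at most that many
    unlabeled epochs are merged into one run (an option for counting
    MID-split seizures as single events); merging never changes the total.
    """
    if not predictions:
        return 0.0, []
    idx = [p.epoch_index for p in predictions]
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate epoch indices in interval predictions")
    if len(idx) > int(INTERVAL_S / EPOCH_S):
        raise ValueError("more predictions than epochs in a 0.5 h interval")
    interval_index = predictions[0].interval_index
    hits = sorted(p.epoch_index for p in predictions if p.label == EVENT)
    total = len(hits) * EPOCH_S
    runs: list[DetectionRun] = []
    for k in hits:
        if runs and k - runs[-1].last_epoch <= 1 + merge_gap_epochs:
            runs[-1] = DetectionRun(interval_index, runs[-1].first_epoch, k)
        else:
            runs.append(DetectionRun(interval_index, k, k))
    return total, runs


def build_timeline(predictions: list[SegmentPrediction],
                   latency_map: dict[int, float],
                   event_kind: str = "seizure",
                   merge_gap_epochs: int = 0) -> DetectionTimeline:
    """Per-interval totals indexed by post-implant latency.

    One entry per interval with a nonzero total, sorted by latency;
    ``n_runs ≥ 2`` flags multi-event (cluster) intervals.  Every interval
    seen in the predictions must have a latency, else ``KeyError``.
    """
    if not predictions:
        return DetectionTimeline("", event_kind)
    subject_id = predictions[0].subject_id
    by_interval: dict[int, list[SegmentPrediction]] = {}
    for p in predictions:
        by_interval.setdefault(p.interval_index, []).append(p)

    entries = []
    for iv, preds in by_interval.items():
        if iv not in latency_map:
            raise KeyError(f"no post-implant latency for interval {iv}")
        total, runs = aggregate_interval(preds, merge_gap_epochs)
        if total > 0:
            entries.append(TimelineEntry(iv, latency_map[iv], total,
                                         len(runs)))
    entries.sort(key=lambda e: e.latency_days)
    return DetectionTimeline(subject_id, event_kind, entries)


def classify_latency(latency_days: float) -> str:
    """"early" iff the latency is ≤ 5 days post-implant, else "late"."""
    if latency_days < 0:
        raise ValueError(f"negative post-implant latency: {latency_days}")
    return "early" if latency_days <= EARLY_LATE_BOUNDARY_DAYS else "late"


@dataclass(frozen=True)
class DurationSummary:
    mean_s: float
    sem_s: float
    n: int
    sem_defined: bool


def summarize_detection_durations(
        timelines: DetectionTimeline | list[DetectionTimeline],
        ) -> DurationSummary:
    """Mean ± SEM of per-interval detected seconds over nonzero intervals.

    Averages over intervals *with detections* (the per-rat "average seizure
    time per 0.5 h interval" summary).  A single interval gives SEM 0 with
    ``sem_defined=False``; no intervals at all raises.
    """
    if isinstance(timelines, DetectionTimeline):
        timelines = [timelines]
    vals = np.array([e.total_detected_s
                     for tl in timelines for e in tl.entries])
    if vals.size == 0:
        raise ValueError("no intervals with detections to summarize")
    if vals.size == 1:
        return DurationSummary(float(vals[0]), 0.0, 1, sem_defined=False)
    sem = float(np.std(vals, ddof=1) / np.sqrt(vals.size))
    return DurationSummary(float(vals.mean()), sem, int(vals.size),
                           sem_defined=True)


def pte_status(timeline: DetectionTimeline, threshold_late: int = 1) -> bool:
    """PTE iff the subject shows at least ``threshold_late`` late detections.

    Late detection runs (latency > 5 d) are counted; the default inclusive
    rule (a single late event suffices) mirrors the study's definition,
    which admitted subjects with only one spontaneous late seizure.
    """
    n_late = sum(e.n_runs for e in timeline.late_entries())
    return n_late >= threshold_late


def plot_timeline(timeline: DetectionTimeline, path=None, ax=None):
    """Vertical-line detection timeline: one line per interval with
    detections, height = total detected seconds, x = post-implant days."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(7, 2.5))
    for e in timeline.entries:
        ax.vlines(e.latency_days, 0, e.total_detected_s,
                  colors="k" if e.n_runs == 1 else "r", linewidths=1.2)
    ax.set_xlabel("post-implant latency (d)")
    ax.set_ylabel("detected s / 0.5 h")
    ax.set_title(f"{timeline.subject_id} ({timeline.event_kind})")
    ax.set_ylim(bottom=0)
    if path is not None:
        ax.figure.tight_layout()
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax


def timeline_to_frame(timelines: list[DetectionTimeline]) -> pd.DataFrame:
    """Tidy export: subject_id, interval_index, latency_days, total, runs."""
    rows = [
        {"subject_id": tl.subject_id, "interval_index": e.interval_index,
         "latency_days": e.latency_days,
         "total_detected_s": e.total_detected_s, "n_runs": e.n_runs}
        for tl in timelines for e in tl.entries
    ]
    return pd.DataFrame(rows, columns=["subject_id", "interval_index",
                                       "latency_days", "total_detected_s",
                                       "n_runs"])
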