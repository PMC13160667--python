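"""Interval aggregation, timelines, latency classes, PTE status."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ictalscan.classify import BACKGROUND, EVENT, SegmentPrediction
from ictalscan.timeline import (
    DetectionTimeline,
    TimelineEntry,
    aggregate_interval,
    build_timeline,
    classify_latency,
    pte_status,
    summarize_detection_durations,
    timeline_to_frame,
)


def preds_with_events(event_epochs, n=180, interval=0, subject="S"):
    return [SegmentPrediction(subject, interval, k, k * 10.0,
                              EVENT if k in event_epochs else BACKGROUND,
                              1.0 if k in event_epochs else 0.0)
            for k in range(n)]


class TestAggregate:
    def test_ten_event_epochs_give_100_seconds(self):
        total, runs = aggregate_interval(preds_with_events(set(range(10, 20))))
        assert total == 100.0
        assert len(runs) == 1

    def test_no_events(self):
        total, runs = aggregate_interval(preds_with_events(set()))
        assert total == 0.0 and runs == []

    def test_two_separated_runs(self):
        total, runs = aggregate_interval(preds_with_events({3, 4, 5, 90, 91}))
        assert total == 50.0
        assert [(r.first_epoch, r.last_epoch) for r in runs] == \
            [(3, 5), (90, 91)]

    def test_duplicate_epochs_rejected(self):
        preds = preds_with_events(set()) + preds_with_events(set())[:1]
        with pytest.raises(ValueError, match="duplicate"):
            aggregate_interval(preds)

    def test_merge_gap_option_preserves_total(self):
        total0, runs0 = aggregate_interval(preds_with_events({3, 5}))
        total1, runs1 = aggregate_interval(preds_with_events({3, 5}),
                                           merge_gap_epochs=1)
        assert total0 == total1 == 20.0
        assert len(runs0) == 2 and len(runs1) == 1

    @given(hits=st.sets(st.integers(min_value=0, max_value=179),
                        max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_run_conservation_and_order_invariance(self, hits):
        preds = preds_with_events(hits)
        total, runs = aggregate_interval(preds)
        assert total == 10.0 * len(hits)
        assert sum(r.n_epochs for r in runs) == len(hits)
        rng = np.random.default_rng(0)
        shuffled = [preds[i] for i in rng.permutation(len(preds))]
        total2, runs2 = aggregate_interval(shuffled)
        assert total2 == total and runs2 == runs


class TestTimeline:
    def test_one_entry_per_interval_with_detections(self):
        preds = []
        latency = {}
        for iv in range(13):
            preds += preds_with_events({5}, interval=iv)
            latency[iv] = 100.0 + iv
        for iv in range(13, 16):
            preds += preds_with_events(set(), interval=iv)
            latency[iv] = 100.0 + iv
        tl = build_timeline(preds, latency)
        assert len(tl.entries) == 13
        assert [e.latency_days for e in tl.entries] == \
            sorted(e.latency_days for e in tl.entries)

    def test_no_detections_empty_timeline(self):
        tl = build_timeline(preds_with_events(set()), {0: 1.0})
        assert tl.entries == []

    def test_cluster_interval_flags_three_runs(self):
        preds = preds_with_events({3, 50, 51, 120}, interval=2)
        tl = build_timeline(preds, {2: 8.0})
        assert tl.entries[0].n_runs == 3

    def test_missing_latency_raises(self):
        with pytest.raises(KeyError):
            build_timeline(preds_with_events({1}), {})

    def test_plot_renders_to_file(self, tmp_path):
        from ictalscan.timeline import plot_timeline

        tl = build_timeline(preds_with_events({1, 2, 50}), {0: 2.0})
        out = tmp_path / "tl.png"
        plot_timeline(tl, path=out)
        assert out.stat().st_size > 0

    def test_export_frame_columns(self):
        tl = build_timeline(preds_with_events({1}), {0: 2.0})
        df = timeline_to_frame([tl])
        assert list(df.columns) == ["subject_id", "interval_index",
                                    "latency_days", "total_detected_s",
                                    "n_runs"]
        assert df.iloc[0]["total_detected_s"] == 10.0


class TestLatencyClass:
    @pytest.mark.parametrize("days,expected", [
        (5.0, "early"), (5.01, "late"), (0.0, "early"), (200.0, "late"),
    ])
    def test_boundary(self, days, expected):
        assert classify_latency(days) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_latency(-0.1)


class TestSummary:
    def _tl(self, totals, latency=1.0):
        entries = [TimelineEntry(i, latency + i, t, 1)
                   for i, t in enumerate(totals)]
        return DetectionTimeline("S", "seizure", entries)

    def test_single_interval_sem_flagged(self):
        s = summarize_detection_durations(self._tl([100.0]))
        assert s.mean_s == 100.0 and s.sem_s == 0.0
        assert not s.sem_defined

    def test_two_intervals_hand_computed(self):
        s = summarize_detection_durations(self._tl([40.0, 60.0]))
        assert s.mean_s == pytest.approx(50.0)
        assert s.sem_s == pytest.approx(10.0)
        assert s.n == 2 and s.sem_defined

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            summarize_detection_durations(self._tl([]))

    def test_subject_average_tracks_generator_target(self, test_subject):
        """Oracle detections on one subject average near the ground-truth
        per-interval seizure seconds (within epoch-boundary slack)."""
        from ictalscan.classify import oracle_predictions
        from ictalscan.synthetic import seizure_events

        preds = oracle_predictions(test_subject, "seizure")
        tl = build_timeline(preds, test_subject.latency_map)
        truth = {}
        n_events = {}
        for _sid, iv, s, e in seizure_events(test_subject.annotations):
            truth[iv] = truth.get(iv, 0.0) + (e - s)
            n_events[iv] = n_events.get(iv, 0) + 1
        for entry in tl.entries:
            iv = entry.interval_index
            # two boundary epochs of slack per event in the interval
            assert abs(entry.total_detected_s - truth[iv]) \
                <= 20.0 * n_events[iv]


class TestPTE:
    def _tl(self, latencies):
        entries = [TimelineEntry(i, d, 30.0, 1)
                   for i, d in enumerate(latencies)]
        return DetectionTimeline("S", "seizure", entries)

    def test_single_late_run_confers_pte(self):
        assert pte_status(self._tl([120.0]))

    def test_only_early_runs_do_not(self):
        assert not pte_status(self._tl([0.5, 2.0, 4.9]))

    def test_threshold_parameter(self):
        tl = self._tl([10.0, 50.0])
        assert pte_status(tl, threshold_late=2)
        assert not pte_status(tl, threshold_late=3)
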