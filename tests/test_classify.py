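"""Detector contracts: splits, training, thresholding, correction loop."""

import numpy as np
import pytest

from ictalscan.classify import (
    BACKGROUND,
    EVENT,
    SegmentPrediction,
    TrainingSet,
    classify_segments,
    evaluate,
    oracle_predictions,
    retrain_with_corrections,
    split_train_val,
    train,
)
from ictalscan.experiments import detect_subject
from ictalscan.scalogram import FeatureConfig
from ictalscan.synthetic import EventAnnotation


def toy_training_set(n_per_class=30, n_features=64, seed=0,
                     separation=1.0):
    """Linearly separable 'bright vs dark' feature images."""
    rng = np.random.default_rng(seed)
    bright = rng.uniform(0.6, 1.0, size=(n_per_class, n_features))
    dark = rng.uniform(0.0, 0.4 * separation, size=(n_per_class, n_features))
    X = np.concatenate([bright, dark]).astype(np.float32)
    y = np.array([EVENT] * n_per_class + [BACKGROUND] * n_per_class)
    return TrainingSet(X, y, "seizure")


class TestSplit:
    def test_half_split_is_stratified(self):
        ts = toy_training_set(30)
        tr, va = split_train_val(ts, fraction=0.5, seed=1)
        assert tr.n_event == tr.n_background == 15
        assert va.n_event == va.n_background == 15

    def test_full_fraction_warns_empty_validation(self):
        ts = toy_training_set(5)
        with pytest.warns(UserWarning):
            _tr, va = split_train_val(ts, fraction=1.0, seed=1)
        assert va.labels.size == 0

    def test_same_seed_same_partition(self):
        ts = toy_training_set(20)
        a = split_train_val(ts, seed=7)
        b = split_train_val(ts, seed=7)
        np.testing.assert_array_equal(a[0].features, b[0].features)
        np.testing.assert_array_equal(a[1].features, b[1].features)

    def test_tiny_class_rejected(self):
        X = np.zeros((3, 4), dtype=np.float32)
        y = np.array([EVENT, EVENT, BACKGROUND])
        with pytest.raises(ValueError):
            split_train_val(TrainingSet(X, y, "seizure"))


class TestTrain:
    def test_separable_toy_reaches_perfect_validation(self):
        model = train(toy_training_set(30), seed=0)
        assert model.metadata["val_accuracy"] == 1.0
        assert model.metadata["converged"]

    def test_identical_seed_and_data_identical_weights(self):
        ts = toy_training_set(20)
        m1 = train(ts, seed=3)
        m2 = train(ts, seed=3)
        for w1, w2 in zip(m1.estimator.coefs_, m2.estimator.coefs_):
            np.testing.assert_array_equal(w1, w2)

    def test_threshold_bounds_enforced(self):
        with pytest.raises(ValueError):
            train(toy_training_set(10), threshold=0.4, seed=0)

    def test_synthetic_seizure_set_validates_well(self, seizure_model):
        assert seizure_model.metadata["val_accuracy"] >= 0.9


class TestClassify:
    def test_one_prediction_per_epoch_in_order(self, seizure_model,
                                               test_subject):
        from ictalscan.scalogram import segment_record

        idx = sorted(test_subject.records)[0]
        epochs = segment_record(test_subject.records[idx], interval_index=idx)
        preds = classify_segments(seizure_model, epochs)
        assert len(preds) == 180
        assert [p.epoch_index for p in preds] == list(range(180))
        assert all(0.0 <= p.confidence <= 1.0 for p in preds)
        assert all((p.label == EVENT) == (p.confidence >
                                          seizure_model.threshold)
                   for p in preds)

    def test_feature_size_mismatch_rejected(self, seizure_model):
        from ictalscan.scalogram import Epoch

        ep = Epoch("x", 0, 0, np.zeros(5000, dtype=np.float32), 0.0, 500.0)
        bad = np.zeros((1, 10), dtype=np.float32)
        with pytest.raises(ValueError, match="feature size"):
            classify_segments(seizure_model, [ep], features=bad)

    def test_lowering_threshold_never_shrinks_detections(self, seizure_model,
                                                         test_subject):
        import copy

        preds_hi = detect_subject(test_subject, seizure_model)
        lo_model = copy.copy(seizure_model)
        lo_model.threshold = 0.8
        preds_lo = detect_subject(test_subject, lo_model)
        hi = {(p.interval_index, p.epoch_index)
              for p in preds_hi if p.label == EVENT}
        lo = {(p.interval_index, p.epoch_index)
              for p in preds_lo if p.label == EVENT}
        assert hi <= lo

    def test_partial_epoch_still_detected(self, seizure_model, test_subject):
        """Epochs with ~half-epoch seizure content are flagged as events."""
        from ictalscan.classify import _event_spans, _overlap_s

        preds = detect_subject(test_subject, seizure_model)
        spans = [(s, e) for _sid, s, e in
                 _event_spans(test_subject.annotations, "seizure",
                              spiking_only=True)]
        partial = [p for p in preds
                   if 4.0 <= _overlap_s(p.start_s, p.start_s + 10.0,
                                        spans) <= 6.0]
        assert partial, "expected at least one ~half-covered epoch"
        assert any(p.label == EVENT for p in partial)


class TestCorrectionLoop:
    def test_pools_grow_by_corrections(self, seizure_model):
        n_bg = seizure_model.pools.n_background
        fp = np.zeros((8, seizure_model.pools.features.shape[1]),
                      dtype=np.float32)
        new = retrain_with_corrections(seizure_model, fp, None)
        assert new.pools.n_background == n_bg + 8
        assert new.metadata["correction_iteration"] == 1

    def test_empty_corrections_is_identity(self, seizure_model):
        assert retrain_with_corrections(seizure_model, None, None) \
            is seizure_model


class TestEvaluate:
    def _preds(self, labels, subject="S"):
        return [SegmentPrediction(subject, 0, k, k * 10.0, lab,
                                  1.0 if lab == EVENT else 0.0)
                for k, lab in enumerate(labels)]

    def _ann(self, start, dur, subject="S"):
        return EventAnnotation(subject, "swd", "whole", start, dur, 0, 0)

    def test_perfect_predictions(self):
        anns = [self._ann(15.0, 10.0)]
        labels = [BACKGROUND] * 18
        labels[1] = labels[2] = EVENT
        m = evaluate(self._preds(labels), anns, "swd")
        assert m.sensitivity == 1.0 and m.fp_count == 0
        assert m.specificity == 1.0

    def test_all_background_predictions(self):
        anns = [self._ann(15.0, 10.0)]
        m = evaluate(self._preds([BACKGROUND] * 18), anns, "swd")
        assert m.sensitivity == 0.0

    def test_two_of_three_events_detected(self):
        anns = [self._ann(5.0, 4.0), self._ann(45.0, 4.0),
                self._ann(95.0, 4.0)]
        labels = [BACKGROUND] * 18
        labels[0] = EVENT      # covers event 1
        labels[4] = EVENT      # covers event 2; event 3 missed
        m = evaluate(self._preds(labels), anns, "swd")
        assert m.sensitivity == pytest.approx(2 / 3)
        assert m.fp_count == 0

    def test_false_positive_counted(self):
        anns = [self._ann(5.0, 4.0)]
        labels = [BACKGROUND] * 18
        labels[0] = EVENT
        labels[10] = EVENT     # overlaps nothing
        m = evaluate(self._preds(labels), anns, "swd")
        assert m.fp_count == 1

    def test_disjoint_subjects_rejected(self):
        anns = [self._ann(5.0, 4.0, subject="A")]
        with pytest.raises(ValueError):
            evaluate(self._preds([EVENT], subject="B"), anns, "swd")

    def test_oracle_predictions_score_perfectly(self, test_subject):
        for kind in ("seizure", "swd"):
            preds = oracle_predictions(test_subject, kind)
            m = evaluate(preds, test_subject.annotations, kind)
            assert m.sensitivity == 1.0
            assert m.fp_count == 0
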