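"""Generator contracts: waveform morphology, scheduling, reproducibility."""

import numpy as np
import pytest

from ictalscan.synthetic import (
    CohortConfig,
    EARLY_SEIZURE_PARAMS,
    EventAnnotation,
    ICTAL_PHASES,
    INTERVAL_S,
    SeizureParams,
    SubjectProfile,
    SWDParams,
    gen_background,
    gen_cohort,
    gen_seizure,
    gen_subject,
    gen_swd,
    seizure_events,
    seizure_phase_plan,
)


class TestBackground:
    def test_sample_count_and_determinism(self):
        x1 = gen_background(1800.0, 500.0, seed=1)
        x2 = gen_background(1800.0, 500.0, seed=1)
        assert x1.size == 900_000
        np.testing.assert_array_equal(x1, x2)

    def test_rms_is_stationary(self):
        x = gen_background(1800.0, 500.0, seed=2)
        w1 = x[: 30_000]                    # first 60 s
        w2 = x[-30_000:]                    # last 60 s
        r1 = np.sqrt(np.mean(w1.astype(float) ** 2))
        r2 = np.sqrt(np.mean(w2.astype(float) ** 2))
        assert abs(r1 - r2) / r1 < 0.20

    def test_rms_matches_request(self):
        x = gen_background(600.0, 500.0, seed=3, rms_uv=50.0)
        assert np.sqrt(np.mean(x.astype(float) ** 2)) == pytest.approx(50.0,
                                                                       rel=1e-3)

    def test_power_decays_with_frequency(self):
        x = gen_background(600.0, 500.0, seed=4)
        spec = np.abs(np.fft.rfft(x.astype(float))) ** 2
        freqs = np.fft.rfftfreq(x.size, 1 / 500.0)
        low = spec[(freqs > 1) & (freqs < 5)].mean()
        high = spec[(freqs > 50) & (freqs < 90)].mean()
        assert low > 5 * high

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            gen_background(0.0, 500.0, seed=1)


class TestSeizure:
    def test_phase_order_with_mid(self):
        params = SeizureParams(p_mid=1.0)
        _, phases = gen_seizure(params, 50.0, seed=5)
        names = [p[0] for p in phases]
        assert names[:4] == ["sz_onset", "mid", "sz_end", "pid"]

    def test_without_mid_duration_is_onset_alone(self):
        params = SeizureParams(p_mid=0.0)
        _, phases = gen_seizure(params, 50.0, seed=6)
        names = [p[0] for p in phases]
        assert "mid" not in names and "sz_end" not in names
        ictal = sum(d for n, _s, d in phases if n in ICTAL_PHASES)
        onset = next(d for n, _s, d in phases if n == "sz_onset")
        assert ictal == pytest.approx(onset)

    def test_phases_tile_contiguously(self):
        wav, phases = gen_seizure(SeizureParams(p_mid=1.0), 50.0, seed=7)
        t = 0.0
        for _name, start, dur in phases:
            assert start == pytest.approx(t)
            t += dur
        assert wav.size / 500.0 == pytest.approx(t, abs=0.02)

    def test_mid_durations_within_bounds(self):
        params = SeizureParams(p_mid=1.0)
        rng = np.random.default_rng(8)
        mids = []
        for _ in range(1000):
            plan = seizure_phase_plan(params, rng)
            mids.append(next(d for n, _s, d in plan if n == "mid"))
        assert min(mids) >= 10.0 and max(mids) <= 180.0

    def test_peak_amplitude_exceeds_threshold(self):
        bg_rms = 50.0
        for seed in range(5):
            wav, _ = gen_seizure(EARLY_SEIZURE_PARAMS, bg_rms, seed=seed)
            assert np.max(np.abs(wav)) > EARLY_SEIZURE_PARAMS.amp_factor * bg_rms

    def test_onset_spectrum_concentrates_below_20hz(self):
        wav, phases = gen_seizure(SeizureParams(p_mid=0.0,
                                                burst_after=False),
                                  50.0, seed=9)
        onset_n = int(phases[0][2] * 500)
        spec = np.abs(np.fft.rfft(wav[:onset_n].astype(float))) ** 2
        freqs = np.fft.rfftfreq(onset_n, 1 / 500.0)
        inband = spec[(freqs >= 1) & (freqs <= 20)].sum()
        assert inband / spec[freqs >= 1].sum() > 0.5

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SeizureParams(amp_factor=1.5)
        with pytest.raises(ValueError):
            SeizureParams(onset_freq_range=(0.5, 10.0))
        with pytest.raises(ValueError):
            SeizureParams(mid_range_s=(5.0, 180.0))


class TestSWD:
    def test_spectral_peak_at_f0(self):
        wav = gen_swd(SWDParams(), seed=1, f0=9.0, duration_s=10.0)
        spec = np.abs(np.fft.rfft(wav.astype(float)))
        freqs = np.fft.rfftfreq(wav.size, 1 / 500.0)
        peak = freqs[spec.argmax()]
        assert peak == pytest.approx(9.0, abs=0.2)

    def test_peaks_always_in_band(self):
        params = SWDParams()
        for seed in range(40):
            wav = gen_swd(params, seed=seed)
            spec = np.abs(np.fft.rfft(wav.astype(float)))
            freqs = np.fft.rfftfreq(wav.size, 1 / 500.0)
            assert 6.8 <= freqs[spec.argmax()] <= 12.2

    def test_zero_envelope_depth_gives_constant_amplitude(self):
        wav = gen_swd(SWDParams(envelope=(0.0, 3.0)), seed=2, f0=10.0,
                      duration_s=10.0)
        # per-second peak amplitudes stationary after the onset ramp
        peaks = [np.abs(wav[i * 500:(i + 1) * 500]).max() for i in range(1, 10)]
        assert (max(peaks) - min(peaks)) / max(peaks) < 0.05

    def test_sudden_onset(self):
        wav = gen_swd(SWDParams(envelope=(0.0, 3.0)), seed=3, f0=10.0,
                      duration_s=10.0)
        first_cycle = np.abs(wav[:50]).max()        # one 10 Hz cycle
        assert first_cycle > 0.8 * np.abs(wav).max()

    def test_duration_bounds_validated(self):
        with pytest.raises(ValueError):
            SWDParams(dur_range_s=(1.0, 70.0))
        with pytest.raises(ValueError):
            SWDParams(f0_range=(5.0, 12.0))


class TestSubject:
    def test_early_seizures_within_five_days(self):
        profile = SubjectProfile(group="Sham_Stress", has_early=True,
                                 n_early=3)
        subj = gen_subject(profile, n_days=6, intervals_per_day=2, seed=13,
                           waveforms=False)
        events = seizure_events(subj.annotations)
        assert len(events) == 3
        assert all(s / 86400.0 <= 5.0 for _sid, _iv, s, _e in events)

    def test_no_seizures_but_swds_present(self):
        profile = SubjectProfile(group="Sham_noStress")
        subj = gen_subject(profile, n_days=3, intervals_per_day=2, seed=14,
                           waveforms=False)
        assert not seizure_events(subj.annotations)
        assert any(a.klass == "swd" for a in subj.annotations)

    def test_swd_load_reaches_plateau(self):
        profile = SubjectProfile(group="FPI_noStress",
                                 swd_rate_params=(10.0, 100.0, 90.0))
        subj = gen_subject(profile, n_days=91, intervals_per_day=2, seed=15,
                           waveforms=False)
        per_interval = {}
        for a in subj.annotations:
            if a.klass == "swd":
                per_interval.setdefault(a.interval_index, 0.0)
                per_interval[a.interval_index] += a.duration_s
        late_ivs = [iv.index for iv in subj.intervals
                    if iv.latency_days >= 85]
        mean_late = np.mean([per_interval.get(i, 0.0) for i in late_ivs])
        assert mean_late == pytest.approx(100.0, rel=0.25)
        early_ivs = [iv.index for iv in subj.intervals
                     if iv.latency_days <= 2]
        mean_early = np.mean([per_interval.get(i, 0.0) for i in early_ivs])
        assert mean_early < mean_late / 3

    def test_events_lie_within_their_interval(self, train_subject):
        latency = train_subject.latency_map
        for a in train_subject.annotations:
            start = latency[a.interval_index] * 86400.0
            assert a.start_s >= start - 1e-6
            assert a.end_s <= start + INTERVAL_S + 1e-6

    def test_phase_rows_tile_each_seizure(self, train_subject):
        by_event = {}
        for a in train_subject.annotations:
            if a.klass == "seizure":
                by_event.setdefault(a.event_id, []).append(a)
        assert by_event
        for rows in by_event.values():
            rows = sorted(rows, key=lambda a: a.start_s)
            for prev, nxt in zip(rows, rows[1:]):
                assert nxt.start_s == pytest.approx(prev.end_s, abs=1e-6)

    def test_annotations_identical_across_waveform_scopes(self):
        profile = SubjectProfile(group="FPI_Stress", has_early=True,
                                 n_early=2)
        kw = dict(n_days=3, intervals_per_day=1, seed=16, subject_id="X")
        full = gen_subject(profile, waveforms="all", **kw)
        none = gen_subject(profile, waveforms="none", **kw)
        assert full.annotations == none.annotations
        assert not none.records


class TestCohort:
    def test_manifest_counts_and_determinism(self, tmp_path):
        from ictalscan.io import write_annotations_csv

        config = CohortConfig()
        c1 = gen_cohort(config, 7, waveforms=False)
        c2 = gen_cohort(config, 7, waveforms=False)
        assert len(c1.manifest["subjects"]) == 8
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_annotations_csv(c1.annotations, p1)
        write_annotations_csv(c2.annotations, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_late_seizures_only_in_designated_group(self):
        config = CohortConfig(pte_fraction=0.25)
        cohort = gen_cohort(config, 8, waveforms=False)
        for sid, subj in cohort.subjects.items():
            if subj.profile.has_late:
                assert subj.profile.group == "FPI_Stress"
                assert not subj.profile.has_early

    def test_empty_group_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(group_sizes={})

    def test_pte_fraction_needs_room_in_group(self):
        config = CohortConfig(group_sizes={"FPI_Stress": 1,
                                           "Sham_noStress": 7},
                              pte_fraction=0.5)
        with pytest.raises(ValueError):
            gen_cohort(config, 1, waveforms=False)


class TestAnnotationType:
    def test_validation(self):
        with pytest.raises(ValueError):
            EventAnnotation("s", "swd", "mid", 0.0, 1.0)
        with pytest.raises(ValueError):
            EventAnnotation("s", "seizure", "sz_onset", -1.0, 1.0)
        with pytest.raises(ValueError):
            EventAnnotation("s", "seizure", "sz_onset", 0.0, 0.0)
        with pytest.raises(ValueError):
            EventAnnotation("s", "noise", "whole", 0.0, 1.0)
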