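"""Shared fixtures: small synthetic subjects and trained detectors.

Heavy artifacts (subjects with waveforms, trained models) are
session-scoped so the suite generates and trains each of them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from ictalscan.classify import build_training_set, train
from ictalscan.scalogram import Epoch
from ictalscan.synthetic import SubjectProfile, gen_subject


@pytest.fixture(scope="session")
def train_subject():
    """One subject with early seizures and SWDs in every interval."""
    profile = SubjectProfile(group="FPI_Stress", has_early=True, n_early=6)
    return gen_subject(profile, n_days=3, intervals_per_day=2, seed=11,
                       subject_id="TRAIN")


@pytest.fixture(scope="session")
def test_subject():
    """A held-out subject drawn from the same parameter family."""
    profile = SubjectProfile(group="FPI_Stress", has_early=True, n_early=4)
    return gen_subject(profile, n_days=3, intervals_per_day=2, seed=21,
                       subject_id="HELD")


@pytest.fixture(scope="session")
def seizure_model(train_subject):
    ts = build_training_set([train_subject], "seizure", seed=0)
    return train(ts, seed=0)


@pytest.fixture(scope="session")
def swd_model(train_subject):
    ts = build_training_set([train_subject], "swd", seed=0)
    return train(ts, seed=0)


def make_tone_epoch(freq_hz: float, fs: float = 500.0, amp: float = 50.0,
                    duration_s: float = 10.0) -> Epoch:
    t = np.arange(int(duration_s * fs)) / fs
    return Epoch("tone", 0, 0, (amp * np.sin(2 * np.pi * freq_hz * t)
                                ).astype(np.float32), start_s=0.0, fs=fs)


@pytest.fixture
def tone_epoch():
    return make_tone_epoch
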