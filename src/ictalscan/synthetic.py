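"""Synthetic chronic-EEG cohorts with exact ground truth.

Generates single-channel rodent EEG (500 Hz, µV) organised as contiguous
0.5 h storage intervals, with three kinds of embedded events:

* **Convulsive seizures** — large-amplitude repetitive spiking (1–20 Hz)
  whose peak exceeds a configurable multiple (>2) of the background RMS.
  A seizure is a contiguous sequence of phases: seizure onset (``sz_onset``),
  an optional mid-ictal depression (``mid``, 10–180 s of amplitude
  suppression) followed by lower-frequency end spiking (``sz_end``),
  post-ictal depression (``pid``), and an optional inter-ictal multi-spike
  burst (``ied_burst``).  Seizure *duration* in ground truth is the
  onset+mid+end span; depression phases are annotated but are not ictal
  content.
* **Spike-wave discharges (SWDs)** — 7–12 Hz oscillations with asymmetric
  spike-wave cycles (fundamental plus weighted harmonics), sudden onset,
  waxing/waning amplitude, abrupt offset, 3 s to tens of seconds long.
* **Background** — band-limited pink (1/f) noise with stationary RMS.

Subjects belong to a 2×2 design (fluid-percussion injury × pre-injury
stress).  Seizures occurring ≤5 days post-implant are "early"; seizures
after day 5 are "late" and define post-traumatic epilepsy (PTE).  Under
the default configuration only FPI_Stress subjects may carry late
seizures, and subjects with late seizures carry no early ones, mirroring
the observed cohort structure.  SWDs occur in every group; their
per-interval load grows from ~10 s just after implant toward a plateau
(~100 s by day 90).

Everything is a pure function of ``(config, seed)``: per-subject random
streams are derived by hashing the subject id into a ``SeedSequence``, so
cohorts are reproducible and subjects can be generated independently.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GROUPS",
    "EVENT_CLASSES",
    "SEIZURE_PHASES",
    "EARLY_LATE_BOUNDARY_DAYS",
    "INTERVAL_S",
    "EEGRecord",
    "EventAnnotation",
    "SubjectProfile",
    "SeizureParams",
    "SWDParams",
    "CohortConfig",
    "SubjectData",
    "Cohort",
    "EARLY_SEIZURE_PARAMS",
    "LATE_SEIZURE_PARAMS",
    "DEFAULT_SWD_PARAMS",
    "gen_background",
    "gen_seizure",
    "gen_swd",
    "gen_subject",
    "gen_cohort",
    "seizure_events",
    "subject_rng",
]

GROUPS = ("FPI_Stress", "FPI_noStress", "Sham_Stress", "Sham_noStress")
EVENT_CLASSES = ("seizure", "swd", "background_noise")
SEIZURE_PHASES = ("sz_onset", "mid", "sz_end", "pid", "whole", "ied_burst")

#: Seizures at ≤5 days post-implant are "early"; later ones are "late"
#: and define PTE.
EARLY_LATE_BOUNDARY_DAYS = 5.0

#: Storage-interval length in seconds (0.5 h recording blocks).
INTERVAL_S = 1800.0

#: Phases that carry ictal content; their union is the detectable event span
#: and their summed duration is the ground-truth seizure duration.
ICTAL_PHASES = ("sz_onset", "mid", "sz_end")


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class EEGRecord:
    """A continuous single-channel voltage trace for one storage interval.

    ``t0_days`` is the post-implant latency of the first sample, in days;
    implant time is the cohort-wide t = 0.
    """

    subject_id: str
    samples: np.ndarray          # µV, float32
    fs: float = 500.0
    t0_days: float = 0.0
    channel: str = "ECoG"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size == 0:
            raise ValueError("record must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("record contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def start_s(self) -> float:
        """Absolute start time in seconds since implant."""
        return self.t0_days * 86400.0


@dataclass(frozen=True)
class EventAnnotation:
    """One annotated event (or seizure phase).

    ``start_s`` is absolute seconds since implant.  For seizures each phase
    is one row; phases of one seizure share ``event_id`` and are contiguous.
    Non-seizure classes use phase ``"whole"``.
    """

    subject_id: str
    klass: str
    phase: str
    start_s: float
    duration_s: float
    interval_index: int = 0
    event_id: int = 0

    def __post_init__(self) -> None:
        if self.klass not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.klass!r}")
        if self.phase not in SEIZURE_PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.klass != "seizure" and self.phase != "whole":
            raise ValueError("non-seizure annotations must use phase 'whole'")
        if self.start_s < 0:
            raise ValueError("start_s must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def latency_days(self) -> float:
        return self.start_s / 86400.0


@dataclass(frozen=True)
class SubjectProfile:
    """Event schedule for one subject."""

    group: str
    has_early: bool = False
    has_late: bool = False
    n_early: int = 0
    n_late: int = 0
    #: (initial s/interval, plateau s/interval, plateau day) for SWD load.
    swd_rate_params: tuple[float, float, float] = (10.0, 100.0, 90.0)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.n_early < 0 or self.n_late < 0:
            raise ValueError("seizure counts must be >= 0")


@dataclass(frozen=True)
class SeizureParams:
    """Morphology/duration parameters for convulsive seizures.

    Durations are (mean, sd) of truncated normals in seconds.  ``amp_factor``
    is the spike peak amplitude as a multiple of the background RMS and must
    exceed 2 (onset spiking is "approximately >2 times" background).
    """

    onset_freq_range: tuple[float, float] = (6.0, 20.0)
    amp_factor: float = 4.0
    p_mid: float = 0.26
    mid_range_s: tuple[float, float] = (10.0, 180.0)
    onset_dur_s: tuple[float, float] = (38.0, 10.0)
    end_dur_s: tuple[float, float] = (15.0, 6.0)
    pid_dur_s: tuple[float, float] = (20.0, 8.0)
    burst_after: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.onset_freq_range
        if not (1.0 <= lo < hi <= 20.0):
            raise ValueError("onset_freq_range must lie within [1, 20] Hz")
        if self.amp_factor <= 2.0:
            raise ValueError("amp_factor must exceed 2")
        if not (0.0 <= self.p_mid <= 1.0):
            raise ValueError("p_mid must be a probability")
        mlo, mhi = self.mid_range_s
        if not (10.0 <= mlo <= mhi <= 180.0):
            raise ValueError("mid_range_s must lie within [10, 180] s")


@dataclass(frozen=True)
class SWDParams:
    """Morphology parameters for spike-wave discharges."""

    f0_range: tuple[float, float] = (7.0, 12.0)
    dur_range_s: tuple[float, float] = (3.0, 70.0)
    #: (modulation depth in [0, 1), modulation period s) of the
    #: waxing/waning envelope.
    envelope: tuple[float, float] = (0.5, 3.0)
    #: weights of fundamental, 2nd and 3rd harmonic; the phase-offset
    #: harmonics sharpen each cycle into a spike-wave shape.
    harmonic_weights: tuple[float, float, float] = (1.0, 0.45, 0.2)
    #: peak amplitude as a multiple of the background RMS.
    amp_factor: float = 3.0

    def __post_init__(self) -> None:
        lo, hi = self.f0_range
        if not (7.0 <= lo <= hi <= 12.0):
            raise ValueError("f0_range must lie within [7, 12] Hz")
        dlo, dhi = self.dur_range_s
        if dlo < 3.0 or dlo > dhi:
            raise ValueError("SWD durations must be >= 3 s")
        depth, period = self.envelope
        if not (0.0 <= depth < 1.0) or period <= 0:
            raise ValueError("envelope must be (depth in [0,1), period > 0)")


#: Early (≤5 d) seizures are generated shorter than late ones — the cohort's
#: visually measured totals averaged ~52 s early vs ~83 s late — while all
#: other morphology parameters are shared.
EARLY_SEIZURE_PARAMS = SeizureParams(onset_dur_s=(38.0, 10.0))
LATE_SEIZURE_PARAMS = SeizureParams(onset_dur_s=(65.0, 15.0))
DEFAULT_SWD_PARAMS = SWDParams()


@dataclass(frozen=True)
class IntervalInfo:
    index: int
    latency_days: float

    @property
    def start_s(self) -> float:
        return self.latency_days * 86400.0


@dataclass
class SubjectData:
    subject_id: str
    profile: SubjectProfile
    intervals: list[IntervalInfo]
    records: dict[int, EEGRecord]
    annotations: list[EventAnnotation]

    @property
    def latency_map(self) -> dict[int, float]:
        return {iv.index: iv.latency_days for iv in self.intervals}


@dataclass
class Cohort:
    subjects: dict[str, SubjectData]
    manifest: dict

    @property
    def annotations(self) -> list[EventAnnotation]:
        out: list[EventAnnotation] = []
        for sid in sorted(self.subjects):
            out.extend(self.subjects[sid].annotations)
        return out


@dataclass(frozen=True)
class CohortConfig:
    """Scaled cohort layout: a few subjects per group over a few days.

    Defaults keep the full pipeline runnable in minutes; the 61-subject,
    months-long design is reachable by raising the sizes.
    """

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {g: 2 for g in GROUPS}
    )
    n_days: int = 6
    intervals_per_day: int = 2
    fs: float = 500.0
    background_rms_uv: float = 50.0
    #: fraction of the whole cohort that develops PTE (late seizures);
    #: assigned within ``pte_group`` unless overridden.
    pte_fraction: float = 0.125
    pte_group: str = "FPI_Stress"
    early_prob: float = 0.6
    n_early_mean: float = 2.0
    n_late_mean: float = 3.0
    early_params: SeizureParams = EARLY_SEIZURE_PARAMS
    late_params: SeizureParams = LATE_SEIZURE_PARAMS
    swd_params: SWDParams = DEFAULT_SWD_PARAMS
    swd_rate_params: tuple[float, float, float] = (10.0, 100.0, 90.0)

    def __post_init__(self) -> None:
        if not self.group_sizes or sum(self.group_sizes.values()) <= 0:
            raise ValueError("group_sizes must name at least one subject")
        for g in self.group_sizes:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
        if self.n_days <= 0 or self.intervals_per_day <= 0:
            raise ValueError("n_days and intervals_per_day must be positive")
        if not (0.0 <= self.pte_fraction <= 1.0):
            raise ValueError("pte_fraction must be in [0, 1]")


# --------------------------------------------------------------------------
# RNG plumbing
# --------------------------------------------------------------------------

def subject_rng(master_seed: int, subject_id: str) -> np.random.Generator:
    """Per-subject random stream: master seed + stable hash of the id."""
    h = zlib.crc32(subject_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), h]))


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float | None = None) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= lo and (hi is None or x <= hi):
            return float(x)
    return float(np.clip(mean, lo, hi if hi is not None else mean))


# --------------------------------------------------------------------------
# waveform primitives
# --------------------------------------------------------------------------

def gen_background(duration_s: float, fs: float = 500.0,
                   seed: int | np.random.Generator | None = None,
                   rms_uv: float = 50.0,
                   band: tuple[float, float] = (0.5, 100.0)) -> np.ndarray:
    """Band-limited pink (1/f) noise with the requested RMS, in µV.

    Spectral amplitude falls as 1/sqrt(f) inside ``band`` and is zero
    outside, the standard stand-in for rodent cortical background.
    """
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec = (rng.standard_normal(freqs.size)
            + 1j * rng.standard_normal(freqs.size))
    amp = np.zeros_like(freqs)
    inband = (freqs >= band[0]) & (freqs <= band[1])
    amp[inband] = 1.0 / np.sqrt(freqs[inband])
    x = np.fft.irfft(spec * amp, n)
    x *= rms_uv / max(np.sqrt(np.mean(x ** 2)), 1e-30)
    return x.astype(np.float32)


def _spike_kernel(fs: float, sharp_ms: float = 8.0, slow_ms: float = 22.0,
                  lag_ms: float = 30.0) -> np.ndarray:
    """Biphasic sharp transient: difference of two offset Gaussians."""
    half = int(round(0.12 * fs))
    t = np.arange(-half, half + 1) / fs
    k = (np.exp(-0.5 * (t / (sharp_ms / 1000.0)) ** 2)
         - 0.65 * np.exp(-0.5 * ((t - lag_ms / 1000.0) / (slow_ms / 1000.0)) ** 2))
    return (k / np.max(np.abs(k))).astype(np.float64)


def _spike_train(rng: np.random.Generator, duration_s: float, fs: float,
                 freq_range: tuple[float, float], peak_uv: float) -> np.ndarray:
    """Repetitive spiking whose instantaneous rate stays in ``freq_range``."""
    n = int(round(duration_s * fs))
    x = np.zeros(n)
    kern = _spike_kernel(fs)
    t = 0.02 * duration_s
    while t < duration_s:
        i = int(t * fs)
        amp = peak_uv * rng.uniform(1.0, 1.5) * rng.choice([1.0, -1.0], p=[0.85, 0.15])
        lo = min(len(kern), n - i)
        if lo > 0:
            x[i:i + lo] += amp * kern[:lo]
        rate = rng.uniform(*freq_range)
        t += 1.0 / rate
    return x


def gen_seizure(params: SeizureParams, background_rms: float,
                fs: float = 500.0,
                seed: int | np.random.Generator | None = None,
                ) -> tuple[np.ndarray, list[tuple[str, float, float]]]:
    """One convulsive seizure waveform plus its phase annotations.

    Returns ``(waveform, phases)`` where ``phases`` is a list of
    ``(phase_name, start_s, duration_s)`` tuples that tile the waveform
    exactly and in order.  With probability ``p_mid`` the seizure contains
    a mid-ictal depression followed by lower-frequency end spiking;
    otherwise the ictal content is the onset spiking alone.  The waveform
    *replaces* background (suppression phases carry attenuated noise).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    plan = seizure_phase_plan(params, rng)
    peak = params.amp_factor * background_rms

    segs: list[np.ndarray] = []
    for name, _start, dur in plan:
        if name == "sz_onset":
            seg = _spike_train(rng, dur, fs, params.onset_freq_range, peak)
            seg += gen_background(dur, fs, rng, rms_uv=0.8 * background_rms)
            # guarantee the headline amplitude contract
            mx = np.max(np.abs(seg))
            if mx < params.amp_factor * background_rms:
                seg *= 1.05 * params.amp_factor * background_rms / mx
        elif name == "mid":
            seg = gen_background(dur, fs, rng, rms_uv=0.3 * background_rms)
        elif name == "sz_end":
            seg = _spike_train(rng, dur, fs, (1.0, 4.0), 0.9 * peak)
            seg += gen_background(dur, fs, rng, rms_uv=0.8 * background_rms)
        elif name == "pid":
            seg = gen_background(dur, fs, rng, rms_uv=0.2 * background_rms)
        else:  # ied_burst
            seg = _spike_train(rng, dur, fs, (2.0, 4.0), 2.5 * background_rms)
            seg += gen_background(dur, fs, rng, rms_uv=background_rms)
        segs.append(seg)

    # annotations use the planned (exact) durations; sample-grid rounding
    # of each segment differs by at most one sample per phase
    waveform = np.concatenate(segs).astype(np.float32)
    return waveform, plan


def seizure_phase_plan(params: SeizureParams,
                       rng: np.random.Generator,
                       ) -> list[tuple[str, float, float]]:
    """Draw a seizure's phase layout without synthesizing the waveform.

    Consumes the event stream identically to the duration draws at the
    head of :func:`gen_seizure`, so plan and waveform agree for one seed.
    """
    durs: list[tuple[str, float]] = []
    durs.append(("sz_onset", _draw_onset_duration(params, rng)))
    if rng.random() < params.p_mid:
        durs.append(("mid", rng.uniform(*params.mid_range_s)))
        em, es = params.end_dur_s
        durs.append(("sz_end", _truncnorm(rng, em, es, lo=4.0,
                                          hi=em + 4 * es)))
    pm, ps = params.pid_dur_s
    durs.append(("pid", _truncnorm(rng, pm, ps, lo=5.0, hi=pm + 4 * ps)))
    if params.burst_after:
        durs.append(("ied_burst", rng.uniform(1.5, 3.0)))
    plan: list[tuple[str, float, float]] = []
    t = 0.0
    for name, d in durs:
        plan.append((name, t, d))
        t += d
    return plan


def gen_swd(params: SWDParams, fs: float = 500.0,
            seed: int | np.random.Generator | None = None,
            background_rms: float = 50.0,
            f0: float | None = None,
            duration_s: float | None = None) -> np.ndarray:
    """One spike-wave discharge waveform (µV).

    A stable-frequency oscillation (f0 drawn from ``f0_range``) whose
    harmonics give each cycle an asymmetric spike-wave shape.  Amplitude
    reaches full scale within one cycle of onset, waxes and wanes with the
    configured envelope, and stops abruptly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if f0 is None:
        f0 = rng.uniform(*params.f0_range)
    if duration_s is None:
        lo, hi = params.dur_range_s
        duration_s = float(np.clip(rng.lognormal(np.log(12.0), 0.6), lo, hi))
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    w1, w2, w3 = params.harmonic_weights
    x = (w1 * np.cos(2 * np.pi * f0 * t)
         + w2 * np.cos(2 * np.pi * 2 * f0 * t + 0.9)
         + w3 * np.cos(2 * np.pi * 3 * f0 * t + 1.8))
    depth, period = params.envelope
    if depth > 0:
        phase0 = rng.uniform(0, 2 * np.pi)
        env = (1.0 - depth) + depth * 0.5 * (
            1 + np.sin(2 * np.pi * t / period + phase0))
    else:
        env = np.ones(n)
    # full amplitude within one cycle of onset; abrupt offset
    ramp = np.minimum(t * f0, 1.0)
    x *= env * ramp
    x *= params.amp_factor * background_rms / max(np.max(np.abs(x)), 1e-30)
    return x.astype(np.float32)


# --------------------------------------------------------------------------
# scheduling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class _Slot:
    """A planned event inside one interval (offsets in seconds)."""
    interval_index: int
    offset_s: float
    total_dur_s: float
    kind: str                    # "seizure_early" | "seizure_late" | "swd"
    draw_seed: int               # per-event stream for waveform synthesis


def _draw_onset_duration(params: SeizureParams,
                         rng: np.random.Generator) -> float:
    """First stochastic draw of a seizure; shared by synthesis and the
    schedule-time length probe so both replay identically from one seed."""
    m, s = params.onset_dur_s
    return _truncnorm(rng, m, s, lo=8.0, hi=m + 4 * s)


def _seizure_duration_bound(params: SeizureParams,
                            rng: np.random.Generator) -> float:
    """Hard upper bound on the total seizure length for slot reservation.

    Consumes the event stream exactly as far as :func:`gen_seizure`'s first
    draw (the onset duration); the remaining phases are bounded by their
    truncation caps, so the synthesized event always fits its slot.
    """
    onset = _draw_onset_duration(params, rng)
    em, es = params.end_dur_s
    pm, ps = params.pid_dur_s
    bound = onset + params.mid_range_s[1] + (em + 4 * es) + (pm + 4 * ps)
    if params.burst_after:
        bound += 3.0
    return bound


def _swd_target_s(latency_days: float,
                  rate: tuple[float, float, float]) -> float:
    initial, plateau, plateau_day = rate
    frac = min(max(latency_days, 0.0) / plateau_day, 1.0)
    return initial + (plateau - initial) * frac


def _place(rng: np.random.Generator, occupied: list[tuple[float, float]],
           dur: float, interval_s: float = INTERVAL_S,
           margin: float = 5.0, tries: int = 200) -> float | None:
    """Draw a non-overlapping offset for an event of length ``dur``."""
    if dur + 2 * margin >= interval_s:
        return None
    for _ in range(tries):
        off = rng.uniform(margin, interval_s - dur - margin)
        if all(off + dur + margin <= s or off >= e + margin
               for s, e in occupied):
            occupied.append((off, off + dur))
            return off
    # fragmentation fallback: scan the free gaps deterministically
    edges = sorted(occupied)
    cursor = margin
    for s, e in edges + [(interval_s - margin, interval_s)]:
        if s - cursor >= dur + margin:
            off = cursor
            occupied.append((off, off + dur))
            return off
        cursor = max(cursor, e + margin)
    return None


def gen_subject(profile: SubjectProfile, n_days: int, intervals_per_day: int,
                seed: int | np.random.Generator,
                fs: float = 500.0,
                background_rms_uv: float = 50.0,
                early_params: SeizureParams = EARLY_SEIZURE_PARAMS,
                late_params: SeizureParams = LATE_SEIZURE_PARAMS,
                swd_params: SWDParams = DEFAULT_SWD_PARAMS,
                subject_id: str = "S1",
                waveforms: bool | str = True) -> SubjectData:
    """Generate one subject's interval records and exhaustive annotations.

    Intervals are 0.5 h blocks sampled ``intervals_per_day`` times per day
    for ``n_days`` days.  Early seizures land at latencies ≤5 d, late ones
    after day 5; SWD seconds per interval follow the subject's growth
    curve.  ``waveforms`` selects which intervals get synthesized records:
    ``True``/``"all"`` for every interval, ``"seizure"`` for only the
    intervals containing seizures (enough for seizure-detection
    experiments), and ``False``/``"none"`` for the annotation-only fast
    path used by statistics-only replicate studies.  The event schedule
    and annotations are identical in every mode.
    """
    if n_days <= 0:
        raise ValueError("n_days must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    intervals = []
    for d in range(n_days):
        for j in range(intervals_per_day):
            latency = d + (j + 0.35) / intervals_per_day * (1.0 - INTERVAL_S / 86400.0)
            intervals.append(IntervalInfo(index=len(intervals),
                                          latency_days=round(latency, 6)))

    early_iv = [iv for iv in intervals
                if iv.latency_days + INTERVAL_S / 86400.0 <= EARLY_LATE_BOUNDARY_DAYS]
    late_iv = [iv for iv in intervals
               if iv.latency_days > EARLY_LATE_BOUNDARY_DAYS]

    occupied: dict[int, list[tuple[float, float]]] = {iv.index: [] for iv in intervals}
    slots: list[_Slot] = []

    def _schedule_seizures(n: int, pool: list[IntervalInfo],
                           params: SeizureParams, kind: str) -> None:
        if n <= 0:
            return
        if not pool:
            raise ValueError(f"no intervals available for {kind} seizures "
                             f"(n_days={n_days})")
        placed = 0
        for _ in range(n):
            for _ in range(100):
                iv = pool[rng.integers(len(pool))]
                draw_seed = int(rng.integers(2 ** 31))
                probe = np.random.default_rng(draw_seed)
                total = _seizure_duration_bound(params, probe)
                off = _place(rng, occupied[iv.index], total)
                if off is not None:
                    slots.append(_Slot(iv.index, off, total, kind, draw_seed))
                    placed += 1
                    break
            else:
                # capacity exhausted: keep the schedule feasible rather
                # than failing the whole subject, but never drop a kind
                # entirely (PTE status depends on ≥1 late seizure)
                logger.warning("%s: placed %d of %d %s seizures; intervals "
                               "full", subject_id, placed, n, kind)
                break
        if n > 0 and placed == 0:
            raise RuntimeError(
                f"could not place any {kind} seizure for {subject_id}")

    n_early = profile.n_early if profile.has_early else 0
    n_late = profile.n_late if profile.has_late else 0
    _schedule_seizures(n_early, early_iv, early_params, "seizure_early")
    _schedule_seizures(n_late, late_iv, late_params, "seizure_late")

    for iv in intervals:
        target = _swd_target_s(iv.latency_days, profile.swd_rate_params)
        acc = 0.0
        for _ in range(200):
            if acc >= target:
                break
            draw_seed = int(rng.integers(2 ** 31))
            probe = np.random.default_rng(draw_seed)
            dur = _swd_duration(swd_params, probe)
            off = _place(rng, occupied[iv.index], dur)
            if off is None:
                break
            slots.append(_Slot(iv.index, off, dur, "swd", draw_seed))
            acc += dur

    # ---- synthesis + annotations -------------------------------------
    scope = {True: "all", False: "none"}.get(waveforms, waveforms)
    if scope not in ("all", "seizure", "none"):
        raise ValueError(f"unknown waveform scope {waveforms!r}")
    annotations: list[EventAnnotation] = []
    records: dict[int, EEGRecord] = {}
    by_interval: dict[int, list[_Slot]] = {iv.index: [] for iv in intervals}
    for s in slots:
        by_interval[s.interval_index].append(s)
    seizure_ivs = {s.interval_index for s in slots
                   if s.kind.startswith("seizure")}

    event_id = 0
    for iv in intervals:
        iv_slots = sorted(by_interval[iv.index], key=lambda s: s.offset_s)
        synth = scope == "all" or (scope == "seizure"
                                   and iv.index in seizure_ivs)
        # the background seed is drawn for every interval so that a given
        # interval's record is identical under every waveform scope
        bg_seed = int(rng.integers(2 ** 31))
        if synth:
            bg_rng = np.random.default_rng(bg_seed)
            x = gen_background(INTERVAL_S, fs, bg_rng, rms_uv=background_rms_uv)
        for s in iv_slots:
            event_id += 1
            ev_rng = np.random.default_rng(s.draw_seed)
            abs_start = iv.start_s + s.offset_s
            if s.kind == "swd":
                if synth:
                    w = gen_swd(swd_params, fs, ev_rng,
                                background_rms=background_rms_uv)
                    i0 = int(round(s.offset_s * fs))
                    x[i0:i0 + w.size] = w[: x.size - i0]
                annotations.append(EventAnnotation(
                    subject_id, "swd", "whole", abs_start, s.total_dur_s,
                    iv.index, event_id))
            else:
                params = early_params if s.kind == "seizure_early" else late_params
                if synth:
                    w, phases = gen_seizure(params, background_rms_uv, fs,
                                            ev_rng)
                    i0 = int(round(s.offset_s * fs))
                    x[i0:i0 + w.size] = w[: x.size - i0]
                else:
                    phases = seizure_phase_plan(params, ev_rng)
                for name, ph_start, ph_dur in phases:
                    annotations.append(EventAnnotation(
                        subject_id, "seizure", name, abs_start + ph_start,
                        ph_dur, iv.index, event_id))
        if synth:
            records[iv.index] = EEGRecord(subject_id, x, fs=fs,
                                          t0_days=iv.latency_days)

    annotations.sort(key=lambda a: a.start_s)
    return SubjectData(subject_id, profile, intervals, records, annotations)


def _swd_duration(params: SWDParams, rng: np.random.Generator) -> float:
    lo, hi = params.dur_range_s
    # consume draws in gen_swd order: f0 first, then duration
    rng.uniform(*params.f0_range)
    return float(np.clip(rng.lognormal(np.log(12.0), 0.6), lo, hi))


def seizure_events(annotations: Iterable[EventAnnotation],
                   ictal_only: bool = True) -> list[tuple[str, int, float, float]]:
    """Group seizure phase rows into events.

    Returns ``(subject_id, interval_index, start_s, end_s)`` per seizure,
    spanning the ictal phases (onset/mid/end) by default, or all phases
    when ``ictal_only`` is false.
    """
    groups: dict[tuple[str, int], list[EventAnnotation]] = {}
    for a in annotations:
        if a.klass != "seizure":
            continue
        if ictal_only and a.phase not in ICTAL_PHASES:
            continue
        groups.setdefault((a.subject_id, a.event_id), []).append(a)
    out = []
    for (sid, _eid), rows in sorted(groups.items()):
        start = min(r.start_s for r in rows)
        end = max(r.end_s for r in rows)
        out.append((sid, rows[0].interval_index, start, end))
    return out


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

def gen_cohort(config: CohortConfig, seed: int,
               waveforms: bool | str = True) -> Cohort:
    """Generate a full cohort: subjects, records, annotations, manifest.

    Pure function of ``(config, seed)``.  Subjects that develop PTE (late
    seizures) are drawn from ``config.pte_group`` and carry no early
    seizures, matching the observed cohort; other subjects may carry early
    seizures in any group.
    """
    sizes = dict(config.group_sizes)
    master = np.random.default_rng(np.random.SeedSequence([int(seed), 19]))

    subject_ids: list[tuple[str, str]] = []
    for g in GROUPS:
        for k in range(sizes.get(g, 0)):
            subject_ids.append((f"{g}-{k + 1:02d}", g))

    n_total = len(subject_ids)
    n_pte = int(round(config.pte_fraction * n_total))
    pte_pool = [sid for sid, g in subject_ids if g == config.pte_group]
    if n_pte > len(pte_pool):
        raise ValueError(
            f"pte_fraction {config.pte_fraction} needs {n_pte} subjects in "
            f"group {config.pte_group}, which has only {len(pte_pool)}")
    pte_ids = ({str(s) for s in master.choice(pte_pool, size=n_pte, replace=False)}
               if n_pte else set())

    subjects: dict[str, SubjectData] = {}
    for sid, g in subject_ids:
        rng = subject_rng(seed, sid)
        has_late = sid in pte_ids
        has_early = (not has_late) and (rng.random() < config.early_prob)
        n_early = int(1 + rng.poisson(max(config.n_early_mean - 1, 0))) if has_early else 0
        n_late = int(1 + rng.poisson(max(config.n_late_mean - 1, 0))) if has_late else 0
        profile = SubjectProfile(group=g, has_early=has_early,
                                 has_late=has_late, n_early=n_early,
                                 n_late=n_late,
                                 swd_rate_params=config.swd_rate_params)
        subjects[sid] = gen_subject(
            profile, config.n_days, config.intervals_per_day, rng,
            fs=config.fs, background_rms_uv=config.background_rms_uv,
            early_params=config.early_params, late_params=config.late_params,
            swd_params=config.swd_params, subject_id=sid,
            waveforms=waveforms)

    manifest = {
        "seed": int(seed),
        "n_days": config.n_days,
        "intervals_per_day": config.intervals_per_day,
        "fs": config.fs,
        "subjects": [
            {
                "subject_id": sid,
                "group": subjects[sid].profile.group,
                "has_early": subjects[sid].profile.has_early,
                "has_late": subjects[sid].profile.has_late,
                "n_intervals": len(subjects[sid].intervals),
                "n_annotations": len(subjects[sid].annotations),
            }
            for sid, _ in subject_ids
        ],
    }
    return Cohort(subjects=subjects, manifest=manifest)
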