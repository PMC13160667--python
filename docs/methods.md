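# Methods

`ictalscan` models the analysis chain used in long-term rodent epilepsy
monitoring: months of continuous single-channel EEG are screened for two
event families — convulsive seizures and spike-wave discharges (SWDs) —
by an image classifier operating on time–frequency scalograms of fixed
10 s epochs, and the detections are aggregated into per-interval duration
timelines that support cohort-level statistics.  Because real chronic-EEG
cohorts of this kind are rarely shareable, the package pairs the pipeline
with a synthetic-cohort generator that produces recordings with exact
ground truth, so every stage can be validated end to end.

## Synthetic EEG model

**Background.** Band-limited pink noise: spectral amplitude ∝ 1/√f inside
0.5–100 Hz, zero outside, scaled to a stationary RMS (default 50 µV).
1/f noise is the standard stand-in for rodent cortical background; no
attempt is made to model state transitions (sleep spindles, movement
artifact).

**Convulsive seizures.** A seizure is a contiguous phase sequence.

* *Onset* (`sz_onset`): repetitive biphasic sharp transients
  (difference-of-Gaussians kernel, ~8 ms sharp lobe) at instantaneous
  rates drawn per spike from 6–20 Hz, peak amplitude `amp_factor`
  (default 4, required > 2) times the background RMS, over an attenuated
  noise floor.  Onset duration is a truncated normal; the default early
  generator uses mean 38 s and the late generator mean 65 s, so early
  seizures are shorter than late ones while sharing all morphology
  parameters — the duration asymmetry observed in this model system.
* *Mid-ictal depression* (`mid`, probability 0.26): amplitude suppression
  to 0.3× background RMS for a uniform 10–180 s, followed by *end
  spiking* (`sz_end`) at 1–4 Hz.  Without a MID, the ictal content is the
  onset alone.
* *Post-ictal depression* (`pid`): 0.2× background suppression; excluded
  from the ground-truth seizure duration.
* Optional *inter-ictal multi-spike burst* (`ied_burst`) after the PID.

**SWDs.** A stable fundamental drawn from 7–12 Hz plus 2nd/3rd harmonics
at fixed phase offsets (weights 1.0/0.45/0.2), giving asymmetric
spike-wave cycles; amplitude reaches full scale within one cycle, waxes
and wanes (depth 0.5, period 3 s) and stops abruptly.  Durations are
log-normal, clipped to 3–70 s; the upper cap is a package choice, since
observed SWDs run from 3 s to "tens of seconds" without a stated bound.

**Scheduling.** Recordings are 0.5 h storage intervals sampled a few
times per simulated day.  Early seizures land at post-implant latencies
≤ 5 d, late seizures after day 5; a subject with at least one late
detection is classed as having post-traumatic epilepsy (PTE).  Under the
default cohort config only injured+stressed (FPI_Stress) subjects can
carry late seizures and PTE subjects carry no early ones, mirroring the
observed cohort structure (both are configurable).  SWD seconds per
interval grow linearly from 10 s at implant toward a 100 s plateau at
day 90 — identically in every group, since SWDs are common to injured
and sham animals.  Events are placed uniformly inside intervals with a
5 s margin and no overlap; an event that cannot be placed is resampled.
Everything is a pure function of `(config, seed)`; per-subject streams
are derived by hashing the subject id into the master `SeedSequence`.

What the generator does **not** emulate: electrode artifacts, movement
and EMG contamination, state-dependent background, multi-channel volume
conduction, fast ripples (> 100 Hz), and drift in event morphology over
months.  Passing tests therefore demonstrate that the pipeline's logic
and statistics behave correctly on signals with the stated
spectro-temporal structure — not that the trained detectors would reach
the same operating point on real recordings.

## Segmentation and scalograms

Records are cut into contiguous, non-overlapping 10 s epochs (half-open
intervals; 180 per 0.5 h record; trailing remainders are dropped and
logged).  Each epoch maps to the magnitude of an analytic Morlet CWT on
96 logarithmically spaced frequencies spanning 1–100 Hz.  The transform
is computed in the frequency domain — one FFT per epoch, multiplied by a
cached bank of constant-Q Gaussian kernels (`n_cycles` = 7, i.e. σ_f =
f/7) that vanish on negative frequencies, then a batched inverse FFT —
with 1.5× zero-padding for linear-convolution semantics.  Kernels are
L∞-normalized so a unit sinusoid at a grid frequency yields a row
magnitude near 1 at any frequency.  Cone-of-influence regions are
retained rather than masked: 10 s epochs make low-frequency edge
distortion unavoidable, and the classifier sees it identically in train
and test.  Frequency localization is verified against an FFT oracle and
cross-checked against PyWavelets' `cmor` implementation in the tests.

Rendered images (default 224×224 RGB, `viridis`; `jet`-like maps
available) use per-image max normalization with a monotone logarithmic
compression, so rescaling a scalogram leaves its image unchanged.

## Detection model

Two independent binary detectors (seizure-vs-background,
SWD-vs-background) consume reduced scalogram feature images: 48
frequencies × 40 time bins from 2×-decimated epochs, log-compressed on a
**fixed** magnitude scale (ceiling 1000 µV) rather than per-image
normalized — absolute amplitude is part of the ictal signature (onset
spiking is by definition > 2× background), and renormalizing suppressed,
background and spiking epochs onto each other measurably degraded
seizure/SWD separation in development.  The default backbone is a small
multilayer perceptron (one hidden layer of 32 units); a logistic
regression backbone is available.  The optimizer runs to near-zero
training loss (tol 1e-7): the detection rule is a fixed posterior
threshold, and unsaturated posteriors would otherwise make the detected
set depend on training-pool size rather than signal content.

An epoch is flagged as an event iff the event-class posterior strictly
exceeds 0.99.  Training exemplars are epochs with ≥ 3 s of spiking-phase
(or SWD) content — clear examples, as a human curator would select; MID
epochs are excluded because a suppressed-EEG epoch carries no ictal
signature (matching the observation that depressed mid-ictal segments go
undetected).  The background pool deliberately includes epochs holding
the *other* event kind, so each detector learns to reject its
counterpart, plus sampled pure-background epochs (1.5 background items
per event item; the pool is rebalanced 1:1 per training run).  Half of
each pool is held out for validation accuracy.  A correction loop
appends reviewed false positives to the background pool and missed
events to the event pool, then retrains.

Evaluation is asymmetric by design: sensitivity is event-level (an
annotated event is detected iff ≥ 1 overlapping epoch is flagged),
specificity and false-positive counts are epoch-level.

## Timelines and statistics

Detected duration is epoch-granular: each flagged epoch contributes
10 s, so an interval total is a multiple of 10 up to 1800 s.  Maximal
consecutive flagged blocks are detection runs; a config option can merge
runs separated by one unlabeled epoch (the MID reading) and never
changes totals.  Intervals are indexed by post-implant latency; ≤ 5 d is
"early", later is "late"; one late detection run (default threshold 1)
marks a subject PTE — the inclusive rule, which admits subjects with a
single late seizure.

Summaries are mean ± SEM over intervals with detections.  Group
comparisons use pooled-variance two-sample t tests (df = n_a + n_b − 2)
and two-way fixed-effects ANOVA (type-II sums of squares via
statsmodels; with one observation per cell the additive model is fit and
the interaction reported untestable).  α = 0.05, no multiple-testing
correction, both one- and two-tailed t p-values are computed because the
literature this mirrors mixes conventions.  Statistical outputs are
tested against brute-force formula evaluation at 1e-10 relative
tolerance.

## Experiment designs and scales

Problem sizes are the package's defaults, chosen so each experiment
completes in minutes on one CPU while keeping every cell statistically
usable; full-cohort scales (tens of subjects, months of recording) are
reachable through `CohortConfig`.

* **Cross-over training** (`CROSSOVER_CONFIG`): 6 subjects, 8 days, half
  with early seizures only and half with late only (~5 per subject).
  Detectors trained on early-only, late-only, and all seizures are each
  applied to every subject; per-interval detection durations are pooled
  over 10 replicate cohorts and analysed by two-way ANOVA
  (training × latency class).  With shared morphology the training main
  effect should be null while the class effect reflects the generated
  duration difference.
* **SWD null calibration** (`SWD_NULL_CONFIG`): 3 subjects per group ×
  4 groups, identical SWD generators; 200 replicate cohorts scored with
  ground-truth detections (no classifier) and tested for an injury main
  effect — the rejection rate should sit near α.
* **PTE recovery** (`PTE_RECOVERY_CONFIG`): 8 subjects with a designed
  PTE fraction of 0.25, recovered from ground truth and from detections.
* **Portability / disjointness**: train on one subject, evaluate on
  held-out subjects; seizure and SWD detectors applied to one record
  must flag disjoint epoch sets.

`scripts/acceptance.py` reruns all of the above from scratch for a given
`--seed` and writes the measured quantities as JSON.

## Numerical and degenerate-input choices

* Epoch counts follow a strict floor rule; sub-10 s records produce an
  empty epoch list with a warning, not an error.
* NaNs in an epoch raise, naming the epoch.
* A constant scalogram renders as a uniform image; an all-zero epoch
  gives all-zero magnitudes.
* `summarize_detection_durations` on a single interval reports SEM 0
  with an explicit `sem_defined=False`; with no intervals it raises.
* Two identical constant samples give t = 0, p = 1 instead of 0/0.
* EDF export quantizes to 16 bits over a symmetric integer-µV range;
  round-trip error is bounded by one quantization step and the writer
  refuses non-integer-second records.

## Known limitations

* The synthetic waveforms are far more stereotyped than real ictal EEG;
  detector operating points (sensitivity ≥ 0.8, specificity ≥ 0.99 at
  the 0.99 threshold) should be read as pipeline checks, not clinical
  performance claims.
* The MLP backbone is a stand-in scaled to CPU budgets; any torchvision
  -style pretrained backbone could replace it behind the same training
  and thresholding interface.
* Ambiguity in separating consecutive SWDs (waxing/waning amplitude) is
  resolved by ground truth here; on real data the per-interval duration
  total — not the event count — is the reliable SWD quantity, which is
  why the SWD analyses aggregate seconds per interval.
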