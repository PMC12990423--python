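# Methods

This note documents the models, conventions, and numerical choices behind
each stage of the pipeline, what the synthetic-data generator does and does
not emulate, and the problem sizes the test suite uses.

## Data model and conventions

All stages exchange four containers (`mobipipe.io_core`): `Recording`
(channels × time µV at a stated rate, with trigger events as 0-based sample
indices), `MarkerStream` (named (n, 3) mm trajectories on a uniform grid),
`ConditionLabel` (motor × sensory × cognitive load), and `PipelineConfig`.
Units are fixed — EEG in µV, positions in mm, reported times in ms — and
event latencies are kept as integer sample indices until reporting, so no
rounding drift accumulates across stages.

Marker axes are x = mediolateral (positive right), y = vertical, z =
anterior–posterior (positive anterior, the direction of treadmill
progression). Input CSVs may declare a different axis assignment in a
`# axes:` header comment and are remapped on read. The same frame is used
for electrode positions (Cz at the vertex, maximal y).

The experiment's five condition codes (S-NF-T, W-NF-NT, W-F-NT, W-NF-T,
W-F-T) are enforced by default; the unused standing-with-flow combination
is rejected unless a permissive flag is set, because downstream factorial
analyses assume the five-cell design.

EEG files are read with `mne` (EDF and BDF). No EDF/BDF writer being
available as a library, the package includes a minimal 24-bit BDF writer
with a `Status` trigger channel; written voltages are quantized at the
±32.768 mV physical range, i.e. ~0.004 µV per bit, which is far below EEG
noise floors. Round-trips are therefore exact in shape, rate, labels, and
events, and within one quantization step in voltage — a format-inherent
limit, not an implementation tolerance. Trigger codes are held for 8
samples (~16 ms) on the Status line and decoded at run onsets; codes are
Go = 1, NoGo = 2, press = 64 (the package defines its own documented
trigger table).

## Behavior

A press is attributed to the most recent stimulus onset. It counts as a
response only if its latency falls in the validity window, default
[100, 800] ms: earlier presses are anticipations, flagged invalid and
attributed to no trial (so a Go trial whose only press is anticipatory is
a Miss); the first valid press wins. The window end equals the maximum
stimulus-onset asynchrony of the design (400 ms stimulus + 400 ms maximum
ISI), so at most one following onset can compete for a press and the
"most recent onset" rule resolves it.

Sensitivity is d′ = Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate), positive for
above-chance performance. Extreme rates (0 or 1) are adjusted before the
probit, by default with the log-linear rule (count + 0.5)/(n + 1); a
clip-to-1/(2n) alternative and a strict error mode are selectable. RT
summaries are computed over Hits only. Per-subject d′ from finite trial
counts carries the usual small convexity (Jensen) bias of the probit —
about +0.05 at 144 Go / 36 NoGo trials — which affects any per-subject
d′ analysis, real or simulated, and is left uncorrected.

## Gait

Heel strike is a local maximum of the anterior–posterior heel trace with a
minimum inter-peak separation (default 600 ms) and minimum prominence
(default 20 mm); heel lift is the AP minimum strictly inside each
inter-strike interval, ties resolving to the earliest sample. Stride time
is the interval between consecutive same-foot strikes; stride length is
the AP distance from a lift to the next strike; step width is the
mediolateral |left − right| heel distance at each right strike. CV% uses
the sample SD (n − 1). Block summaries average strides of both feet;
condition values are unweighted means over a condition's blocks, and
strides never span block boundaries.

Manual visual confirmation of detected peaks is replaced by a reproducible
QC report: a stride-time histogram plus outliers beyond 3 scaled-MAD of
the median. Optional zero-phase moving-average smoothing (50 ms) before
extremum detection is exposed for noisy data and enabled in the default
pipeline configuration; the detectors are tested unsmoothed against a
brute-force local-extremum oracle. Step width uses the absolute lateral
distance; negative detected stride lengths (backward excursions, i.e.
detection failures) are excluded with a warning.

`mph_to_mps` converts preferred treadmill speeds (1 mph = 0.44704 m/s).

## EEG / ERP

Preprocessing: 4th-order Butterworth band-pass 0.25–40 Hz applied
forward–backward (`sosfiltfilt`, zero phase), then average reference.
Bad channels are those whose log-variance robust z-score (scaled MAD about
the median) exceeds 3.5 in magnitude, plus flat channels; more than 25% bad
channels aborts the block. Replacement uses Perrin spherical splines with
stiffness m = 4, Legendre series to n = 7, and ridge regularization 1e-5
on the kernel diagonal — constants chosen once and exposed in code; an
independent implementation (mne's, with a longer series) agrees to well
under the noise floor. ICA is deliberately not part of the default chain:
no reproducible component-rejection rule exists to implement, so the stage
would add an unauditable degree of freedom.

Epochs span −100..800 ms around stimulus onset. At 512 Hz the window is
realized as samples [onset − 51, onset + 409] inclusive — 461 samples,
with symmetric rounding of both edges; the onset sample is t = 0. Baseline
correction subtracts each channel's mean over the pre-stimulus samples
(t ≤ 0); it can be disabled. Epochs exceeding the recording are dropped
with a warning.

Grand averages are computed subject-first: each subject's trials are
averaged within a (condition, response type) cell, then subjects are
averaged with equal weight, which protects against unequal trial counts.
Peak measurement is two-pass: the canonical windows (P2 at FCz 200–280 ms,
max; N2 at FCz 280–380 ms, min; P3 at CPz 350–500 ms, max) locate each
group's grand-average peak latency, and subject-level peaks are then the
signed extrema within that latency ± 25 ms (P2, N2) or ± 50 ms (P3, a
broader component), intersected with the epoch. Local extrema are
preferred over window edges; an edge extremum is returned flagged. Ties
resolve to the earliest latency for determinism. The raw extremum is
reported; a mean-around-peak amplitude is available as an option since
"average peak amplitude" admits both readings.

Difference waves are CR grand average minus Hit grand average
(antisymmetric under swapping); topographic segment means are per-channel
time-means in ten 50 ms bins from 100 to 600 ms.

## Statistics

**Cluster maps.** Two-tailed t-tests (paired, or pooled-variance
two-sample) at every channel × time point; points in a same-channel run of
at least `min_run` consecutive p < α samples (defaults α = 0.05,
min_run = 10 ≈ 20 ms at 512 Hz) survive the mask. The criterion is purely
temporal — no spatial clustering across channels and no permutation step;
run-length filtering is monotone, so it can only reduce the pointwise
false-positive cells. Zero-variance points get t = 0, p = 1 with a
warning, keeping grid shapes stable. The full suite comprises nine maps:
Hit-vs-CR within each group × task condition (6), plus between-group
two-sample maps on the per-subject CR − Hit differences (3).

**Mixed RM-ANOVA.** Univariate approach via per-subject orthonormal
(Helmert) contrast scores: each within-effect stratum (each subset of the
1–2 within factors) is tested against its own subject-interaction error;
the between factor is tested on scaled subject means against
subjects-within-groups. Group combination uses unweighted (Type III)
means, matching standard statistical packages under unequal group sizes;
this was verified against R's `car::Anova` (type III, sum-to-zero
contrasts) and frozen into the tests. Greenhouse–Geisser ε comes from the
pooled within-group covariance of the contrast scores,
ε = tr(M)² / (d · tr(M²)), clipped to [1/d, 1]; it is identically 1 for
1-df effects, 1 under compound symmetry, and 1/(k−1) for a rank-one
non-spherical covariance. Both uncorrected and ε-corrected p are always
reported, with partial η² = SS_effect / (SS_effect + SS_error). The
design must be complete and balanced within subjects; missing cells raise
an error naming them.

**Effect sizes.** Pooled Cohen's d
(m₁ − m₂)/s_pooled with s_pooled² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2) for
between-group contrasts, paired d (mean difference over difference SD) for
within contrasts. The two-sample t uses pooled variance with
df = n₁+n₂−2 (not Welch). Bonferroni adjustment is min(1, m·p).

## Synthetic-data generator

The generator emulates the study conditions rather than any participant's
data:

* **Trial streams** — 180 trials per block, exactly 20% NoGo (a seeded
  permutation of a fixed multiset rather than i.i.d. Bernoulli, so the
  design proportion is an exact testable property), 400 ms stimuli,
  200–400 ms uniform ISI.
* **Behavior** — Go/NoGo presses as Bernoulli(hit rate / FA rate) with
  log-normal latencies (the standard positive-support choice; only means
  and SDs are specified) clipped to [100, 800] ms. Default group
  calibrations imply d′ ≈ 2.4 (TD-like: hit .94, FA .20) and ≈ 1.7
  (ASD-like: hit .89, FA .32), with condition RT means around 348–367 ms.
* **EEG** — per trial, each component adds amplitude ×
  Gaussian(t; latency, sd) × spatial weight, with spatial weights
  exp(−angular distance²/2·spread²) around the centre electrode on the
  unit sphere (component loci are only qualitatively known:
  fronto-central P2/N2, centro-parietal P3). Background noise is
  white noise spectrally shaped to 1/f (slope configurable), scaled to a
  per-channel RMS (default 10 µV). CR trials carry stronger/later P2, N2,
  and P3 than Hits, more so in the TD-like calibration. The layout is the
  standard 64-channel montage projected to the unit sphere.
* **Gait** — per stride, duration and length are drawn from normal
  distributions with the configured means and CV%; the heel's AP trace
  drifts posterior at belt speed during stance for length/belt-speed
  seconds (so lift-to-next-strike distance equals the drawn length
  exactly) and returns by a half-cosine swing peaking exactly at the next
  strike. Feet are anti-phase; lateral separation at right strikes
  follows the configured step-width mean and CV%. Ground-truth event
  times and per-stride metrics are returned alongside. Note the emulator's
  `belt_speed_mms` is the effective posterior heel speed during stance
  (default 1580 mm/s); with the default stride geometry it exceeds
  typical preferred treadmill speeds because the lift-to-strike stride
  length definition spans more than the stance-phase drift.
* **Scenarios** — `default_scenario()` encodes the study design: 18 + 20
  subjects, five conditions, three 180-trial blocks each, markers only for
  walking blocks, all seeded through `SeedSequence` children so the whole
  tree (including manifests) is byte-reproducible.

Not emulated: biophysical head volume conduction (no forward model),
eye-blink/EMG artifact taxonomies, gait-locked EEG artifact (an optional
stride-frequency sinusoid can be added for robustness checks), optic-flow
rendering, and real-time acquisition. Passing tests therefore demonstrate
correctness of the analysis chain under controlled signal models, not
robustness to the full artifact spectrum of real MoBI recordings.

## Problem sizes and numerical tolerances in the tests

The suites run on scaled-down instances chosen to make each tolerance
informative: gait recovery uses ~200+ strides per configuration (mean
recovery within 2%, CV% within 0.6 points); ERP peak recovery uses 50
seeded runs of 200 trials at 0.75 µV background RMS — a moderate-noise
setting at which the ±4 ms / ±2 SE tolerances probe systematic error of
the epoching and peak-measurement chain, since under broadband 10 µV noise
the irreducible latency jitter of a wide component exceeds the sampling
grid severalfold; ANOVA correctness is checked against a brute-force
balanced-design SS oracle on 100 random small designs (≤ 1e-8 relative)
plus frozen R reference values, and calibration against 1000 null
simulations (per-effect type-I rate 0.05 ± 0.02); cluster-mask null
behavior uses 100 paired-design replicates on a 16-channel × 461-sample
grid. End-to-end pipeline tests run a 6-subject, 40-trial-per-block
synthetic study.

## Known limitations

* The ANOVA supports exactly one between factor with two levels and one or
  two within factors with 2–3 levels — the designs this analysis needs —
  not general multi-way mixed models.
* The run-length cluster criterion controls isolated spurious points, not
  the family-wise error rate; it is exploratory by construction.
  Permutation-based max-statistic control is out of scope.
* Bad-channel thresholds are this package's defaults (robust-z 3.5, 25%
  floor); the original manual confirmation step has no reproducible
  counterpart.
* EDF/BDF voltage round-trips are quantization-limited (see above).
* Paired Cohen's d requires the difference SD, which printed group
  summaries do not provide; only pooled d is recomputable from them.
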