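# Methods

## The measurement problem

Cut-point intensity classification maps a wrist accelerometer summary
metric — here AVM, the per-epoch average of the gravity-subtracted vector
magnitude — onto sedentary / light / MVPA classes. The mapping assumes
wrist acceleration tracks whole-body energy expenditure. During walking
that assumption fails whenever the arm is constrained (gait aids, ADL
postures, carrying) or moves for reasons other than locomotion (tremor).
`walkanchor` quantifies the failure by establishing walking independently
from the ankle, where per-step impact transients survive any arm
behavior, and then auditing the wrist labels inside those known walks.

## Signal processing

**Calibration.** Offsets and gains per axis are fitted so that stationary
windows (10 s, per-axis SD < 0.013 g) lie on the 1 g sphere, by an
iteratively re-weighted axis-wise linear regression onto the current
unit-sphere projection (converged to machine precision; ≤ 1000
iterations). The fit is refused — identity returned, flagged
uncalibrated — with fewer than 5 stationary windows, when all window
orientations fall within 30° of each other (under-determined), or when
the fitted parameters leave plausible bounds (gain outside [0.8, 1.2],
|offset| > 0.25 g). Calibration is idempotent to < 1e-6 g.

**AVM.** Axes are low-pass filtered (4th-order Butterworth, 20 Hz cutoff,
zero-phase; skipped when the Nyquist frequency does not exceed the
cutoff), then ENMO is computed per sample, max(‖a‖ − 1 g, 0), averaged
over 1-s epochs, scaled to milli-g, and reaveraged into 15-s epochs
(trailing partials dropped, never padded). 20 Hz preserves all gait and
tremor content at both 50 and 75 Hz sampling. Filtering precedes gravity
subtraction; the alternative order is exposed through the API
(`compute_avm(lowpass_hz=...)` on pre-subtracted data) but not default.
AVM is exactly invariant to fixed device-frame rotations because the
same linear filter acts on every axis.

**Nonwear.** 60-s windows where ≥ 2 of 3 axes have SD < 0.013 g and range
< 0.05 g; runs merged across gaps < 5 min, kept at ≥ 60 min. Merging is
applied before the duration threshold, so two qualifying blocks bridged
by a brief interruption report as one interval. Without a temperature
channel, very still sleep can satisfy these criteria; daily accounting is
unaffected because sleep is removed from waking wear independently.

**Steps.** The detection axis is the non-gravity axis (gravity = largest
absolute mean) with the highest 0.5–3 Hz spectral power; it is zero-phase
band-passed to 0.5–3 Hz (cadences 30–180 spm) and local maxima at least
0.25 s apart count as steps above a threshold
`max(0.03 g, 1.0 × rolling MAD)` (MAD over 10-s blocks). The absolute
floor silences sensor noise in quiet periods; the MAD term scales with
sustained ambient motion while remaining below per-step peaks, which for
a band-limited periodic signal sit at ≈ 1.4 × MAD — a multiplier much
above 1 would reject every peak of its own signal. Peak times are refined
to sub-sample precision by parabolic interpolation; without it,
inter-step intervals quantize to the sample grid (20 ms at 50 Hz) and
cadence medians can be biased by ~3 spm near 140 spm.

**Bouts and cadence.** Steps with gaps ≤ 5 s (inclusive) form one bout;
boundaries are the first/last step times (no padding); < 2 steps are
discarded. Cadence is the median of 60/interval over the bout's step
pairs — robust for short bouts and matching the median summary used
downstream. LONG: duration ≥ 60 s and median cadence strictly > 80 spm.
ALL: ≥ 5 steps. Bout segmentation is idempotent and partitions the steps.

**Epoch/walk intersection.** The 15-s grid is anchored at the recording
start and global across the day. An epoch belongs to a LONG walk iff it
starts at or after the walk start **and** ends at or before the walk end;
epochs straddling the end are excluded (they mix walking with what
follows). Boundary classes are lower-inclusive upward: AVM exactly at a
cut point takes the higher class.

**Sleep.** Explicit annotations pass through unchanged. The built-in
heuristic (recordings ≥ 24 h) takes, per 20:00→noon night window, the
longest run with 5-min rolling median AVM < 5 mg, kept at ≥ 5 h. It
exists to partition wear time for valid days, not to stage sleep.

**Valid days.** Full calendar days only; waking wear = worn epochs (wear
fraction > 0.5) outside sleep (epoch midpoint rule); valid at ≥ 10 h.
Class minutes are 15-s epoch counts × 0.25, so they sum exactly to
waking wear.

## Statistics

* **Fisher exact test**: the observed sedentary/active split is compared
  to a pseudo-group of equal size with zero sedentary epochs — the only
  2×2 faithful to "all walking epochs should be active". Two-sided p by
  hypergeometric tail summation (scipy), verified against full
  enumeration for small totals. p decreases monotonically in the
  sedentary count at fixed total.
* **Bonferroni**: multiplier = number of participants tested (one test
  per participant is the family), capped at 1.
* **Clinical threshold**: sedentary epochs × 0.25 min, inclusive at
  exactly 20.0 min (≈ one day of the weekly 150-min MVPA recommendation,
  over a ~7-day wear).
* **AVM CoV**: sample (n−1) SD / mean × 100, pooled over all of a
  participant's LONG-walk 15-s epochs (not per-walk-then-averaged).
* **Quartiles**: group size ⌈n/4⌉ (35 → 9 per group); ties at a boundary
  break by participant id for determinism; Q1 ∩ Q4 = ∅ asserted.
* **Group comparisons**: pooled-variance two-sample t, df = n₁+n₂−2;
  zero pooled variance gives t = 0 (equal means) or signed infinity.

## The synthetic generator

Per step the ankle receives a damped burst, exp(−t/0.05 s)·sin(2π·8 Hz·t),
amplitude 0.8 g ± 10%, at times spaced 60/cadence s with 2% Gaussian
interval jitter. The wrist receives an arm-swing sinusoid at **stride**
frequency (half the step frequency — one swing cycle per stride) with
amplitude ~0.4–0.6 g partly along the gravity axis; suppressed walking
zeroes it; ADL posture additionally rotates gravity onto the forearm
axis; tremor substitutes a 4.5 Hz pronation–supination sinusoid
(0.35 g). Elsewhere: low-frequency fidgeting (0.02 g) at the wrist,
white device noise (SD 0.01 g) on all axes, near-motionless sleep, and
exactly constant zero-noise nonwear so the stand-in nonwear detector has
unambiguous truth. The expected wrist AVM of a walk is A/π g (half-wave
rectified sinusoid mean), which keeps expected labels far from cut-point
boundaries in every preset.

Scenario presets: `active_oa` (normal swing, 95–125 spm), `gait_aid`
(85% of walks suppressed, 88–108 spm), `tremor_pd` (suppressed or
tremor, 105–150 spm), `mixed_adl` (normal vs ADL posture). Preset LONG
walks last 90–240 s at ≥ 88 spm so ledger expectations are unambiguous
relative to the 60 s / 80 spm criteria. `graded_profile` fixes a
participant's expected LONG-walk sedentary fraction exactly by mixing
suppressed and normal walks of equal duration.

What the generator does **not** emulate: biomechanical coupling between
trunk, arm and leg; energy expenditure; overground speed; realistic ADL
taxonomies; device temperature; sub-sample clock jitter. Passing the
recovery suites therefore shows the pipeline is correct *given* the
stated signal phenomenology, not that the step detector matches any
specific commercial algorithm on real data.

## Problem sizes

The test and acceptance runs use 12 simulated participants of ~2 h at
50 Hz (≈ 4.3 M samples total) for parameter recovery, a paired
half-hour participant for the arm-suppression dissociation, and ≥ 24 h
single participants for sleep/valid-day behavior. Recovery results at
these sizes: step-count error ≤ 0.4%, LONG-walk recall 100% with zero
false admissions, cadence medians within ~1.2 spm of ledger, quartile
extremes recovered exactly, and identical ankle statistics under arm
suppression (the wrist change is 100% MVPA → 100% sedentary).

## Known limitations

* The step detector is deliberately parameter-light; heavily shuffling
  or very slow (< 40 spm) gaits and non-walking rhythmic leg motion are
  out of its design envelope.
* EDF start times truncate to whole seconds (header limitation); CSV
  keeps microseconds.
* Clock-drift correction is linear through at most two anchors; nothing
  is estimated without anchors.
* Cut points ship as generic placeholders by design: population-specific
  thresholds are deployment configuration, and all misclassification
  results depend on them.
* The sleep heuristic fails on shift-work or highly fragmented nights;
  external annotations are the supported path there.
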