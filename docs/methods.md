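# Methods

This note documents the models, conventions and numerical choices
behind `gaitwave`: what each stage assumes, which knobs matter, what
the synthetic-data generator does and does not emulate, and the design
decisions taken where more than one reasonable option existed.

## The analysis model

The quantity under study is the *normalized EEG amplitude as a function
of gait phase*: for each subject and walking condition, every gait
cycle of cleaned, band-limited EEG is amplitude-normalized to its local
peak, resampled to 100 phase points, and averaged across cycles into a
30-electrode × 100-point matrix. Group-level questions — does treadmill
vs overground walking, or auditory cueing, change this profile, and
where in the stride? — are answered with a two-way mixed-design ANOVA
(group between subjects, condition within subjects) evaluated
independently at each phase point, with family-wise control over the
100-point continuum by max-statistic permutation (SnPM).

Key assumptions:

* The IMU thigh angle and the EEG share a time origin (sync markers);
  clock drift is not modeled.
* Within a cycle, gait phase is proportional to elapsed time (linear
  time-warping between contacts).
* Exchangeability: group labels are exchangeable across whole subjects
  under the no-group-effect null; condition labels are exchangeable
  within a subject under the no-condition-effect null. The interaction
  scheme composes both and is approximate, as is standard for mixed
  designs.

## Filtering (preprocess)

Four band chains, all order-4 Butterworth: delta 0.5–100 Hz band-pass
then 4 Hz low-pass; theta 4.5–100 / 7.5; alpha 8–100 / 12; beta
13–100 / 30; plus a 50 Hz band-stop (half-width 1 Hz, a documented
choice — only the center frequency and order are fixed by convention).
Filters run forward–backward by default (zero phase, effective order
8): any group delay would translate directly into a gait-phase shift.
The causal single-pass variant is selectable.

Numerical care: the 0.5 Hz high-pass corner has a settling time of
seconds, so forward–backward application pads the signal with an
odd-symmetric extension of at least three time constants of the lowest
corner (`3·rate/f_low` samples), not the few-dozen-sample default.
Verification compares measured steady-state sinusoid gains — estimated
by quadrature demodulation at the probe frequency, which is immune to
residual sub-hertz edge drift — against the magnitude response
evaluated from the designed coefficients.

## fastICA (ica)

The staged procedure: remove per-channel means, eigendecompose the
channel covariance, keep the leading `n_components` principal axes
(default 5), whiten, then symmetric fixed-point iteration with the
tanh contrast (`tol = 1e-4`, `max_iter = 1000`). The only randomness
is the seeded initial rotation; component signs are fixed so the
largest-magnitude mixing weight is positive, making fits bit-identical
across runs. Five-of-thirty is an aggressive reduction; it is the
default because the artifact inventory this pipeline targets (two
ocular, one glossokinetic, two muscular components during walking) has
five members, and it is configurable because other montages or tasks
may need more.

Component labels come from four scores: the share of squared mixing
weight on Fp1/Fp2/Fpz (ocular topography) and on F7/F8/T7/T8
(inferior-frontal/temporal), and the fractions of Welch power below
4 Hz and above 20 Hz. Defaults: ocular = frontal share > 0.35 and
low-frequency ratio > 0.55; muscle = high-frequency ratio > 0.45;
glossokinetic = inferior share > 0.35 with low-frequency dominance;
otherwise brain. Rules are evaluated in that priority order and always
return a label. By default only non-brain components are removed;
removing all five estimated components (leaving the residual outside
the top-5 principal subspace) is reachable via configuration.

## Gait segmentation

Initial contact is the per-stride maximum of the right-thigh flexion
angle: peaks with ≥ 5° prominence (default; raise to ~10° for noisy
traces) and ≥ 0.5 s separation — slow walking implies stride periods
of a second or more. Flat peaks resolve to the first plateau sample
for determinism. The stance → swing boundary is the angle minimum
strictly inside each cycle. Angles are assumed flexion-positive
(`flexion_positive=False` flips the convention) and already smoothed
upstream; a centered moving-average pre-smoother (default window 5) is
available for rough fixtures, though on traces with a sharp contact
reversal it trades timing accuracy for robustness. Cycle validation
invalidates cycles outside [0.5, 1.5] × the median duration by
default; EEG index mapping uses half-open `[round(t·rate),
round(t_next·rate))` ranges so adjacent cycles share their boundary
sample exactly once.

## Epoching

"Local peak" normalization is per electrode and per cycle: each
electrode's trace in a cycle is divided by its own maximum absolute
value, keeping every constituent trace in [−1, 1] (a single
global-across-electrodes peak is available via configuration).
Normalization precedes time-resampling. Resampling is linear
interpolation onto phases k/100, k = 0…99 — the half-open convention
excludes the next cycle's shared boundary sample. Averaging uses the
arithmetic mean across cycles (per subject) and the mean and sample SD
(n−1) across subjects (per design cell). Group maps can be computed on
normalized traces (default) or on pre-normalization microvolt traces;
both conventions appear in practice and the stage at which microvolt
summaries are taken is otherwise underdetermined.

One property of peak normalization worth stating explicitly: an
amplitude change that coincides with the trace's peak is unobservable
in normalized units — it simply rescales the cycle — and instead
surfaces as an apparent suppression elsewhere in the cycle. Effects
are therefore only localizable in phase regions away from the profile
maximum.

## SnPM statistics

Split-plot sums of squares: group is tested against the
subject-within-group mean square, condition and interaction against
the condition × subject-within-group mean square; with a two-level
within factor no sphericity correction is needed. The vectorized
implementation is verified to 1e-8 against an explicit loop-based
oracle and against an external mixed-ANOVA implementation.

Permutation conventions:

* Monte-Carlo p-values carry the add-one correction,
  `p = (1 + #{perm ≥ obs}) / (n_perm + 1)`; exhaustive enumerations
  include the identity relabeling, `p = #{perm ≥ obs} / n_total`.
  Exhaustive mode engages automatically when the number of distinct
  relabelings is at most `n_perm`.
* F\* is the matching order statistic (the `⌊α(n_perm+1)⌋`-th largest
  permutation maximum), so "observed max ≥ F\*" holds exactly when the
  omnibus p is ≤ α. Fewer distinct relabelings than 1/α raises an
  "alpha unattainable" error.
* Clusters are maximal runs with F ≥ F\*; their extents are reported
  in percent of gait cycle with linear interpolation at threshold
  crossings, and cluster p-values compare the observed extent with
  each permutation's largest suprathreshold extent.
* Zero-variance timepoints are excluded from the max-statistic with a
  logged warning; degenerate F ratios (zero denominator) are flagged.
* Post hoc comparisons (OSC–OsSC and TSC–TsSC paired, OSC–TSC and
  OsSC–TsSC unpaired) run max-|t| permutation tests over the full
  100-point cycle and are Bonferroni-adjusted by the number of
  executed comparisons (default 4); they run only when the omnibus
  interaction is significant. Whether post hoc tests should be
  restricted to significant windows is underdetermined; the full-cycle
  default is conservative and windows are reported alongside.
* Per-electrode analyses are *not* corrected across electrodes
  (results are electrode-wise); a family-wise option exists but is off
  by default.
* The Shapiro–Wilk normality check on cell-centered residuals is
  advisory only: the pipeline always proceeds to permutation
  inference, which does not need normality.

Defaults: `n_perm = 10 000` in the library API, α = 0.05, mandatory
seeds; all-electrode runs spawn one child seed stream per electrode
from a root seed sequence, making whole reports reproducible.

## The synthetic-data generator

What it emulates: 32-channel EEG at 512 Hz (30 active electrodes of a
10-20 montage plus mastoids; reference and ground are not recorded)
synchronized with a 200 Hz right-thigh angle stream; 3-minute walks;
per-cell stride counts drawn from the reference table's distributions
(treadmill self-selected 116.7 ± 17.0 strides/3 min, overground
self-selected 88.4 ± 16.0, cued conditions 68 ± 0.7–0.8); a
gait-locked delta-band cortical source; the five-artifact inventory;
1/f background noise (default SD 3 µV per channel against a 5 µV gait
component); and injectable amplitude effects confined to a gait-phase
window at named electrodes, applied only in chosen design cells.

Design choices that matter:

* **Thigh angle**: piecewise quarter-sinusoids with a sub-linear
  exponent, giving a smooth minimum at the stance → swing transition
  (60 % of the cycle by default — a convention, since stance fractions
  are not otherwise pinned down) and a sharp reversal at initial
  contact. The sharp reversal is what makes the contact maximum
  localizable to within one IMU sample; angle noise, when requested,
  is band-limited to 15 Hz because the residual noise of a
  Kalman-smoothed orientation stream is smooth, not white.
* **Gait-locked waveform**: a fixed mix of stride harmonics 2–4 with
  its magnitude peak at 25 % of the cycle (mid stance). Harmonics ≥ 2
  keep the waveform inside the delta passband even at slow cadences,
  where the stride fundamental (≈ 0.38 Hz at 68 strides/3 min) falls
  under the 0.5 Hz high-pass corner; the peak sits away from early
  stance so that phase-confined effects injected there remain
  observable after peak normalization (see the epoching note above).
* **Scalp projection**: smooth Gaussian-like gain profiles on 2-D
  electrode positions — centro-frontal for the gait source, prefrontal
  for blinks, an F7/F8 dipole for eye drift, an inferior-frontal/
  temporal ring for the glossokinetic source, left/right temporal for
  the EMG pair. EMG sources are burst-modulated band-limited noise
  locked to opposite gait phases; bursts make them non-Gaussian and
  hence separable by ICA.
* **Determinism**: one seed fixes everything; cohorts spawn per-subject
  child seeds from a root seed sequence.

The **matrix-level cohort path** (`generate_cohort_matrices`) emulates
the statistics of the *post-epoching* subject matrices directly:
template × subject gain (a shared between-subject random effect,
SD 0.1) plus per-point noise of SD `cycle_noise_sd / √n_cycles`, with
`n_cycles` drawn from the same stride-count distributions. The default
`cycle_noise_sd = 0.6` is the background-to-component amplitude ratio
of the signal-level defaults, expressed in normalized units; dividing
by √n_cycles is exactly what ensemble averaging across strides does to
per-cycle noise. This path makes calibration studies (hundreds of
cohorts) affordable; the signal-level path exercises the same
statistics end to end at single-cohort scale.

What the generator does **not** emulate: biomechanically realistic
joint kinematics, treadmill-vs-overground physiological differences
beyond the injected effect, spatially correlated background EEG, clock
drift between streams, or electrode motion artifacts beyond the five
modeled sources. Passing tests therefore demonstrate that the
*machinery* is correct and calibrated — filters match their designed
responses, ICA separates sources it is geometrically able to separate,
segmentation recovers events the waveform encodes, the permutation
test holds its nominal error rate and detects effects of the stated
size — not that real walking EEG satisfies these models.

## Scales used in tests and verification

Test and verification runs use reduced problem sizes chosen to keep
the statistical properties intact: end-to-end pipeline cohorts use 12
subjects per group (the design's n) at 60 s of walking and 500–1000
permutations; calibration studies use 200 matrix-level null cohorts
and 50 effect replicates at 1000 permutations. Type-I error is
assessed against the binomial band [0.02, 0.09] around the nominal
0.05 for 200 cohorts. The end-to-end recovery test injects 8 µV
(≈ 2.7 × the background SD) at Fz over 3–8 % of the cycle — a strong
but in-band effect.

## Known limitations

* The interaction permutation scheme is approximate for mixed designs;
  its empirical type-I error is verified by simulation rather than by
  exactness arguments.
* Between-group stride-count differences make subject-matrix noise
  variances mildly heterogeneous across groups; the permutation test
  absorbs this in calibration but exactness is again approximate.
* EDF storage quantizes to 16 bits over each channel's physical range;
  round-trips are lossless only to that precision.
* Classification rules are heuristics with documented thresholds, not
  a learned classifier; unusual artifact topographies can be
  mislabeled (the conservative failure mode keeps a component).
* With five retained components, everything outside the top-5
  principal subspace bypasses ICA cleaning entirely; this mirrors the
  staged procedure's design but limits how much artifact energy can be
  removed.
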