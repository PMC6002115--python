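# Methods

`headingcues` simulates and analyzes a two-alternative ("did I move left or
right?") heading-discrimination experiment in which visual and inertial
self-motion cues are dissociated by eccentric gaze, and in which the
reliability of the *inertial* cue is manipulated by superimposed vertical
vibration. This note records the model, the defaults and why they have the
values they do, the numerical choices, and what the synthetic data can and
cannot establish.

## Stimulus kinematics

The translation stimulus is a straight-line motion whose acceleration is one
cycle of a sine wave, `a(t) = A sin(2πt/T)`. With `A = 2πd/T²` the platform
starts and ends at rest and travels a distance `d`; the closed-form peaks are
`v_max = 2d/T` and `a_max = A`. The default stimulus (`d = 16` cm, `T = 2` s)
peaks at 16 cm/s and `8π ≈ 25.13` cm/s² (25 when rounded to the precision of
the platform specification). The vertical vibration is a sinusoidal heave
displacement at 6 Hz. Its **amplitude parameter is peak-to-peak
displacement**: this is the only reading under which 0.20 cm at 6 Hz
reproduces the accelerometer-verified peaks of 3.77 cm/s and 0.145 g
(`g = 981` cm/s²). The vibration phase is a keyword defaulting to 0
(sine). Profiles are ideal: the small off-axis leakage a physical platform
exhibits is not modeled, and optic-flow rendering (star density, dot
coherence mechanics) is out of scope — coherence is carried as a condition
label only.

Validation grids use `dt = 1e-4` s (1e-5 s for the 6 Hz vibration so its
peaks resolve to 3 significant figures); display-rate output uses 1/60 s.

## Adaptive staircases

Each block interleaves four independent 1-up-1-down tracks (gaze left/right
× start ±50°), 20 trials each, 80 trials per block. The step starts at 8°,
halves on each response reversal down to 0.5°, and doubles (cap 8°) after
three responses in the same direction. Two genuinely open readings of the
doubling rule are implemented:

* `double_rule="reset"` (default): the run counter resets after a doubling,
  so a long run doubles at most every third trial. This keeps the track
  stable during the long initial descent from ±50°.
* `double_rule="raw"`: the counter keeps growing, doubling on every further
  same-direction response.

Both are consistent with published sample trajectories; the flag makes the
choice explicit rather than silent. Step adjustments take effect before the
move they precede; clamping at ±50° leaves the stored step untouched; the
first trial of a track involves no adjustment. The reachable step set from
8° is exactly {8, 4, 2, 1, 0.5}. Interleaving draws uniformly among
unfinished tracks and cannot alter any single track's trajectory.

## The synthetic observer

An observer is a set of condition-dependent cumulative-Gaussian
psychometric functions. Sign convention, fixed package-wide: headings are
positive rightward; the PSE μ is the heading judged rightward half the
time, so **μ > 0 means a midline stimulus is more likely reported "left"**.

| parameter | meaning | default | unit |
|---|---|---|---|
| `sigma_V` | visual threshold at 50% coherence | 3.6 | deg |
| `sigma_I0` | inertial threshold, no vibration | 4.8 | deg |
| `vib_inflation` | multiplicative σ_I step when any vibration is present | 11/6 (→ 8.8°) | – |
| `bias_V` | visual PSE shift opposite gaze | 9.6 | deg |
| `bias_I` | inertial PSE shift toward gaze | 3.0 | deg |
| `integration_mode` | `optimal` (inverse-variance) or `fixed` w_I | `optimal` | – |
| `w_I_fixed` | inertial weight in `fixed` mode | – | – |
| `lapse` | stimulus-independent error rate | 0 | – |

Defaults are the group-average values of the study the package emulates.
The inertial bias is set to 3.0°: the across-amplitude group means are
3.3° (left gaze, rightward shift) and 2.9° (right gaze, leftward shift),
i.e. ≈ 3° toward gaze; the single no-vibration left-gaze figure of 3.6°
is within the between-subject spread of the same quantity. The vibration
effect on σ_I is a **step, not a dose**: all non-zero amplitudes inflate
σ_I by the same factor, mirroring the empirical null for amplitude. A
dose-response hook would be a one-line change but defaults to off because
the data motivating the model show none.

Combined conditions follow `μ_VI = w_I μ_I + w_V μ_V`, `w_V = 1 − w_I`.
In `optimal` mode the weights are inverse-variance weights; in `fixed` mode
`w_I` is free, which is how inertial-overweighted observers are built. The
combined σ defaults to the optimal-fusion value
`σ_V σ_I/√(σ_V²+σ_I²)` even when the weights are not optimal — the
empirical literature reports reduced combined σ without committing to a
formula, so an override (`sigma_VI_mode="override"`) exists for
sensitivity analyses rather than asserting a model.

Cohorts (`make_cohort`) draw each parameter uniformly from a range
spanning the between-subject spread; a configurable fraction of subjects
(default 0.6, at least one) integrates with a fixed inertial weight drawn
from [0.87, 0.95] — the inertial-overweighted phenotype the design exists
to detect.

## Psychometric fitting

`HeadingPsychometric` / `PsychometricResults` follow the model/results
idiom. The likelihood is the exact Bernoulli likelihood of
`P(right) = Φ((h − μ)/σ)`; weighting by presentation count is implicit in
the sum, and grouping identical headings is a speed detail that provably
does not change the value. No lapse parameter is fitted (a fixed-lapse
argument exists for robustness studies). Probabilities are clipped to
[1e-9, 1 − 1e-9] before the log.

Maximization is multi-start Nelder–Mead on (μ, log σ): 20 starts by
default — one deterministic start at (median heading, IQR) and the rest
with μ uniform over the observed heading range and σ log-uniform over
[0.25, 50]°. The optimizer is checked against a brute-force 401×200 grid
oracle in the test suite and never loses. Tight tolerances
(`xatol 1e-6`) for the primary fit.

**Bootstrap.** Confidence intervals are percentile intervals from
case-resampling at the trial level within a block, refit per resample,
2000 resamples by default. Refits warm-start at the original MLE with a
single Nelder–Mead run at `xatol 1e-4` — far below percentile resolution;
on fixtures the interval endpoints agree with multi-start refits to within
resampling noise. Unidentifiable resamples (all-same responses) are
redrawn and counted; if more than half of draws fail, the data are
declared degenerate. BCa was considered and rejected in favor of the plain
percentile interval, matching the analysis being emulated.

**Adaptive-sampling bias.** Staircase trials are treated as independent
Bernoulli trials, the standard practice. The adaptive placement
concentrates trials near the PSE, which under-informs σ: in the recovery
suite, with 40 trials per function (the per-gaze count of a single block)
the mean σ̂ is ~0.73–0.81 of truth, while μ̂ is essentially unbiased
(< 0.15°). With 80 trials per function the σ̂ ratio improves to
0.87–0.92. The recovery tests therefore evaluate at 80 trials per
psychometric function; users fitting single 40-trial gaze cells should
expect σ̂ to run low by roughly a fifth.

## Cue weights

Optimal weights come from the unisensory σs
(`w_V_opt = σ_I²/(σ_I²+σ_V²)` via inverse variances), empirical weights
from the PSEs (`w_I_emp = (μ_VI − μ_V)/(μ_I − μ_V)`); each pair sums to 1
exactly by construction. Empirical weights outside [0, 1] are flagged,
never clipped — a negative visual weight is a finding, not an error. A
separation floor of 1e-6° on |μ_V − μ_I| makes genuinely coincident
unisensory PSEs fail loudly instead of producing huge weights.

Weight CIs are propagated by applying both formulas to bootstrap
resamples of the three underlying fits paired by index (after an optional
seeded shuffle, since the three bootstraps are independent), dropping and
counting degenerate triples, and taking the 5th–95th percentile interval.

Aggregation across gaze (open in the source analysis): empirical weights
are computed per gaze — where the unisensory PSEs are actually dissociated
— and averaged over the two gazes per subject × amplitude; optimal weights
use gaze-averaged σs. The μ_V enters from the same pipeline run's visual
block (no prior-study 100%-coherence means exist here; the choice is a
config knob in spirit and documented), and μ_I is matched to the vibration
amplitude of the combined condition being analyzed.

Two derived report statistics: the gaze-wise visual–inertial PSE
separation (mean of |μ_V − μ_I| over gazes; 11.4° at the reported group
PSEs) and the per-modality gaze-relative bias (left-gaze PSEs negated
before averaging; positive = opposite gaze). Both round half away from
zero to one decimal, the precision of the human-readable tables; the CSV
outputs keep full precision.

## Pipeline and reproducibility

`run_experiment` is a pure function of config + master seed. Seeds derive
through `SeedSequence` entropy tuples — cohort from `(seed, 20000)`, block
order per subject from `(seed, subject, 10000)`, block content from
`(seed, subject, block_index)` with the index taken in canonical block
order — so any subject or block regenerates in isolation and block order
never affects block content. Central-gaze conditions are not simulated
(dropped in the emulated design). No trial-exclusion stage exists because
fixation behavior is not simulated; users importing real data should
exclude fixation failures upstream if desired. Repeated-measures ANOVA is
out of scope; per-amplitude σs appear in the summary so the
amplitude-null is inspectable, and a paired t-test is provided as
reporting plumbing.

## Problem sizes used in the tests

Recovery: 100 seeds × 2 gazes × 3 conditions at 80 trials per function.
Coverage: 200 blocks × 300 resamples at (μ=0, σ=6). Overweighting
signature: 5 subjects × 720 trials, point estimates only (no bootstrap).
These sizes give sampling error comfortably inside the asserted bands
while keeping the full suite in the low minutes on one core.

## Limitations

* The generator draws from exactly the model family the fitter assumes
  (cumulative Gaussians, no lapses, perfect cue synchrony); passing tests
  demonstrate self-consistency and estimator quality, not that real
  subjects behave this way.
* Bias magnitudes are free parameters, not derived from gaze geometry or
  retinal coordinates; nothing here explains *why* visual PSEs shift
  opposite gaze.
* Combined-condition σ follows optimal fusion by default even for
  non-optimal weights — a modeling convenience, overridable.
* Group-average weights of the emulated study average per-subject
  quantities whose raw inputs are not public; the package reproduces the
  qualitative divergence (empirical w_I ≈ 0.9 vs optimal < 0.5 under
  vibration), not those exact printed averages.
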