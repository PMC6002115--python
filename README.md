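# headingcues

Simulation and analysis of **visual–inertial heading discrimination under
eccentric gaze**, for psychophysicists studying multisensory cue
integration.

Visual headings are encoded in retinal coordinates, inertial (vestibular +
proprioceptive) headings in body coordinates, so looking 25° to the side
makes the *same* physical heading feel different to the two senses: the
visual percept shifts opposite gaze (≈ 9.6°), the inertial percept shifts
slightly toward gaze (≈ 3°). That dissociation makes the weight each cue
receives in the combined percept measurable. `headingcues` provides the
full in-silico version of such an experiment:

* **Stimulus kinematics** — single-cycle sine-in-acceleration translations
  (16 cm, 2 s → peaks 16 cm/s and 8π ≈ 25 cm/s²) and vertical 6 Hz
  vibration (0.20 cm peak-to-peak → 3.77 cm/s, 0.145 g) used to degrade
  inertial reliability.
* **Adaptive staircases** — 1-up-1-down tracks with variable step
  (8° halving to 0.5° on reversals, doubling after three same-direction
  responses), four interleaved tracks × 20 trials per block.
* **Synthetic observers** — cumulative-Gaussian responders with
  gaze-dependent biases, a step (not dose) inflation of inertial σ under
  vibration (4.8° → 8.8°), and combined-cue PSEs following the weighted
  sum `μ_VI = w_I μ_I + w_V μ_V` with optimal or deliberately
  inertial-overweighted weights.
* **Psychometric fitting** — exact Bernoulli maximum likelihood of
  `P(right) = Φ((h − μ)/σ)` via multi-start Nelder–Mead, with trial-level
  case-resampling bootstrap CIs (statsmodels-style model/results API).
* **Cue-weight analysis** — optimal (inverse-variance) weights
  `w_V = σ_I²/(σ_I²+σ_V²)` versus empirical weights
  `w_I = (μ_VI − μ_V)/(μ_I − μ_V)`, with resampled 5th–95th percentile
  CIs, never clipped when outside [0, 1].

## Worked example

Fit one gaze direction of a simulated inertial block (0.15 cm vibration):

```python
from headingcues import ConditionSpec, ObserverParams, run_block, bootstrap_fit

obs = ObserverParams(integration_mode="fixed", w_I_fixed=0.9)
records = run_block(obs, ConditionSpec("inertial", 0.15), seed=1)
left = [r for r in records if r.gaze == "left"]
res, pairs = bootstrap_fit(left, n_boot=500, seed=2)
print(res.summary())
```

```
Cumulative-Gaussian psychometric fit
------------------------------------
n trials     : 40
log-lik      : -17.6099
converged    : True
PSE mu       :    4.368 deg   95% CI [0.853, 8.329]
sigma        :    7.108 deg   95% CI [3.047, 12.523]
bootstrap    : 500 resamples (0 redrawn)
```

The true generating values for this cell are μ = +3° (inertial percepts
shift toward the left gaze; positive μ means a midline stimulus is more
often called "left") and σ = 8.8° (vibration-inflated); both lie inside
their 95% CIs. `pairs` holds the 500 resampled (μ, σ) estimates for
propagating uncertainty into cue weights.

The full experiment — 5 subjects × 9 blocks (4 inertial amplitudes,
4 combined, 1 visual) × 80 trials — runs from the command line:

```bash
headingcues all --seed 7 --n-boot 0 --out demo_out
```

```
Group summary
=============
subjects                                 5
trials                                   3600
visual-inertial PSE separation (deg)     10.9
inertial sigma, no vibration (deg)       4.3
inertial sigma, with vibration (deg)     7.8
mean optimal w_I, no vibration           0.41
mean empirical w_I, no vibration         0.66
mean optimal w_I, vibration              0.2
mean empirical w_I, vibration            0.62
combined bias re gaze (deg)              1.0 (opposite gaze)
inertial bias re gaze (deg)              -2.8 (toward gaze)
visual bias re gaze (deg)                7.5 (opposite gaze)
```

This default cohort mixes optimal and inertial-overweighted subjects:
vibration collapses the *optimal* inertial weight to 0.2 (the inertial cue
becomes much noisier) while the *empirical* weight stays around 0.6 —
the signature of non-Bayesian, inertially dominated integration. Full-
precision tables land in `demo_out/` (`trials.csv`, `fits.csv`,
`weights.csv`, `summary.csv`); `config init`, `simulate`, `fit`,
`weights`, and `report` expose the individual stages, and `--n-boot 2000`
adds bootstrap CIs throughout.

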