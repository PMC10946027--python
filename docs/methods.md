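# Methods

This note documents the models, measures, and numerical choices behind
`stridelearn`, in the order the pipeline runs them.

## Protocol model

A session is three (or four) phases of strides indexed 1-based within each
phase: baseline (250 strides, walk normally), learning (900 strides), and a
post-learning probe — either a 900-stride washout (implicit aftereffects)
or two explicit retention tests, 25 strides immediately after learning and
250 strides 24 h later. Phases are stored separately rather than
concatenated, which removes any off-by-one ambiguity at phase boundaries.

The learning-phase target is adaptive: it holds at the subject's baseline
LSL for 50 strides, then rises 1% of baseline every 10 strides (the first
stride of each 10-stride block carries the new level — the only reading
under which the plateau spans strides 141–900) until it reaches +10%, where
it stays. The reward window is the target centre ± 2 cm: the *centre* is
relative to the subject's baseline, the *width* is absolute, so task
difficulty does not scale with body size. Window bounds are inclusive on
both sides; a physical ±2 cm tolerance has no open edge. Success is
evaluated on the raw per-stride step length (the real-time system's exact
filtering is unknowable offline; raw is the reproducible choice).

Named analysis epochs: `baseline_ref` = final 50 baseline strides (the ΔLSL
reference), `early_learning` = strides 141–190 (first 50 strides at the
plateau), `late_learning` = strides 851–900, `immediate_washout` = washout
strides 1–5, `early_washout` = 6–30, and the first 25 strides of each
retention test.

## Gait-event detection

Offline mirror of the real-time rule: a left heel strike is a kinematic
sample at which (a) the left belt is loaded — vertical GRF above 20 N at
the nearest 1000 Hz sample (nearest-sample lookup, 10:1 rate ratio, no
interpolation) — and (b) the smoothed anterior–posterior velocity of the
left heel marker first crosses from positive to non-positive. Velocity is a
centred finite difference of the 100 Hz position smoothed with a 5-sample
moving average; a deadband zeroes |v| < 1e-9 m/s so float round-off of
constant signals cannot masquerade as a crossing. A 0.4 s same-side
refractory period suppresses jitter double-detections — stride times at
1.0–1.2 m/s are more than twice that. Left step length is the AP
marker separation `left_heel − right_heel` at the event sample; negative
values are passed through for downstream flagging, never clamped. The +y
axis is the walking direction; readers can sign-flip via configuration.

The trace synthesizer inverts this: heel trajectories are antiphase
sinusoids (period = cadence, default 1.1 s snapped to the kinematic grid)
riding on a per-stride offset, phased so the velocity peak falls half a
kinematic sample before each planted strike time; the detector then fires
exactly on the planted sample, where the marker separation equals the
planted step length. Offsets are re-anchored by linear ramps placed
mid-swing, when the force gate is off, so re-anchoring can never spawn
events; stance force (700 N square wave, 60% duty cycle) starts 2 ms before
the strike so float jitter cannot leave the strike sample unloaded. The
noiseless round trip recovers planted lengths to ~1e-15 m.

## Synthetic walkers

Both agents execute every intended step ("aim") with additive Gaussian
motor noise, SD = 1.5% of baseline LSL by default, which keeps the ±2 cm
window well inside baseline variability (for a 0.6 m baseline: noise
0.9 cm vs window half-width 2 cm). Gaussianity is a modelling convenience;
the downstream Student-t inference is robust to it.

**TE agent** — sees the target error and corrects a fraction of it:
`aim(s+1) = aim(s) + gain·(centre(s) − x(s))`, default gain 0.3. The
tracking fixed point is the target centre, so late-learning ΔLSL
averages 10%; stationary aim variance adds gain/(2−gain) ≈ 18% to motor
variance, leaving σ_ΔLSL near 1.1.

**RPE agent** — win-stay/lose-shift on the hidden reward window. After a
rewarded stride the aim is retained (optionally jittered by
`exploit_shift_sd_scale`, default 0) and becomes the *anchor*; the
exploration scale decays multiplicatively (`explore_decay`, default 0.995)
with a floor of 1. After an unrewarded stride the next aim is drawn
Normal(anchor, scale·baseline_sd); the scale recovers by one decay step per
failure, capped at its initial value (`explore_sd_scale`, default 2.5).
Two design points deserve emphasis:

- *Anchored lose-shift.* Exploring around the last rewarded aim, rather
  than the current (failed) aim, is what makes learning reliable: an
  unanchored perturbation chain is a random walk that loses the ramping
  target in roughly half of simulated subjects and can drift tens of
  percent away. With the anchor, 40/40 seeds learn (late ΔLSL 10.2 ± 0.7%).
  Before any reward exists there is no anchor, so a never-rewarded agent
  degenerates to the pure random walk (aim variance grows linearly in
  strides), and with scale 1 the variability stays within √2 of baseline —
  both limits are tested.
- *Uncertainty-tracking scale.* Decay on success, recovery on failure:
  exploration shrinks as the reward landscape is learned and rebounds while
  it is not. A full reset-to-cap on failure was evaluated and rejected — it
  erases the early→late exploration decrease because rare late failures
  keep re-inflating variability.

**Post-learning memory.** Washout stride s expresses
`washout_retain · ΔLSL_late · washout_decay^(s−1)` plus motor noise
(defaults: retain 0.55 for TE, 0.45 for RPE; decay 0.995/stride). Retention
reproduces `ΔLSL_late + recall_bias_pct` at both tests (bias +2.5 points
for TE — overstepping — and −1.5 for RPE — understepping), a signed,
roughly constant bias consistent with the reported retention signatures.

**Cohorts.** Baseline LSL is drawn uniformly from 0.5–0.7 m per subject;
all other parameters are fixed at the group defaults unless a
hyper-distribution (fixed value or lognormal) is configured. Subject seeds
derive from the master seed; stride tables are bit-reproducible.

*What the generator does and does not emulate.* It reproduces the
qualitative structure: reliable reward-based acquisition, elevated
early-learning exploration that decays by late learning, larger
trial-to-trial changes after failures, washout decay that is larger for
the TE group, and opposite-signed retention biases. Magnitudes are not
calibrated to human data: in particular, early-learning σ_ΔLSL for the RPE
agent runs ~1.4× baseline versus the ~2×–3× seen in people, because the
anchored search tracks the ramp more efficiently than human learners do.
Passing tests therefore demonstrate self-consistency of generator +
pipeline, not external validity; with the smaller effect size, individual
15 + 15 cohorts can occasionally yield exploration contrasts with direction
probabilities below 90%.

## Measures

All SDs are sample (n−1) estimators — the conventional choice at epoch
sizes of 50. σ_ΔLSL divides the epoch SD of ΔLSL by the `baseline_ref` SD
and is scale-free. σ_trial-to-trial uses learning strides 51–900 (after
the initial hold): each change Δ(s) = ΔLSL(s+1) − ΔLSL(s) is conditioned
on the outcome of stride s — the stride that was or was not rewarded, the
natural win-stay/lose-shift reading — and each conditional SD is normalised
by the SD of *unconditional* consecutive changes over `baseline_ref` (no
success flags exist at baseline). Conditional sets with fewer than two
changes are reported missing, never zero. Baseline-reference SDs at or
below 1e-9 percentage points are treated as degenerate (float round-off of
constant series) and rejected.

Percent-of-learned measures (aftereffects, retention) compute
`100 · ΔLSL(s) / mean(ΔLSL_late)` per stride and average over the epoch;
the ratio-of-epoch-means variant is available but not the default.
Subjects with |late ΔLSL| < 0.5 points are flagged unreliable. Absolute
retention error is `|mean ΔLSL over the retention epoch − ΔLSL_late|`.

Variability matching pairs subjects across groups greedily on the raw
(non-normalised) SD of ΔLSL over plateau strides 141–900: all cross-group
pairs ranked by absolute SD difference, selected smallest-first without
reuse; ties break on the sorted id pair, making the result invariant under
swapping group labels.

The learning-rate proxy (per-100-stride decline of the per-stride target
error across the plateau, from an OLS slope) is an operationalisation
choice exposed for baseline-variability regressions, not a
protocol-defined measure.

## Bayesian estimation

The cell-means model: `y_gt ~ Student-t(ν, μ_gt, σ_gt)` for each
group × time cell, ν shared across cells (per-cell ν is a config option).
Priors follow the BEST convention, anchored once to the pooled data slice:
`μ_gt ~ Normal(pooled mean, 100 · pooled SD)`,
`σ_gt ~ Uniform(pooled SD/1000, pooled SD·1000)`,
`ν ~ 1 + Exponential(mean 29)`. There are no subject-level random effects;
cells are treated as unpaired (a paired variant across epochs is an open
modelling question for repeated measures).

Sampling uses an affine-invariant ensemble MCMC (emcee) with a
differential-evolution move mixture, run as independent ensembles — one per
"chain" — of 32 walkers. Scale parameters are sampled on the log scale
(σ as log σ with a +log σ Jacobian restoring the uniform prior; ν as
log(ν−1) with the corresponding shifted-exponential Jacobian); this plus
the DE moves is what keeps split-Rhat below 1.01 on the correlated
(scales, ν) block. Per chain, `tune` burn-in steps are discarded and
`draws` posterior draws are retained by flattening the walkers with a
thinning stride (default 12 steps between retained draws). Defaults mirror
the protocol's reported sampler budget (4 chains × 10,000 draws, 2,000
tuning steps); tests and the acceptance script use 4 × 1,000 draws with
600–800 tuning steps, which the calibration suite shows is sufficient
(95% HDIs cover a true group difference of 2.0 in ~93–96 of 100 runs).
Fits are deterministic given the seed and sampler version. Every fit is
diagnosed with split-Rhat and bulk ESS (arviz); contrasts from fits with
max Rhat > 1.01 are marked unreliable in reports.

Contrasts: `group_difference` is first-group-minus-second at one timepoint
(RPE − TE by default, so negative values mean the TE group is larger);
`slope_difference` is `(μ_g0,t1 − μ_g0,t0) − (μ_g1,t1 − μ_g1,t0)` with
(t0, t1) the fitted time order — *late minus early*, so a larger decrease
in the first group makes the contrast negative. Published analyses of this
protocol print slope differences in the opposite (early-minus-late)
orientation; the evidence is identical up to sign.

The 95% HDI is the narrowest-window estimator: sort the draws, slide a
window of ⌈0.95·n⌉ consecutive order statistics, return the narrowest
(ties to the lowest start). Valid for the unimodal posteriors summarised
here; cross-checked against closed forms (Normal, Exponential) and an
independent implementation. Probability of direction is
`max(share > 0, share < 0)·100` with draws at exactly 0 split evenly,
reported with its dominant sign in [50, 100].

The robust regression (`y = α + β·x`, Student-t residuals) uses the same
machinery with priors `α ~ Normal(ȳ, 100·sd_y)`,
`β ~ Normal(0, 100·sd_y/sd_x)`.

## Pipeline and reproducibility

Tables are TSV ('.' decimal), reports JSON. A run writes per-stage
subdirectories (`01_simulate`, `02_metrics`, `03_infer`) with manifests
recording the package version, config hash, master seed, and row counts; a
config plus seed reproduces stride and metric tables bit-for-bit. Problem
sizes in the shipped tests and acceptance script — 15 + 15 (washout) and
12 + 12 (retention) cohorts, 4 × 1,000-draw fits, a 100-dataset
calibration, 50-stride gait round trips, 10^6-draw HDI checks — are the
package's chosen desk-scale defaults; all scale up through configuration.

## Known limitations

- The generator's exploration magnitudes are smaller than human data (see
  above); it also omits biomechanical limb dynamics, handrail/harness
  effects, reward-magnitude effects (reward is binary), and right-leg
  measures.
- The online detector the lab used may have run on unsmoothed velocity;
  exact equivalence with its real-time output is not claimed.
- Whether excess reward-learning variability lives at the aim or execution
  level is unidentifiable from these measures; the generator defaults
  attribute it to aim shifts after failure but exposes both knobs.
- The cell-means model ignores within-subject pairing across epochs.
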