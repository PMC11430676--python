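# Methods

This note documents the models, defaults, and design choices behind
`nfbtrain`: what the reward engine computes, what the synthetic
participant emulates (and deliberately does not), how the nested
training-effect models are estimated, and where the genuinely open
choices were resolved.

## 1. Protocol and timing

The canonical schedule is 7 sessions with (3, 6, 6, 6, 6, 6, 3) runs —
36 runs of 4 blocks × 12 MSIT trials (block 1 baseline, blocks 2–4
regulation), inter-block interval 7.5 s. A trial is fixation 1.5 s,
stimulus 1 s, blank 3.5 s, feedback 1.5 s (7.5 s total, exactly 5 TRs
at TR = 1.5 s); a 48-trial run spans 382.5 s = 255 TRs. The reward
window is the 2 TRs covering the stimulus second plus the first 2 s of
the blank screen — i.e. 0–3 s after stimulus onset, with **no added
hemodynamic lag** by default. Physiologically a lag would be expected
(the BOLD response peaks ~5–6 s post stimulus); the window placement is
kept as the protocol draws it, and `TrialTiming.hemodynamic_lag_trs`
exposes the lag as configuration. A consequence worth knowing: a
trial's window mostly reflects the hemodynamic tail of the *preceding*
trials, so single-trial feedback is temporally blurred — which is
faithful to how such online protocols actually behave.

MSIT stimuli: the original task uses a fixed list of interference
displays that is not publicly enumerated, so the package constructs the
complete valid space instead — 3 control displays (target at its
congruent position, zero distractors: 100, 020, 003) and 12
interference displays (target digit × incongruent position × repeated
response-digit distractor, e.g. 232) — and samples uniformly. Face
overlays are symbolic labels (happy/angry/scrambled); the package
operates at signal/behavior level, not pixel level.

## 2. Reward engine

Per trial, `BOLDdiff` = mean over the window TRs of
(dACC_L + dACC_R − PAC_L − PAC_R); per run, baseline statistics are the
mean and standard deviation of `BOLDdiff` over the 12 baseline-block
trials; per regulation trial, the raw score is
`c·(BOLDdiff − mean_bl)/std_bl`. Display transforms and accounting
resolve four under-determined details, each chosen once and
configurable where sensible:

- **SD convention**: population SD (divide by n). The statistic
  normalizes a display score rather than estimating a variance;
  `ddof=1` is available.
- **Clamp-then-round**: the score is clipped to [0, 10] first, then
  rounded half-even to 2 decimals, guaranteeing the display bounds
  exactly.
- **Degenerate baseline** (zero SD) raises an error instead of emitting
  infinities; realistic streams never produce exactly zero dispersion.
- **Payout uses displayed values**: earned points are the clamped,
  rounded numbers participants saw; baseline-block trials ("* Points")
  and missed responses ("No Response") earn 0. Bonus =
  min(total × $0.008, $100).

The engine is affine-invariant (replacing every `BOLDdiff` by `a·x + b`
with a > 0 leaves displayed points unchanged, up to a ±0.01 rounding
boundary) and anti-symmetric in the condition factor; both are enforced
as property tests.

## 3. Synthetic participant

Each ROI channel is `level + task·h(t) + gain-modulated h(t) (dACC
only) + AR(1) noise + drift`, sampled at TR midpoints, where `h` is the
SPM double-gamma HRF (peak-normalized) convolved with the 1-s stimulus
boxcar. Defaults (arbitrary scanner units, levels ~1000):

| parameter | default | meaning |
|---|---|---|
| `task_amp` | 6 | stimulus response shared by all four ROI channels |
| `noise_sd`, `ar1_rho` | 4, 0.3 | stationary AR(1) channel noise |
| `drift_amp`, `drift_period` | 2, 128 s | sinusoidal drift, random phase |
| `gain_0`, `gain_slope` | preset | dACC regulation amplitude, per-session change |
| `amp_noise_sd`, `amp_rho` | 2.5, 0.6 | trial-level attention fluctuation (AR(1) across trials) |
| `rt_coupling` | −0.02 s/unit | RT change per unit dACC amplitude |
| `acc_coupling` | +0.25 logit/unit | accuracy change per unit amplitude |

The task response is *common* to dACC and PAC by default so that it
cancels exactly in the contrast; the regulation gain (dACC only,
regulation trials only) is then the only systematic signal the engine
can reward, which makes the null case exactly null. Behavior couples to
the realized per-trial amplitude (gain + attention fluctuation): RT
linearly (truncated to [0.15, 4.5] s), correctness through a logistic,
responding through a logistic in the current motivation report.
Trial-level attention is AR(1)-correlated across trials; without that
autocorrelation the measured window BOLD (which mostly reflects
preceding trials) would carry no information about the same trial's
behavior.

Group presets reproduce the four study arms qualitatively — magnitudes
are the package's own choices, since the study reports directions and
significance rather than generative effect sizes in signal units, and
they are deliberately sized so that parameter recovery succeeds at the
study's arm sizes (they are unanchored to any measured physiology):

- **experimental** (older, up): gain 2.5 + 1.5/session; steady
  motivation; slower baseline RT; mid accuracy rising with gain.
- **age-control** (young, up): gain 7.0, flat across sessions,
  −0.8/run within session; motivation −5/run; near-ceiling accuracy.
- **inverse-control** (older, down): gain −3.0 fading by +0.45/session,
  plus a dACC-specific task offset declining −0.8/session on *all*
  trials — the baseline normalizer itself drifts down, the mechanism
  that erodes this arm's rewards and accuracy.
- **young-down**: gain −2.0, slight drift, near-ceiling accuracy.

Participant draws add heterogeneity (SDs: gain_0 1.0, gain_slope 0.5,
rt_base 0.08 s, acc_intercept 0.3, motivation_0 5). All randomness
descends from one `SeedSequence`; identical seeds give bit-identical
datasets.

What the generator does **not** emulate: voxel-level or image-level
structure, physiological (cardiac/respiratory) noise, motion, scanner
drift nonstationarities, strategy changes, or any nonlinear
gain-learning dynamics. Passing tests therefore demonstrate that the
pipeline is correct and well-calibrated under this generative model,
not that the study's empirical coefficients would be reproduced on real
scanner data.

## 4. Training-effect models

Run-level outcomes: summed displayed points over regulation trials
(0–360); accuracy = correct regulation trials (0–36; a missed response
counts as incorrect); RT = mean over correct regulation trials (missing
if none); dACC ratio = per-trial window dACC/global ratio averaged over
the run's regulation trials — only the TRs that generated points enter,
and regulation trials are used because those are the trials the paper's
outcome scores. Motivation is the post-run 0–100 report.

Predictors: session centered at the grand mean over the rows analysed
(the 36-run schedule is symmetric, so canonical session_c runs −3…+3),
run centered within session, plus their product. Estimation is
`statsmodels` MixedLM with a participant random intercept, fitted by
ML; Wald z and normal-approximation p-values match the field's
reporting shape. Missing outcomes are excluded listwise per model.
Moderation models interact all three predictors with treatment-coded
group (reference: experimental), so main effects are the reference
arm's effects and interactions are departures from it. Random slopes
are not fitted by default (the covariance structure of the original
analysis is unstated); the fallback estimator covers the robustness
question instead.

**Fallback/oracle estimator.** Every within-group fit also computes
per-participant OLS coefficients and a one-sample t-test on them,
implemented from the normal equations with no shared code path. On
balanced designs the two routes agree on the fixed effects (a GLS
identity, verified to 1e-6 in tests); when the mixed fit fails — e.g.
noiseless data with zero residual variance — the result is flagged
non-converged and carries the fallback estimates.

**Trial-level models.** RT: `rt ~ points + dacc` (MixedLM, correct
regulation trials). Accuracy: logistic `correct ~ points + dacc` with
exchangeable within-participant correlation via GEE. A true
random-intercept logistic in statsmodels is only available through a
Bayesian variational approximation that does not yield Wald z/p, so the
population-averaged GEE was chosen as the closest estimator with the
right link and reporting shape. Caveat: GEE sandwich errors are
anti-conservative with very few clusters (noticeable below ~5
participants); the tests use 8+. The `dacc` predictor is the trial's
window dACC/global ratio, matching the run-level outcome definition.
Complete separation (all trials correct or incorrect) returns a flagged
degenerate result rather than an estimate.

## 5. Operating characteristics and problem sizes

Three Monte-Carlo studies characterize the pipeline (sizes chosen as
the package's own scaled designs):

- **Type-I error**: 200 replicates of a null run-level table
  (18 participants, random intercept SD 15, residual SD 20) — the
  session test rejects at ≈ 5% (observed 0.04–0.06 across seeds).
- **Power**: 100 closed-loop replicates of the experimental arm at the
  study's size (n = 18, full 36-run protocol, default presets); the
  within-group session effect on reward points is detected (p < 0.05,
  positive) in ≥ 95% of replicates — comfortably above the 80% the
  study's own sensitivity analysis reports for within-group effects.
  Only the experimental arm is simulated because the within-group fit
  consumes nothing else.
- **Sign recovery**: 100 replicates at 10 participants × 21 runs; the
  GEE accuracy model recovers the positive dACC-coupling sign in ≈ 99%.

## 6. Numerical conventions and edge cases

Sessions/runs/blocks/trials are 1-based; TR indices 0-based. Streams
are sampled at TR midpoints. Tables are TSV with `%.6f` floats and no
timestamps, so reruns are byte-identical and manifests (SHA-256 per
file) change iff config, seed, or outputs change. The event-regressor
matrix is cached per run structure, which is what makes the replicate
studies affordable. Degenerate inputs — empty runs, truncated streams,
sub-2-trial baselines, zero baseline dispersion, single-session
designs, constant motivation, missing reference group — raise typed
errors or warnings rather than propagating silently.

One physical subtlety: with a canonical double-gamma HRF, the first
trial after an inter-block gap sits in the *undershoot* of the previous
block's response, so its window BOLDdiff can dip slightly below
baseline even with a positive gain. Separation between regulation and
baseline windows is therefore a steady-state property (and holds
strictly for trials after each block's first).

## 7. Known limitations

- Generative magnitudes are unanchored; only directions and the
  qualitative four-arm pattern are calibrated.
- The global signal is simulated as a separate smooth channel, not as
  an aggregate of the ROI channels.
- The GEE accuracy model is population-averaged, not
  participant-conditional; coefficients are attenuated relative to a
  conditional logistic model.
- No correction for multiple outcomes is applied (matching the
  original reporting); interpret families of p-values accordingly.
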