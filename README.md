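# nfbtrain

Closed-loop real-time fMRI neurofeedback training — protocol, reward
engine, synthetic participants, and nested training-effect analysis —
runnable entirely offline.

## The problem

Real-time fMRI neurofeedback trains volitional control of a target
brain region: while the participant performs a task in the scanner,
each trial ends with a reward display computed from their current BOLD
signal. The protocol implemented here targets bilateral dorsal anterior
cingulate cortex (dACC) during the Multi-Source Interference Task
(MSIT, a selective-attention task: report the one digit in a
three-digit string that differs from the other two, e.g. `100` or
`232`, under positional and face-overlay interference). Training spans
7 sessions of (3, 6, 6, 6, 6, 6, 3) runs — 36 runs, each with one
baseline block and three regulation blocks of 12 trials.

The core computation is the per-trial reward. First the ROI-contrast
BOLD difference over the trial's 2-TR (3 s) data-collection window,
with primary auditory cortex (PAC) as a task-unrelated control region:

    BOLDdiff = mean over window TRs of (dACC_L + dACC_R − PAC_L − PAC_R)

then a z-score against the run's baseline block, signed by the
regulation direction *c* (+1 up, −1 down):

    score = c · (BOLDdiff_trial − mean(BOLDdiff_baseline)) / std(BOLDdiff_baseline)

clamped to [0, 10], rounded to two decimals, displayed, and paid out at
$0.008/point with a $100 cap. Analysis of training success fits
two-level (runs/sessions within participants) regressions of run-level
outcomes — reward points (0–360), dACC/global BOLD ratio, correct-trial
reaction time, accuracy (0–36) — on grand-mean-centered session and
within-session-centered run, with group moderation against the
up-regulation reference arm.

Because raw scanner data are not reproducible at desk scale, the
package ships a **closed-loop synthetic participant**: ROI streams
(canonical-HRF-convolved task responses, AR(1) noise, slow drift), a
regulation gain that grows across sessions per group preset, and
behavior (RT, accuracy, responding) coupled to the realized dACC
amplitude. Every simulated point is produced by the same engine that
would score a scanner stream.

## Worked example

```python
import numpy as np
from nfbtrain import build_protocol, run_feedback_session, simulate_roi_run
from nfbtrain.simulate import HemodynamicModel

protocol = build_protocol("up")              # 7 sessions, 36 runs
run = next(protocol.runs())                  # 4 blocks x 12 trials
stream = simulate_roi_run(run, protocol.trial_timing, HemodynamicModel(),
                          gain=6.0, rng=np.random.default_rng(0))
outcomes, baseline = run_feedback_session(stream, run,
                                          protocol.trial_timing, c=+1)
total = sum(o.earned_points for o in outcomes)
print(f"baseline mean={baseline.mean_diff:.2f} sd={baseline.std_diff:.2f}")
print(f"run total = {total:.2f} points "
      f"(first regulation trial: {outcomes[12].displayed_points:.2f})")
```

prints

```
baseline mean=101.29 sd=6.54
run total = 23.34 points (first regulation trial: 0.00)
```

The baseline block's twelve BOLDdiff values normalize the run; a
regulation gain of 6 signal units yields about 23 of the 360 attainable
points (the first regulation trial scores low because the hemodynamic
response to its own stimulus has barely risen inside its 3 s window).

The full study-shaped pipeline lives in `analysis/`:

```bash
python analysis/01_simulate_cohort.py        # 46 participants, 4 arms
python analysis/02_rescore_streams.py        # engine re-scoring check
python analysis/03_training_models.py        # session/run mixed models
python analysis/04_brain_behavior.py         # trial-level couplings
python analysis/05_motivation.py             # run-wise motivation decline
python analysis/06_operating_characteristics.py   # type-I error, power
```

or, from the command line, `nfbtrain simulate|feedback|analyze|report`
(see `nfbtrain --help`).

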