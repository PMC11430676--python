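"""Operating-characteristic studies of the nested training-effect models.

These are the package's parameter-recovery companions: the study's
headline regression coefficients come from raw scanner data that a desk
reproduction cannot access, so what can be verified instead is that the
estimator pipeline (a) holds its nominal type-I error on null data,
(b) detects the experimental group's session effect at the study's
sample size under the default generative presets, and (c) recovers the
signs of the generative brain-behavior couplings.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .analysis import brain_behavior_model, fit_training_model, summarize_runs
from .protocol import CANONICAL_RUNS_PER_SESSION
from .simulate import GROUP_PRESETS, simulate_training_course

__all__ = [
    "simulate_null_run_summaries",
    "type_one_error",
    "session_effect_power",
    "acc_coupling_sign_recovery",
]


def simulate_null_run_summaries(
    n_participants: int,
    rng: np.random.Generator,
    runs_per_session: Sequence[int] = CANONICAL_RUNS_PER_SESSION,
    mean: float = 50.0,
    intercept_sd: float = 15.0,
    resid_sd: float = 20.0,
) -> pd.DataFrame:
    """Run-level reward-point table with no session/run structure.

    Participant random intercepts plus i.i.d. run residuals around a
    flat mean — the null model of the session test. Lightweight (no
    BOLD simulation) so large replicate counts stay cheap.
    """
    rows = []
    for i in range(n_participants):
        b = rng.normal(0.0, intercept_sd)
        for s, n_runs in enumerate(runs_per_session, start=1):
            for r in range(1, n_runs + 1):
                rows.append((f"sub-{i + 1:03d}", s, r,
                             mean + b + rng.normal(0.0, resid_sd)))
    return pd.DataFrame(rows, columns=["participant", "session", "run",
                                       "reward_points"])


def type_one_error(
    n_reps: int = 200,
    n_participants: int = 18,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the session effect on null run-level data."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    rejections = 0
    for _ in range(n_reps):
        data = simulate_null_run_summaries(n_participants, rng)
        fit = fit_training_model(data, "reward_points")
        if fit.pvalue("session_c") < alpha:
            rejections += 1
    return {"rate": rejections / n_reps, "n_reps": n_reps,
            "n_participants": n_participants, "alpha": alpha}


def session_effect_power(
    n_reps: int = 100,
    n_participants: int = 18,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Detection rate of the experimental session effect on reward points.

    Each replicate simulates the experimental arm (older up-regulators,
    default preset, full 7-session protocol) closed loop, summarises the
    runs and fits the within-group model; detection means p(session) <
    alpha with a positive estimate. Only the experimental arm is
    simulated because the within-group fit consumes nothing else.
    """
    detected = 0
    slopes = []
    for k in range(n_reps):
        rep_seed = int(np.random.SeedSequence([seed, 202, k]).generate_state(1)[0]
                       % (2**31 - 1))
        ds = simulate_training_course(
            n_per_group={"experimental": n_participants},
            seed=rep_seed, assign_stims=False)
        fit = fit_training_model(summarize_runs(ds.trials), "reward_points")
        est = fit.estimate("session_c")
        slopes.append(est)
        if fit.pvalue("session_c") < alpha and est > 0:
            detected += 1
    return {"rate": detected / n_reps, "n_reps": n_reps,
            "n_participants": n_participants, "alpha": alpha,
            "mean_session_slope": float(np.mean(slopes))}


def acc_coupling_sign_recovery(
    n_reps: int = 100,
    n_participants: int = 10,
    runs_per_session: Sequence[int] = (3, 6, 6, 6),
    seed: int = 0,
) -> dict:
    """How often the accuracy model recovers a positive dACC coupling.

    Scaled-down experimental-arm replicates (the coupling is a trial-
    level effect, so a few hundred trials per participant suffice);
    reports the fraction of replicates whose GEE dACC coefficient on
    correctness is positive, matching the generative direction.
    """
    correct_sign = 0
    for k in range(n_reps):
        rep_seed = int(np.random.SeedSequence([seed, 303, k]).generate_state(1)[0]
                       % (2**31 - 1))
        ds = simulate_training_course(
            n_per_group={"experimental": n_participants},
            seed=rep_seed, runs_per_session=runs_per_session,
            assign_stims=False)
        fits = brain_behavior_model(
            ds.trials[ds.trials["group"] == "experimental"])
        if fits["accuracy"].estimate("dacc_sig") > 0:
            correct_sign += 1
    return {"rate": correct_sign / n_reps, "n_reps": n_reps,
            "n_participants": n_participants,
            "generative_coupling": GROUP_PRESETS["experimental"].acc_coupling}
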