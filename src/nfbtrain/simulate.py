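"""Synthetic participants: ROI BOLD streams and behavior for the closed loop.

The generator produces the statistical structure the downstream analysis
assumes, so the whole train-score-analyze loop runs without a scanner:

* ROI streams: per-channel baseline level + a canonical-HRF-convolved
  response to every 1-s MSIT stimulus + AR(1) noise + slow sinusoidal
  drift, sampled on the 1.5-s TR grid. The task response is common to
  all four ROI channels by default, so it cancels exactly in the
  dACC-PAC contrast; the participant's *regulation gain* adds to the two
  dACC channels during regulation trials only and is what the reward
  engine can detect.
* Regulation learning: the gain evolves linearly across sessions (and
  optionally across runs within a session), with participant-level
  heterogeneity in starting gain and learning slope.
* Behavior: reaction time is linear in the realized trial-level dACC
  amplitude (faster with more dACC drive), correctness is a logistic
  function of the same amplitude, and responding at all follows the
  current motivation level. Trial amplitudes carry AR(1) fluctuations
  ("attention drifts"), which is what makes the measured window BOLD
  informative about the same trial's behavior.
* Group presets reproduce the study's four-arm design qualitatively:
  older up-regulation learners, young up-regulators starting near
  ceiling with declining motivation, older down-regulators whose dACC
  drifts down across baseline trials, and young down-regulators.

All randomness flows from an explicit seed; identical seeds give
bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import engine as _engine
from .protocol import (
    CANONICAL_RUNS_PER_SESSION,
    RunSpec,
    TrainingProtocol,
    TrialTiming,
    assign_stimuli,
    build_protocol,
    run_n_scans,
    trial_timeline,
)

__all__ = [
    "HemodynamicModel",
    "AgentParams",
    "SimulatedDataset",
    "GROUP_PRESETS",
    "GROUP_SIZES",
    "unit_response",
    "event_matrix",
    "simulate_roi_run",
    "p_correct",
    "p_respond",
    "simulate_behavior",
    "simulate_training_course",
]


# ---------------------------------------------------------------------------
# hemodynamics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HemodynamicModel:
    """Signal model for one ROI stream.

    ``task_amp`` is the stimulus-evoked amplitude shared by all four ROI
    channels (per-channel signal units at the HRF peak); ``noise_sd`` is
    the stationary SD of the per-channel AR(1) noise; ``drift_amp`` /
    ``drift_period`` parameterise a slow sinusoidal drift with a random
    phase per channel. Levels are arbitrary scanner units (~1000).
    """

    task_amp: float = 6.0
    noise_sd: float = 4.0
    ar1_rho: float = 0.3
    drift_amp: float = 2.0
    drift_period: float = 128.0
    baseline_levels: Mapping[str, float] = field(
        default_factory=lambda: {
            "dacc_l": 1000.0, "dacc_r": 1005.0,
            "pac_l": 950.0, "pac_r": 955.0,
        })
    global_level: float = 980.0
    global_task_amp: float = 3.0
    global_noise_sd: float = 2.0
    hrf_dt: float = 0.1

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.global_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must lie in [0, 1)")
        if self.hrf_dt <= 0:
            raise ValueError("hrf_dt must be positive")


_UNIT_RESPONSE_CACHE: dict[tuple, np.ndarray] = {}
_EVENT_MATRIX_CACHE: dict[tuple, np.ndarray] = {}


def unit_response(stimulus_duration: float = 1.0, dt: float = 0.1) -> np.ndarray:
    """Canonical (SPM double-gamma) response to one stimulus, peak 1.

    Boxcar of the stimulus duration convolved with the canonical HRF on a
    fine grid of step ``dt`` seconds.
    """
    key = (round(stimulus_duration, 6), round(dt, 6))
    if key not in _UNIT_RESPONSE_CACHE:
        from nilearn.glm.first_level.hemodynamic_models import spm_hrf

        hrf = spm_hrf(dt, oversampling=1)
        box = np.ones(max(1, int(round(stimulus_duration / dt))))
        resp = np.convolve(box, hrf)
        resp = resp / resp.max()
        _UNIT_RESPONSE_CACHE[key] = resp
    return _UNIT_RESPONSE_CACHE[key]


def event_matrix(run: RunSpec, timing: TrialTiming, dt: float = 0.1) -> np.ndarray:
    """(n_scans, n_trials) matrix of per-trial unit responses on the TR grid.

    Column j holds the HRF response to trial j's stimulus, sampled at TR
    midpoints; a stream channel is then ``levels + E @ amplitudes + noise``.
    Cached per run structure, so repeated simulation is cheap.
    """
    events = trial_timeline(run, timing)
    onsets = tuple(round(e.onset + timing.fixation, 6) for e in events)
    n_scans = run_n_scans(run, timing)
    key = (onsets, n_scans, round(timing.tr, 6), round(timing.stimulus, 6),
           round(dt, 6))
    if key not in _EVENT_MATRIX_CACHE:
        resp = unit_response(timing.stimulus, dt)
        t_mid = (np.arange(n_scans) + 0.5) * timing.tr
        mat = np.zeros((n_scans, len(onsets)))
        for j, s in enumerate(onsets):
            tau = t_mid - s
            idx = np.floor(tau / dt).astype(int)
            valid = (idx >= 0) & (idx < resp.size)
            mat[valid, j] = resp[idx[valid]]
        _EVENT_MATRIX_CACHE[key] = mat
    return _EVENT_MATRIX_CACHE[key]


def _ar1(rng: np.random.Generator, n: int, m: int, sd: float, rho: float) -> np.ndarray:
    """(n, m) stationary AR(1) noise columns with stationary SD ``sd``."""
    if sd == 0:
        return np.zeros((n, m))
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), size=(n, m))
    eps[0] = rng.normal(0.0, sd, size=m)  # stationary start
    return lfilter([1.0], [1.0, -rho], eps, axis=0)


def simulate_roi_run(
    run: RunSpec,
    timing: TrialTiming,
    hemo: HemodynamicModel,
    gain: float,
    rng: np.random.Generator,
    dacc_mod: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate one run's ROI stream.

    ``gain`` is the dACC regulation amplitude (per dACC channel, signal
    units) applied on regulation trials only; ``dacc_mod`` optionally
    gives the full per-trial dACC amplitude modulation instead (e.g.
    including trial-level attention fluctuations), overriding ``gain``.
    """
    events = trial_timeline(run, timing)
    n_scans = run_n_scans(run, timing)
    E = event_matrix(run, timing, hemo.hrf_dt)
    if dacc_mod is None:
        dacc_mod = np.array([
            gain if e.block_kind == "regulation" else 0.0 for e in events])
    else:
        dacc_mod = np.asarray(dacc_mod, dtype=float)
        if dacc_mod.shape != (len(events),):
            raise ValueError("dacc_mod must have one amplitude per trial")

    task = E.sum(axis=1)  # unit-amplitude response to every stimulus
    dacc_extra = E @ dacc_mod

    noise = _ar1(rng, n_scans, 4, hemo.noise_sd, hemo.ar1_rho)
    gnoise = _ar1(rng, n_scans, 1, hemo.global_noise_sd, hemo.ar1_rho)[:, 0]
    t = np.arange(n_scans) * timing.tr
    if hemo.drift_amp > 0:
        phases = rng.uniform(0, 2 * np.pi, size=5)
        drift = hemo.drift_amp * np.sin(
            2 * np.pi * t[:, None] / hemo.drift_period + phases[None, :])
    else:
        rng.uniform(0, 2 * np.pi, size=5)  # keep the rng stream aligned
        drift = np.zeros((n_scans, 5))

    cols = {"time": t}
    for j, ch in enumerate(_engine.ROI_CHANNELS):
        level = hemo.baseline_levels[ch]
        sig = level + hemo.task_amp * task + noise[:, j] + drift[:, j]
        if ch.startswith("dacc"):
            sig = sig + dacc_extra
        cols[ch] = sig
    cols["global"] = (hemo.global_level + hemo.global_task_amp * task
                      + gnoise + drift[:, 4])
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# agents
# ---------------------------------------------------------------------------


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one simulated participant (or group preset).

    The regulation gain at session s, run r (1-based) is
    ``gain_0 + gain_slope*(s-1) + gain_run_slope*(r-1)`` (per-channel
    dACC signal units). ``dacc_task_offset_0/_session_slope`` add a
    dACC-specific task amplitude on *all* trials (baseline included),
    which moves the baseline normalizer itself — the mechanism behind
    the down-regulation control group's declining baseline signal.
    Behavioral couplings act on the realized trial amplitude:
    rt = rt_base + rt_session_slope*(s-1) + rt_coupling*amp + noise and
    P(correct) = logistic(acc_intercept + acc_coupling*amp).
    """

    group: str
    condition: str  # 'up' | 'down'
    gain_0: float
    gain_slope: float
    gain_run_slope: float = 0.0
    dacc_task_offset_0: float = 0.0
    dacc_task_session_slope: float = 0.0
    amp_noise_sd: float = 2.5
    amp_rho: float = 0.6
    motivation_0: float = 75.0
    motivation_run_slope: float = 0.0
    motivation_noise_sd: float = 4.0
    rt_base: float = 1.0
    rt_coupling: float = -0.02  # seconds per amplitude unit (<= 0)
    rt_session_slope: float = 0.0
    rt_noise_sd: float = 0.25
    acc_intercept: float = 1.6  # log-odds
    acc_coupling: float = 0.25  # log-odds per amplitude unit (>= 0)
    resp_intercept: float = 3.3
    resp_motivation_coef: float = 0.04
    # between-participant heterogeneity (SDs of participant draws)
    gain_0_sd: float = 1.0
    gain_slope_sd: float = 0.5
    rt_base_sd: float = 0.08
    acc_intercept_sd: float = 0.3
    motivation_0_sd: float = 5.0

    def gain_at(self, session: int, run_within_session: int = 1) -> float:
        return (self.gain_0 + self.gain_slope * (session - 1)
                + self.gain_run_slope * (run_within_session - 1))

    def dacc_offset_at(self, session: int) -> float:
        return (self.dacc_task_offset_0
                + self.dacc_task_session_slope * (session - 1))

    def motivation_at(self, run_within_session: int) -> float:
        return float(np.clip(
            self.motivation_0
            + self.motivation_run_slope * (run_within_session - 1), 0, 100))


#: Qualitative four-arm presets. Magnitudes are the package's own choices
#: (the study reports directions and significance, not generative effect
#: sizes in signal units); see docs/methods.md.
GROUP_PRESETS: dict[str, AgentParams] = {
    # older adults, up-regulation: learns across sessions
    "experimental": AgentParams(
        group="experimental", condition="up",
        gain_0=2.5, gain_slope=1.5,
        motivation_0=75.0, rt_base=1.05, acc_intercept=1.6),
    # young adults, up-regulation: high start, no learning, motivation
    # declines across runs within a session (and points with it)
    "age-control": AgentParams(
        group="age-control", condition="up",
        gain_0=7.0, gain_slope=0.0, gain_run_slope=-0.8,
        motivation_0=85.0, motivation_run_slope=-5.0,
        rt_base=0.75, acc_intercept=3.2),
    # older adults, down-regulation: early down-regulation success fades
    # while the dACC task response itself drifts down across sessions
    "inverse-control": AgentParams(
        group="inverse-control", condition="down",
        gain_0=-3.0, gain_slope=0.45,
        dacc_task_offset_0=4.0, dacc_task_session_slope=-0.8,
        motivation_0=72.0, rt_base=1.0, rt_session_slope=-0.015,
        acc_intercept=1.6),
    # young adults, down-regulation: near-ceiling accuracy, small drift
    "young-down": AgentParams(
        group="young-down", condition="down",
        gain_0=-2.0, gain_slope=-0.2,
        motivation_0=80.0, rt_base=0.78, rt_session_slope=-0.01,
        acc_intercept=3.2),
}

#: Study-arm sample sizes (experimental group oversampled 2:1).
GROUP_SIZES: dict[str, int] = {
    "experimental": 18,
    "age-control": 10,
    "inverse-control": 9,
    "young-down": 9,
}


def p_correct(dacc_amp: float, agent: AgentParams) -> float:
    """Probability of a correct response given the trial's dACC amplitude."""
    return float(_logistic(agent.acc_intercept + agent.acc_coupling * dacc_amp))


def p_respond(motivation: float, agent: AgentParams) -> float:
    """Probability of responding at all, increasing in current motivation."""
    return float(_logistic(agent.resp_intercept
                           + agent.resp_motivation_coef * (motivation - 50.0)))


def simulate_behavior(
    trial,
    dacc_amp: float,
    agent: AgentParams,
    rng: np.random.Generator,
    motivation: float | None = None,
    session: int = 1,
) -> tuple[bool, float, bool]:
    """Simulate one trial's (responded, rt, correct).

    RT is truncated to [0.15 s, 4.5 s] (a response must land before the
    feedback screen); a missed response yields rt = nan and correct=False.
    """
    motivation = agent.motivation_0 if motivation is None else motivation
    responded = rng.random() < p_respond(motivation, agent)
    if not responded:
        return False, float("nan"), False
    rt = (agent.rt_base + agent.rt_session_slope * (session - 1)
          + agent.rt_coupling * dacc_amp
          + rng.normal(0.0, agent.rt_noise_sd))
    rt = float(np.clip(rt, 0.15, 4.5))
    correct = rng.random() < p_correct(dacc_amp, agent)
    return True, rt, bool(correct)


# ---------------------------------------------------------------------------
# closed-loop dataset
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    """A closed-loop simulated cohort.

    ``trials`` holds one row per trial with the engine's scoring attached
    (the simulation is closed-loop: every displayed point comes from
    :func:`nfbtrain.engine.run_feedback_session` on the simulated
    stream). ``streams`` maps (participant, session, run) to the ROI
    stream when streams are kept.
    """

    trials: pd.DataFrame
    agents: dict[str, AgentParams]
    protocols: dict[str, TrainingProtocol]
    seed: int
    streams: dict[tuple[str, int, int], pd.DataFrame] | None = None


def _draw_agent(preset: AgentParams, rng: np.random.Generator) -> AgentParams:
    """Participant-level parameter draw around a group preset."""
    return replace(
        preset,
        gain_0=float(rng.normal(preset.gain_0, preset.gain_0_sd)),
        gain_slope=float(rng.normal(preset.gain_slope, preset.gain_slope_sd)),
        rt_base=float(rng.normal(preset.rt_base, preset.rt_base_sd)),
        acc_intercept=float(rng.normal(preset.acc_intercept,
                                       preset.acc_intercept_sd)),
        motivation_0=float(np.clip(
            rng.normal(preset.motivation_0, preset.motivation_0_sd), 0, 100)),
    )


def _window_means(stream: pd.DataFrame, windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dacc = 0.5 * (stream["dacc_l"].to_numpy() + stream["dacc_r"].to_numpy())
    glob = stream["global"].to_numpy()
    return dacc[windows].mean(axis=1), glob[windows].mean(axis=1)


def simulate_participant(
    participant: str,
    agent: AgentParams,
    protocol: TrainingProtocol,
    hemo: HemodynamicModel,
    rng: np.random.Generator,
    keep_streams: bool = False,
    assign_stims: bool = True,
) -> tuple[pd.DataFrame, dict[tuple[str, int, int], pd.DataFrame]]:
    """Run one participant through the whole protocol, closed loop."""
    c = protocol.condition_factor
    timing = protocol.trial_timing
    chunks: list[dict] = []
    streams: dict[tuple[str, int, int], pd.DataFrame] = {}
    for run in protocol.runs():
        s, r = run.session_index, run.run_index_within_session
        run_spec = assign_stimuli(run, rng) if assign_stims else run
        events = trial_timeline(run_spec, timing)
        n_trials = len(events)
        is_reg = np.array([e.block_kind == "regulation" for e in events])

        gain = agent.gain_at(s, r)
        offset = agent.dacc_offset_at(s)
        eta = _ar1(rng, n_trials, 1, agent.amp_noise_sd, agent.amp_rho)[:, 0]
        amps = offset + np.where(is_reg, gain, 0.0) + eta

        stream = simulate_roi_run(run_spec, timing, hemo, gain, rng,
                                  dacc_mod=amps)

        motivation = float(np.clip(
            agent.motivation_at(r) + rng.normal(0, agent.motivation_noise_sd),
            0, 100))
        p_resp = p_respond(motivation, agent)
        responded = rng.random(n_trials) < p_resp
        rt = (agent.rt_base + agent.rt_session_slope * (s - 1)
              + agent.rt_coupling * amps
              + rng.normal(0, agent.rt_noise_sd, n_trials))
        rt = np.clip(rt, 0.15, 4.5)
        pc = _logistic(agent.acc_intercept + agent.acc_coupling * amps)
        correct = (rng.random(n_trials) < pc) & responded
        rt = np.where(responded, rt, np.nan)

        outcomes, _bl = _engine.run_feedback_session(
            stream, run_spec, timing, c, responded=responded.tolist(),
            clamp=protocol.points_clamp)

        windows = np.array([e.window_trs for e in events])
        w_dacc, w_glob = _window_means(stream, windows)

        stims = [t.stimulus for _, _, t in run_spec.trials()]
        chunks.append({
            "participant": np.repeat(participant, n_trials),
            "group": np.repeat(agent.group, n_trials),
            "condition": np.repeat(agent.condition, n_trials),
            "session": np.repeat(s, n_trials),
            "run": np.repeat(r, n_trials),
            "block": np.array([e.block_number for e in events]),
            "block_kind": np.array([e.block_kind for e in events]),
            "trial": np.array([e.trial_in_run for e in events]),
            "stimulus": np.array([st.as_string() if st else "" for st in stims]),
            "face_overlay": np.array([st.face_overlay if st else "" for st in stims]),
            "dacc_amp": amps,
            "responded": responded,
            "rt": rt,
            "correct": correct,
            "raw_score": np.array([o.raw_score for o in outcomes]),
            "displayed_points": np.array([o.displayed_points for o in outcomes]),
            "earned_points": np.array([o.earned_points for o in outcomes]),
            "display": np.array([o.display for o in outcomes]),
            "window_dacc": w_dacc,
            "window_global": w_glob,
            "motivation": np.repeat(motivation, n_trials),
        })
        if keep_streams:
            streams[(participant, s, r)] = stream
    cols = {k: np.concatenate([ch[k] for ch in chunks]) for k in chunks[0]}
    return pd.DataFrame(cols), streams


def simulate_training_course(
    n_per_group: Mapping[str, int] | None = None,
    presets: Mapping[str, AgentParams] | None = None,
    hemo: HemodynamicModel | None = None,
    seed: int = 0,
    runs_per_session: Sequence[int] = CANONICAL_RUNS_PER_SESSION,
    trials_per_block: int = 12,
    keep_streams: bool = False,
    assign_stims: bool = True,
) -> SimulatedDataset:
    """Simulate a full multi-group cohort through the training protocol.

    Defaults reproduce the study's arms and sizes: experimental n=18,
    age-control n=10, inverse-control n=9, young-down n=9, each over 7
    sessions of (3, 6, 6, 6, 6, 6, 3) runs. The loop is closed: every
    stream is scored by the reward engine with the group's condition
    factor, and behavior is coupled to the realized dACC amplitudes.
    """
    n_per_group = dict(n_per_group if n_per_group is not None else GROUP_SIZES)
    presets = dict(presets if presets is not None else GROUP_PRESETS)
    hemo = hemo or HemodynamicModel()
    for g, n in n_per_group.items():
        if g not in presets:
            raise ValueError(f"no preset for group {g!r}")
        if n < 1:
            raise ValueError(f"need at least one participant in group {g!r}")

    protocols = {
        g: build_protocol(presets[g].condition,
                          runs_per_session=runs_per_session,
                          trials_per_block=trials_per_block)
        for g in n_per_group
    }

    root = np.random.SeedSequence(seed)
    frames: list[pd.DataFrame] = []
    agents: dict[str, AgentParams] = {}
    streams: dict[tuple[str, int, int], pd.DataFrame] = {}
    pid_counter = 0
    for g in sorted(n_per_group):  # sorted: group order never affects seeds
        for k in range(n_per_group[g]):
            pid_counter += 1
            pid = f"sub-{pid_counter:03d}"
            rng = np.random.default_rng(root.spawn(1)[0])
            agent = _draw_agent(presets[g], rng)
            agents[pid] = agent
            tdf, st = simulate_participant(
                pid, agent, protocols[g], hemo, rng,
                keep_streams=keep_streams, assign_stims=assign_stims)
            frames.append(tdf)
            streams.update(st)
    trials = pd.concat(frames, ignore_index=True)
    return SimulatedDataset(trials=trials, agents=agents, protocols=protocols,
                            seed=seed, streams=streams if keep_streams else None)
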