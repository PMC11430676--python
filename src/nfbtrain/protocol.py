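"""Training protocol: session/run/block/trial schedule, timing, and MSIT stimuli.

The canonical protocol comprises seven scanning sessions with
(3, 6, 6, 6, 6, 6, 3) neurofeedback training runs — 36 runs in total.
Each run holds four blocks of 12 Multi-Source Interference Task (MSIT)
trials: one baseline block (scored silently, it calibrates the reward
normalizer) followed by three regulation blocks (each trial ends with a
reward-point feedback screen). A trial is fixation (1.5 s), stimulus
(1 s), blank screen (3.5 s) and feedback (1.5 s); the reward computation
reads the two 1.5-s TRs that cover the stimulus second plus the first
2 s of the blank screen.

Everything here is structural and deterministic apart from MSIT stimulus
sampling, which draws uniformly from the enumerated valid stimulus space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "ProtocolError",
    "TrialTiming",
    "MSITStimulus",
    "TrialSpec",
    "BlockSpec",
    "RunSpec",
    "SessionSpec",
    "TrainingProtocol",
    "TrialEvent",
    "CANONICAL_RUNS_PER_SESSION",
    "FACE_OVERLAYS",
    "build_protocol",
    "enumerate_stimuli",
    "generate_msit_trial",
    "assign_stimuli",
    "trial_timeline",
    "run_duration",
    "run_n_scans",
    "condition_factor",
]


class ProtocolError(ValueError):
    """A protocol structure violates one of its invariants."""


CANONICAL_RUNS_PER_SESSION: tuple[int, ...] = (3, 6, 6, 6, 6, 6, 3)
FACE_OVERLAYS: tuple[str, ...] = ("happy", "angry", "scrambled")
RESPONSE_DIGITS: tuple[int, ...] = (1, 2, 3)

Condition = Literal["up", "down"]
BlockKind = Literal["baseline", "regulation"]
TrialType = Literal["interference", "control"]


def condition_factor(condition: str) -> int:
    """Map a regulation direction to the signed condition factor c.

    Up-regulation rewards increases of the dACC-PAC contrast (c = +1),
    down-regulation rewards decreases (c = -1).
    """
    try:
        return {"up": +1, "down": -1}[condition]
    except KeyError:
        raise ProtocolError(
            f"condition must be 'up' or 'down', got {condition!r}"
        ) from None


# ---------------------------------------------------------------------------
# timing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialTiming:
    """Within-trial event durations (seconds) and the feedback TR window.

    ``hemodynamic_lag_trs`` shifts the feedback window later on the TR
    grid; the default of 0 places it exactly over the stimulus second
    plus the following 2 s of blank screen, with no added lag.
    """

    fixation: float = 1.5
    stimulus: float = 1.0
    blank: float = 3.5
    feedback: float = 1.5
    tr: float = 1.5
    feedback_window_trs: int = 2
    hemodynamic_lag_trs: int = 0

    def __post_init__(self) -> None:
        for name in ("fixation", "stimulus", "blank", "feedback", "tr"):
            if not (getattr(self, name) > 0):
                raise ProtocolError(f"timing field {name!r} must be positive")
        if self.feedback_window_trs < 1:
            raise ProtocolError("feedback_window_trs must be >= 1")
        if self.hemodynamic_lag_trs < 0:
            raise ProtocolError("hemodynamic_lag_trs must be >= 0")

    @property
    def trial_duration(self) -> float:
        return self.fixation + self.stimulus + self.blank + self.feedback

    @property
    def window_duration(self) -> float:
        """Length of the data-collection window in seconds (2 TRs -> 3 s)."""
        return self.feedback_window_trs * self.tr


# ---------------------------------------------------------------------------
# MSIT stimuli
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MSITStimulus:
    """One three-digit MSIT display, e.g. (2, 3, 2): press 3.

    Exactly one digit (the target, always in 1-3) differs from the other
    two. Control trials pad with zeros and put the target at the position
    matching its identity (100, 020, 003); interference trials repeat a
    different response digit and displace the target from its congruent
    position (e.g. 232). A face (or scrambled image) behind the digits
    adds a further interference source; it is represented by its label.
    """

    digits: tuple[int, int, int]
    target_digit: int
    target_position: int  # 1-based
    face_overlay: str
    trial_type: str

    def __post_init__(self) -> None:
        d = self.digits
        if len(d) != 3 or any(x not in (0, 1, 2, 3) for x in d):
            raise ProtocolError(f"digits must be a triple over 0-3, got {d}")
        if self.target_digit not in RESPONSE_DIGITS:
            raise ProtocolError("target_digit must be 1, 2 or 3")
        if not 1 <= self.target_position <= 3:
            raise ProtocolError("target_position must be 1-3")
        if d[self.target_position - 1] != self.target_digit:
            raise ProtocolError("target_digit does not sit at target_position")
        others = [x for i, x in enumerate(d) if i != self.target_position - 1]
        if others[0] != others[1] or others[0] == self.target_digit:
            raise ProtocolError("the two distractor digits must match each "
                                "other and differ from the target")
        if self.trial_type == "control":
            if others[0] != 0 or self.target_position != self.target_digit:
                raise ProtocolError("control trials use zero distractors with "
                                    "the target at its congruent position")
        elif self.trial_type == "interference":
            if others[0] not in RESPONSE_DIGITS:
                raise ProtocolError("interference distractors must be "
                                    "response digits (1-3)")
            if self.target_position == self.target_digit:
                raise ProtocolError("interference targets sit at an "
                                    "incongruent position")
        else:
            raise ProtocolError(f"unknown trial_type {self.trial_type!r}")

    def as_string(self) -> str:
        return "".join(str(x) for x in self.digits)


def enumerate_stimuli(trial_type: str) -> list[tuple[tuple[int, int, int], int, int]]:
    """Enumerate every valid (digits, target_digit, target_position).

    Control: 3 stimuli (100, 020, 003). Interference: target digit x
    incongruent position x repeated response-digit distractor = 12.
    """
    out = []
    if trial_type == "control":
        for t in RESPONSE_DIGITS:
            digits = [0, 0, 0]
            digits[t - 1] = t
            out.append((tuple(digits), t, t))
    elif trial_type == "interference":
        for t, p, dist in itertools.product(RESPONSE_DIGITS, (1, 2, 3), RESPONSE_DIGITS):
            if p == t or dist == t:
                continue
            digits = [dist, dist, dist]
            digits[p - 1] = t
            out.append((tuple(digits), t, p))
    else:
        raise ProtocolError(f"unknown trial_type {trial_type!r}")
    return out


def generate_msit_trial(
    rng: np.random.Generator,
    trial_type: str = "interference",
    face_set: Sequence[str] = FACE_OVERLAYS,
) -> MSITStimulus:
    """Sample one valid MSIT stimulus uniformly, with a uniform overlay."""
    if len(face_set) == 0:
        raise ProtocolError("face_set must be non-empty")
    space = enumerate_stimuli(trial_type)
    digits, target, pos = space[rng.integers(len(space))]
    face = face_set[rng.integers(len(face_set))]
    return MSITStimulus(digits, target, pos, face, trial_type)


# ---------------------------------------------------------------------------
# schedule structures
# ---------------------------------------------------------------------------


@dataclass
class TrialSpec:
    index_in_block: int  # 1-based
    trial_type: str = "interference"
    stimulus: MSITStimulus | None = None


@dataclass
class BlockSpec:
    kind: str
    trials: list[TrialSpec]
    inter_block_interval: float = 7.5

    def __post_init__(self) -> None:
        if self.kind not in ("baseline", "regulation"):
            raise ProtocolError(f"block kind must be baseline/regulation, got {self.kind!r}")
        if not self.inter_block_interval >= 0:
            raise ProtocolError("inter_block_interval must be >= 0")


@dataclass
class RunSpec:
    session_index: int  # 1-based
    run_index_within_session: int  # 1-based
    blocks: list[BlockSpec]

    def __post_init__(self) -> None:
        # an empty run (no blocks) is permitted and yields an empty timeline
        if len(self.blocks) == 0:
            return
        if self.blocks[0].kind != "baseline":
            raise ProtocolError("block 1 of a run must be the baseline block")
        if any(b.kind != "regulation" for b in self.blocks[1:]):
            raise ProtocolError("blocks after the first must be regulation blocks")

    @property
    def n_trials(self) -> int:
        return sum(len(b.trials) for b in self.blocks)

    @property
    def n_regulation_trials(self) -> int:
        return sum(len(b.trials) for b in self.blocks if b.kind == "regulation")

    def trials(self) -> Iterator[tuple[int, BlockSpec, TrialSpec]]:
        """Yield (block_number 1-based, block, trial) in presentation order."""
        for bi, block in enumerate(self.blocks, start=1):
            for trial in block.trials:
                yield bi, block, trial


@dataclass
class SessionSpec:
    index: int  # 1-based
    runs: list[RunSpec]

    def __post_init__(self) -> None:
        if len(self.runs) == 0:
            raise ProtocolError("a session must contain at least one run")


@dataclass
class TrainingProtocol:
    """The full multi-session schedule plus reward-display economics."""

    sessions: list[SessionSpec]
    condition: str
    trial_timing: TrialTiming = field(default_factory=TrialTiming)
    points_clamp: tuple[float, float] = (0.0, 10.0)
    bonus_rate: float = 0.008  # dollars per point
    bonus_cap: float = 100.0  # dollars

    def __post_init__(self) -> None:
        condition_factor(self.condition)  # validates
        if len(self.sessions) == 0:
            raise ProtocolError("protocol must contain at least one session")
        lo, hi = self.points_clamp
        if not lo < hi:
            raise ProtocolError("points_clamp must be an interval (lo < hi)")
        if not self.bonus_rate > 0:
            raise ProtocolError("bonus_rate must be > 0")
        if not self.bonus_cap > 0:
            raise ProtocolError("bonus_cap must be > 0")

    @property
    def condition_factor(self) -> int:
        return condition_factor(self.condition)

    @property
    def n_runs(self) -> int:
        return sum(len(s.runs) for s in self.sessions)

    @property
    def n_trials(self) -> int:
        return sum(r.n_trials for r in self.runs())

    @property
    def n_regulation_trials(self) -> int:
        return sum(r.n_regulation_trials for r in self.runs())

    def runs(self) -> Iterator[RunSpec]:
        for s in self.sessions:
            yield from s.runs


def _build_run(session_index: int, run_index: int, blocks_per_run: int,
               trials_per_block: int, inter_block_interval: float) -> RunSpec:
    blocks = []
    for bi in range(blocks_per_run):
        kind = "baseline" if bi == 0 else "regulation"
        trials = [TrialSpec(index_in_block=ti + 1) for ti in range(trials_per_block)]
        blocks.append(BlockSpec(kind=kind, trials=trials,
                                inter_block_interval=inter_block_interval))
    return RunSpec(session_index=session_index,
                   run_index_within_session=run_index, blocks=blocks)


def build_protocol(
    condition: str,
    runs_per_session: Sequence[int] = CANONICAL_RUNS_PER_SESSION,
    blocks_per_run: int = 4,
    trials_per_block: int = 12,
    inter_block_interval: float = 7.5,
    timing: TrialTiming | None = None,
    points_clamp: tuple[float, float] = (0.0, 10.0),
    bonus_rate: float = 0.008,
    bonus_cap: float = 100.0,
) -> TrainingProtocol:
    """Construct the training schedule; defaults give the canonical protocol.

    The canonical call ``build_protocol("up")`` yields 7 sessions with
    (3, 6, 6, 6, 6, 6, 3) runs = 36 runs of 4 x 12 trials. Overrides
    (fewer sessions/runs/trials) are for testing and small simulations
    and are validated against the same structural invariants.
    """
    if len(runs_per_session) == 0:
        raise ProtocolError("runs_per_session must list at least one session")
    if any(n < 1 for n in runs_per_session):
        raise ProtocolError("every session needs at least one run")
    if blocks_per_run < 2:
        raise ProtocolError("a run needs a baseline block and at least one "
                            "regulation block (blocks_per_run >= 2)")
    if trials_per_block < 1:
        raise ProtocolError("trials_per_block must be >= 1")
    timing = timing or TrialTiming()
    sessions = [
        SessionSpec(
            index=si + 1,
            runs=[
                _build_run(si + 1, ri + 1, blocks_per_run, trials_per_block,
                           inter_block_interval)
                for ri in range(n_runs)
            ],
        )
        for si, n_runs in enumerate(runs_per_session)
    ]
    return TrainingProtocol(
        sessions=sessions,
        condition=condition,
        trial_timing=timing,
        points_clamp=points_clamp,
        bonus_rate=bonus_rate,
        bonus_cap=bonus_cap,
    )


def assign_stimuli(
    run: RunSpec,
    rng: np.random.Generator,
    face_set: Sequence[str] = FACE_OVERLAYS,
) -> RunSpec:
    """Return a copy of the run with a sampled stimulus on every trial."""
    blocks = []
    for block in run.blocks:
        trials = [
            replace(t, stimulus=generate_msit_trial(rng, t.trial_type, face_set))
            for t in block.trials
        ]
        blocks.append(replace(block, trials=trials))
    return replace(run, blocks=blocks)


# ---------------------------------------------------------------------------
# timeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialEvent:
    """One trial placed on the run's clock."""

    block_number: int  # 1-based
    block_kind: str
    trial_in_block: int  # 1-based
    trial_in_run: int  # 1-based
    onset: float  # seconds from run start (start of fixation)
    window_trs: tuple[int, ...]  # 0-based TR indices feeding the reward


def run_duration(run: RunSpec, timing: TrialTiming) -> float:
    """Total run length in seconds, including inter-block fixation gaps."""
    dur = 0.0
    for bi, block in enumerate(run.blocks):
        if bi > 0:
            dur += block.inter_block_interval
        dur += len(block.trials) * timing.trial_duration
    return dur


def run_n_scans(run: RunSpec, timing: TrialTiming) -> int:
    """Number of TRs needed to cover the run (and any lagged window)."""
    base = int(np.ceil(run_duration(run, timing) / timing.tr - 1e-9))
    events = trial_timeline(run, timing)
    if not events:
        return base
    last_needed = max(e.window_trs[-1] for e in events) + 1
    return max(base, last_needed)


def trial_timeline(run: RunSpec, timing: TrialTiming) -> list[TrialEvent]:
    """Lay every trial on the run clock and resolve its feedback TRs.

    The feedback window starts at the first TR boundary at/after stimulus
    onset (fixation end), shifted by ``hemodynamic_lag_trs``, and spans
    ``feedback_window_trs`` consecutive TRs.
    """
    events: list[TrialEvent] = []
    t = 0.0
    trial_counter = 0
    for bi, block in enumerate(run.blocks, start=1):
        if bi > 1:
            t += block.inter_block_interval
        for trial in block.trials:
            trial_counter += 1
            stim_onset = t + timing.fixation
            first_tr = int(np.ceil(stim_onset / timing.tr - 1e-9))
            first_tr += timing.hemodynamic_lag_trs
            window = tuple(first_tr + k for k in range(timing.feedback_window_trs))
            if (window[-1] + 1) * timing.tr - (t + timing.trial_duration) > \
                    timing.feedback + timing.tr * timing.feedback_window_trs + 1e-9:
                raise ProtocolError(
                    "TR grid cannot cover the feedback window for trial "
                    f"{trial_counter} (tr={timing.tr}, lag="
                    f"{timing.hemodynamic_lag_trs})")
            events.append(TrialEvent(
                block_number=bi,
                block_kind=block.kind,
                trial_in_block=trial.index_in_block,
                trial_in_run=trial_counter,
                onset=t,
                window_trs=window,
            ))
            t += timing.trial_duration
    return events
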