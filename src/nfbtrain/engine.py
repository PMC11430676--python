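"""Online reward computation for the ROI-contrast neurofeedback loop.

Each trial's feedback derives from two steps. First the ROI-contrast
BOLD difference over the trial's 2-TR data-collection window::

    BOLDdiff = mean over window TRs of (dACC_left + dACC_right - PAC_left - PAC_right)

(dACC = dorsal anterior cingulate cortex, the training target; PAC =
primary auditory cortex, a task-unrelated control region). Then the
trial's reward score, a z-score of the current trial's BOLDdiff against
the run's baseline block, signed by the regulation direction::

    score = c * (BOLDdiff_trial - mean(BOLDdiff_baseline)) / std(BOLDdiff_baseline)

with c = +1 for up-regulation and -1 for down-regulation. The displayed
value is the score clamped to [0, 10] and rounded (half-even) to two
decimals. Baseline-block trials display "* Points" and missed responses
display "No Response"; neither earns points. Earned points convert to a
monetary bonus at a fixed rate with a cap.

Display conventions (clamp before round; population SD for the baseline;
displayed values are what is summed for payout) are documented design
choices — see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .protocol import (
    RunSpec,
    TrainingProtocol,
    TrialTiming,
    trial_timeline,
)

__all__ = [
    "EngineError",
    "InsufficientBaselineError",
    "DegenerateBaselineError",
    "StreamTruncationError",
    "RoiSample",
    "TrialWindow",
    "BaselineStats",
    "RewardOutcome",
    "ROI_CHANNELS",
    "STREAM_COLUMNS",
    "DISPLAY_POINTS",
    "DISPLAY_BASELINE",
    "DISPLAY_NO_RESPONSE",
    "compute_bold_diff",
    "compute_baseline_stats",
    "compute_reward_points",
    "accumulate_run",
    "compute_bonus",
    "run_feedback_session",
    "window_diffs",
    "extract_roi_stream",
]


class EngineError(ValueError):
    """Invalid input to the reward engine."""


class InsufficientBaselineError(EngineError):
    """Fewer than two baseline trials: the dispersion is undefined."""


class DegenerateBaselineError(EngineError):
    """Baseline dispersion is zero: the reward score would be infinite."""


class StreamTruncationError(EngineError):
    """The ROI stream ends before the run's last feedback window."""


ROI_CHANNELS: tuple[str, ...] = ("dacc_l", "dacc_r", "pac_l", "pac_r")
STREAM_COLUMNS: tuple[str, ...] = ("time",) + ROI_CHANNELS + ("global",)
#: ROI-contrast weights over (dacc_l, dacc_r, pac_l, pac_r)
CONTRAST_WEIGHTS = np.array([1.0, 1.0, -1.0, -1.0])

DISPLAY_POINTS = "points"
DISPLAY_BASELINE = "baseline-asterisk"
DISPLAY_NO_RESPONSE = "no-response"


@dataclass(frozen=True)
class RoiSample:
    """The four ROI BOLD values (plus optional global signal) at one TR."""

    t: int
    dacc_l: float
    dacc_r: float
    pac_l: float
    pac_r: float
    global_signal: float | None = None

    def roi_values(self) -> np.ndarray:
        return np.array([self.dacc_l, self.dacc_r, self.pac_l, self.pac_r])


@dataclass
class TrialWindow:
    """The ROI samples feeding one trial's reward computation."""

    samples: list[RoiSample]
    trial_id: int
    block_kind: str
    responded: bool = True


@dataclass(frozen=True)
class BaselineStats:
    """Mean and dispersion of BOLDdiff over a run's baseline block."""

    mean_diff: float
    std_diff: float
    n: int


@dataclass(frozen=True)
class RewardOutcome:
    """One trial's scored feedback."""

    trial_id: int
    block_kind: str
    responded: bool
    raw_score: float
    displayed_points: float
    earned_points: float
    display: str


def compute_bold_diff(window: TrialWindow | Sequence[RoiSample],
                      expected_trs: int | None = None) -> float:
    """ROI-contrast difference averaged over the trial's window TRs.

    Per TR: dacc_l + dacc_r - pac_l - pac_r; then the mean across TRs.
    """
    samples = window.samples if isinstance(window, TrialWindow) else list(window)
    if expected_trs is not None and len(samples) != expected_trs:
        raise EngineError(
            f"window has {len(samples)} TRs, expected {expected_trs}")
    if len(samples) == 0:
        raise EngineError("window contains no TRs")
    vals = np.array([s.roi_values() for s in samples], dtype=float)
    for j, name in enumerate(ROI_CHANNELS):
        if not np.all(np.isfinite(vals[:, j])):
            raise EngineError(f"non-finite BOLD value in channel {name!r}")
    return float(np.mean(vals @ CONTRAST_WEIGHTS))


def compute_baseline_stats(diffs: Iterable[float], ddof: int = 0) -> BaselineStats:
    """Mean and standard deviation of BOLDdiff across baseline trials.

    The population convention (``ddof=0``) is the default; the sample
    convention is available via ``ddof=1``.
    """
    arr = np.asarray(list(diffs), dtype=float)
    if arr.size < 2:
        raise InsufficientBaselineError(
            f"need at least 2 baseline trials, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise EngineError("non-finite baseline BOLDdiff value")
    std = float(np.std(arr, ddof=ddof))
    if std == 0.0:
        raise DegenerateBaselineError(
            "baseline BOLDdiff has zero dispersion; reward scores undefined")
    return BaselineStats(mean_diff=float(np.mean(arr)), std_diff=std, n=arr.size)


def _display_points(raw: float, clamp: tuple[float, float]) -> float:
    lo, hi = clamp
    # clamp first so the displayed bounds are exact, then round half-even
    return float(np.round(min(max(raw, lo), hi), 2))


def compute_reward_points(
    diff_ct: float,
    bl: BaselineStats,
    c: int,
    window: TrialWindow,
    clamp: tuple[float, float] = (0.0, 10.0),
) -> RewardOutcome:
    """Score one trial's window against the run's baseline statistics.

    Baseline-block trials and missed responses earn nothing; their
    ``raw_score`` is still recorded for analysis.
    """
    if c not in (+1, -1):
        raise EngineError(f"condition factor must be +1 or -1, got {c}")
    if bl.std_diff <= 0:
        raise DegenerateBaselineError("baseline std must be positive")
    raw = c * (diff_ct - bl.mean_diff) / bl.std_diff
    displayed = _display_points(raw, clamp)
    if window.block_kind == "baseline":
        return RewardOutcome(window.trial_id, window.block_kind,
                             window.responded, raw, displayed,
                             earned_points=0.0, display=DISPLAY_BASELINE)
    if not window.responded:
        return RewardOutcome(window.trial_id, window.block_kind,
                             window.responded, raw, displayed,
                             earned_points=0.0, display=DISPLAY_NO_RESPONSE)
    return RewardOutcome(window.trial_id, window.block_kind, window.responded,
                         raw, displayed, earned_points=displayed,
                         display=DISPLAY_POINTS)


def accumulate_run(trial_outcomes: Iterable[RewardOutcome]) -> float:
    """Sum of earned points over the run's regulation trials.

    Baseline and no-response trials carry zero earned points, so the sum
    runs over earned points of regulation outcomes only.
    """
    return float(sum(o.earned_points for o in trial_outcomes
                     if o.block_kind == "regulation"))


def compute_bonus(total_points: float, protocol: TrainingProtocol) -> float:
    """Convert total earned points into the capped monetary bonus."""
    if total_points < 0:
        raise EngineError("total_points must be >= 0")
    return float(min(total_points * protocol.bonus_rate, protocol.bonus_cap))


# ---------------------------------------------------------------------------
# stream scoring
# ---------------------------------------------------------------------------


def _stream_matrix(roi_stream: pd.DataFrame | np.ndarray) -> np.ndarray:
    """ROI channels as an (n_scans, 4) array in canonical channel order."""
    if isinstance(roi_stream, pd.DataFrame):
        missing = [c for c in ROI_CHANNELS if c not in roi_stream.columns]
        if missing:
            raise EngineError(f"ROI stream is missing columns {missing}")
        return roi_stream.loc[:, list(ROI_CHANNELS)].to_numpy(dtype=float)
    arr = np.asarray(roi_stream, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 4:
        raise EngineError("ROI stream array must be (n_scans, >=4)")
    return arr[:, :4]


def window_diffs(roi_stream: pd.DataFrame | np.ndarray,
                 windows: Sequence[Sequence[int]]) -> np.ndarray:
    """Vectorised BOLDdiff for many trial windows of one stream."""
    mat = _stream_matrix(roi_stream)
    idx = np.asarray(windows, dtype=int)
    if idx.size and idx.max() >= mat.shape[0]:
        raise StreamTruncationError(
            f"stream has {mat.shape[0]} TRs but a trial window needs TR "
            f"{int(idx.max())}")
    contrast = mat @ CONTRAST_WEIGHTS
    return contrast[idx].mean(axis=1)


def run_feedback_session(
    roi_stream: pd.DataFrame | np.ndarray,
    run: RunSpec,
    timing: TrialTiming,
    c: int,
    responded: Sequence[bool] | None = None,
    clamp: tuple[float, float] = (0.0, 10.0),
) -> tuple[list[RewardOutcome], BaselineStats]:
    """Score a whole run from its ROI stream.

    Baseline statistics come from block 1 only and are then applied
    unchanged to every regulation trial. ``responded`` flags trials in
    presentation order (default: all responded). Deterministic: the same
    stream yields bit-identical outcomes.
    """
    events = trial_timeline(run, timing)
    if responded is None:
        responded_arr = [True] * len(events)
    else:
        responded_arr = list(responded)
        if len(responded_arr) != len(events):
            raise EngineError(
                f"responded has {len(responded_arr)} entries for "
                f"{len(events)} trials")
    diffs = window_diffs(roi_stream, [e.window_trs for e in events])
    baseline_diffs = [d for d, e in zip(diffs, events)
                      if e.block_kind == "baseline"]
    bl = compute_baseline_stats(baseline_diffs)
    outcomes = []
    for d, e, resp in zip(diffs, events, responded_arr):
        window = TrialWindow(samples=[], trial_id=e.trial_in_run,
                             block_kind=e.block_kind, responded=bool(resp))
        outcomes.append(compute_reward_points(float(d), bl, c, window, clamp))
    return outcomes, bl


# ---------------------------------------------------------------------------
# NIfTI adapter
# ---------------------------------------------------------------------------


def extract_roi_stream(bold_img, dacc_l_mask, dacc_r_mask, pac_l_mask,
                       pac_r_mask, global_mask=None, tr: float = 1.5) -> pd.DataFrame:
    """Average a 4D BOLD series within ROI masks into a stream table.

    Accepts nibabel images or paths. Each mask is binarised (> 0); the
    per-TR channel value is the mean over in-mask voxels. The global
    channel defaults to the mean over all nonzero-variance voxels.
    """
    import nibabel as nib

    def _load(img):
        return nib.load(img) if isinstance(img, (str, bytes)) or hasattr(img, "__fspath__") else img

    bold = _load(bold_img)
    data = np.asarray(bold.dataobj, dtype=float)
    if data.ndim != 4:
        raise EngineError("BOLD image must be 4D")
    flat = data.reshape(-1, data.shape[3])

    def _mask_mean(mask_img):
        mask = np.asarray(_load(mask_img).dataobj) > 0
        if mask.shape != data.shape[:3]:
            raise EngineError("mask shape does not match BOLD volume")
        if not mask.any():
            raise EngineError("mask is empty")
        return flat[mask.reshape(-1)].mean(axis=0)

    channels = {
        "dacc_l": _mask_mean(dacc_l_mask),
        "dacc_r": _mask_mean(dacc_r_mask),
        "pac_l": _mask_mean(pac_l_mask),
        "pac_r": _mask_mean(pac_r_mask),
    }
    if global_mask is not None:
        channels["global"] = _mask_mean(global_mask)
    else:
        channels["global"] = flat.mean(axis=0)
    out = pd.DataFrame(channels)
    out.insert(0, "time", np.arange(data.shape[3]) * tr)
    return out
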