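"""Markdown report with per-group session trajectories and model tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .analysis import FitResult

__all__ = ["trajectory_figure", "render_report"]

OUTCOME_LABELS = {
    "reward_points": "Reward points (0-360 per run)",
    "dacc_ratio": "dACC / global BOLD ratio",
    "rt_mean": "Reaction time (s, correct trials)",
    "accuracy": "Response accuracy (0-36 per run)",
    "motivation": "Motivation to continue (0-100)",
}


def trajectory_figure(run_summaries: pd.DataFrame, path: str | Path,
                      outcomes: tuple[str, ...] = ("reward_points", "dacc_ratio",
                                                   "rt_mean", "accuracy")) -> Path:
    """Session-mean trajectories per group, one panel per outcome."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outcomes = tuple(o for o in outcomes if o in run_summaries.columns)
    fig, axes = plt.subplots(1, len(outcomes), figsize=(4 * len(outcomes), 3.2))
    if len(outcomes) == 1:
        axes = [axes]
    has_group = "group" in run_summaries.columns
    for ax, outcome in zip(axes, outcomes):
        if has_group:
            for g, d in run_summaries.groupby("group"):
                m = d.groupby("session")[outcome].mean()
                ax.plot(m.index, m.values, marker="o", label=g)
        else:
            m = run_summaries.groupby("session")[outcome].mean()
            ax.plot(m.index, m.values, marker="o")
        ax.set_xlabel("session")
        ax.set_title(OUTCOME_LABELS.get(outcome, outcome), fontsize=9)
    if has_group:
        axes[0].legend(fontsize=7)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def _fit_section(title: str, fit: FitResult) -> str:
    lines = [f"### {title}", ""]
    lines.append(f"- method: {fit.method}; converged: {fit.converged}; "
                 f"n_obs: {fit.n_obs}; participants: {fit.n_participants}")
    lines.append("")
    lines.append(fit.fixed.round(4).to_markdown(index=False))
    lines.append("")
    return "\n".join(lines)


def render_report(run_summaries: pd.DataFrame, fits: dict[str, FitResult],
                  out_dir: str | Path, figure: bool = True) -> Path:
    """Write report.md (and the trajectory figure) for one analysis."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    parts = ["# Neurofeedback training analysis", ""]
    parts.append(f"Runs analysed: {len(run_summaries)} across "
                 f"{run_summaries['participant'].nunique()} participants.")
    parts.append("")
    if figure:
        figpath = trajectory_figure(run_summaries, out_dir / "trajectories.png")
        parts.append(f"![session trajectories]({figpath.name})")
        parts.append("")
    for name, fit in fits.items():
        parts.append(_fit_section(OUTCOME_LABELS.get(name, name), fit))
    path = out_dir / "report.md"
    path.write_text("\n".join(parts))
    return path
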