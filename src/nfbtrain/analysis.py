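"""Nested training-effect models over sessions and runs.

Outcomes per run: summed reward points (0-360), the dACC/global BOLD
ratio over the feedback windows, mean correct-trial reaction time, and
correct-trial count (0-36), plus the post-run motivation report (0-100).
Runs are nested in sessions nested in participants, so every model is a
two-level regression with a participant random intercept, fixed effects
for session (grand-mean centered), run (centered within session) and
their interaction, and — in the moderation models — group main effects
and group x session / group x run interactions with the experimental
group as reference.

Each mixed fit is accompanied by an independent fallback estimator:
ordinary least squares within each participant, then a one-sample t-test
on the per-participant coefficients. On balanced designs the two routes
agree on the fixed effects, which the test-suite exploits as an oracle;
when the mixed fit fails to converge the fallback is what is reported.

p-values are normal-approximation Wald tests on the fixed-effect z, the
reporting shape used for multilevel models in this literature. The
trial-level accuracy model uses a logistic link with exchangeable
within-participant correlation (GEE); see docs/methods.md for why.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "AnalysisError",
    "FitResult",
    "summarize_runs",
    "center_design",
    "per_participant_slopes",
    "fit_training_model",
    "moderation_analysis",
    "brain_behavior_model",
    "motivation_model",
    "OUTCOMES",
    "REFERENCE_GROUP",
]


class AnalysisError(ValueError):
    """Invalid input to an analysis operation."""


OUTCOMES = ("reward_points", "dacc_ratio", "rt_mean", "accuracy")
REFERENCE_GROUP = "experimental"

#: canonical fixed-effect terms of the within-group model
BASE_TERMS = ("Intercept", "session_c", "run_c", "session_c:run_c")


@dataclass
class FitResult:
    """Fixed effects (and uncertainty) from one nested model.

    ``fixed`` has columns term/estimate/se/z/p; ``fallback`` holds the
    per-participant-OLS companion estimates (columns term/estimate/se/
    t/p) where applicable. ``converged`` is False when the primary
    estimator failed and ``fixed`` carries the fallback numbers.
    """

    outcome: str
    method: str
    fixed: pd.DataFrame
    converged: bool
    n_obs: int
    n_participants: int
    random_intercept_var: float | None = None
    fallback: pd.DataFrame | None = None
    warnings_: list[str] = field(default_factory=list)

    def estimate(self, term: str) -> float:
        row = self.fixed.loc[self.fixed["term"] == term]
        if row.empty:
            raise KeyError(f"no term {term!r} in fit for {self.outcome!r}")
        return float(row["estimate"].iloc[0])

    def pvalue(self, term: str) -> float:
        row = self.fixed.loc[self.fixed["term"] == term]
        if row.empty:
            raise KeyError(f"no term {term!r} in fit for {self.outcome!r}")
        return float(row["p"].iloc[0])


# ---------------------------------------------------------------------------
# run summaries
# ---------------------------------------------------------------------------


def summarize_runs(trial_records: pd.DataFrame) -> pd.DataFrame:
    """Collapse trial records to one row per (participant, session, run).

    Reward points and accuracy run over regulation trials only; reaction
    time averages over correct regulation trials (missing if none); the
    dACC ratio is the per-trial feedback-window dACC/global ratio
    averaged over the run's regulation trials — the same TRs that
    generated the points.
    """
    required = {"participant", "session", "run", "block_kind", "correct",
                "earned_points"}
    missing = required - set(trial_records.columns)
    if missing:
        raise AnalysisError(f"trial records are missing columns {sorted(missing)}")
    df = trial_records.copy()
    reg = df[df["block_kind"] == "regulation"]
    if reg.empty:
        raise AnalysisError("no regulation trials in the input")
    keys = ["participant", "session", "run"]
    counts = reg.groupby(keys).size()
    if (set(map(tuple, df[keys].drop_duplicates().itertuples(index=False)))
            - set(counts.index)):
        raise AnalysisError("a run has no regulation trials")

    g = reg.groupby(keys)
    out = pd.DataFrame({
        "reward_points": g["earned_points"].sum(),
        "accuracy": g["correct"].sum(),
    })
    if "rt" in reg.columns:
        corr = reg[reg["correct"].astype(bool)]
        out["rt_mean"] = corr.groupby(keys)["rt"].mean()
    if {"window_dacc", "window_global"}.issubset(reg.columns):
        ratio = reg["window_dacc"] / reg["window_global"]
        out["dacc_ratio"] = ratio.groupby([reg[k] for k in keys]).mean()
    if "motivation" in reg.columns:
        out["motivation"] = g["motivation"].first()
    if "group" in reg.columns:
        out.insert(0, "group", g["group"].first())
    out = out.reset_index()
    out["accuracy"] = out["accuracy"].astype(int)
    return out.sort_values(keys, ignore_index=True)


def center_design(summaries: pd.DataFrame, warn_single_session: bool = True) -> pd.DataFrame:
    """Attach session_c (grand-mean), run_c (within-session) and interaction.

    Centering is computed over the rows provided, so on a balanced
    design the centered columns have exactly zero mean (run_c within
    every session; session_c overall).
    """
    for col in ("session", "run"):
        if col not in summaries.columns:
            raise AnalysisError(f"summaries are missing column {col!r}")
    out = summaries.copy()
    if out["session"].nunique() < 2 and warn_single_session:
        warnings.warn("only one session present: session effects are "
                      "unidentified (degenerate design)", UserWarning,
                      stacklevel=2)
    out["session_c"] = out["session"] - out["session"].mean()
    out["run_c"] = out["run"] - out.groupby("session")["run"].transform("mean")
    out["session_c:run_c"] = out["session_c"] * out["run_c"]
    return out


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def per_participant_slopes(data: pd.DataFrame, outcome: str,
                           terms: tuple[str, ...] = BASE_TERMS) -> pd.DataFrame:
    """Independent fallback: OLS within each participant, t-test on slopes.

    Implemented directly from the normal equations so it shares no code
    path with the mixed-model estimator it cross-checks.
    """
    rows = []
    coefs = []
    for pid, d in data.groupby("participant"):
        X = np.column_stack([
            np.ones(len(d)) if t == "Intercept" else d[t].to_numpy()
            for t in terms
        ])
        y = d[outcome].to_numpy(dtype=float)
        keep = np.isfinite(y)
        if keep.sum() < X.shape[1]:
            continue
        beta, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        coefs.append(beta)
    if not coefs:
        raise AnalysisError(f"no participant has enough data for {outcome!r}")
    C = np.array(coefs)
    n = C.shape[0]
    mean = C.mean(axis=0)
    se = C.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full(C.shape[1], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / se
    p = 2 * stats.t.sf(np.abs(t), df=max(n - 1, 1))
    for j, term in enumerate(terms):
        rows.append({"term": term, "estimate": mean[j], "se": se[j],
                     "t": t[j], "p": p[j], "n_participants": n})
    return pd.DataFrame(rows)


def _wald_table(params: pd.Series, bse: pd.Series) -> pd.DataFrame:
    z = params / bse
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({
        "term": params.index,
        "estimate": params.to_numpy(),
        "se": bse.to_numpy(),
        "z": z.to_numpy(),
        "p": p,
    }).reset_index(drop=True)


def _fit_mixedlm(formula: str, data: pd.DataFrame, outcome: str,
                 method_label: str,
                 fallback: pd.DataFrame | None) -> FitResult:
    notes: list[str] = []
    n_part = data["participant"].nunique()
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            model = smf.mixedlm(formula, data=data, groups=data["participant"])
            res = model.fit(reml=False)
        notes.extend(str(w.message) for w in wlist)
        converged = bool(getattr(res, "converged", True))
        fixed = _wald_table(res.fe_params, res.bse_fe)
        re_var = float(np.asarray(res.cov_re).ravel()[0])
        return FitResult(outcome=outcome, method=method_label, fixed=fixed,
                         converged=converged, n_obs=int(res.nobs),
                         n_participants=n_part, random_intercept_var=re_var,
                         fallback=fallback, warnings_=notes)
    except Exception as err:  # singular/non-convergent fits fall back
        notes.append(f"mixed model failed ({err}); reporting per-participant "
                     "OLS fallback")
        if fallback is None:
            raise AnalysisError(
                f"mixed model failed for {outcome!r} and no fallback is "
                f"available: {err}") from err
        fixed = fallback.rename(columns={"t": "z"}).drop(
            columns=["n_participants"])
        return FitResult(outcome=outcome, method=method_label + "+fallback",
                         fixed=fixed, converged=False, n_obs=len(data),
                         n_participants=n_part, random_intercept_var=None,
                         fallback=fallback, warnings_=notes)


def fit_training_model(summaries: pd.DataFrame, outcome: str) -> FitResult:
    """Two-level training-effect model for one outcome within one group.

    outcome ~ session_c * run_c with a participant random intercept,
    fitted by maximum likelihood; the per-participant-OLS fallback is
    always computed and attached.
    """
    if outcome not in summaries.columns:
        raise AnalysisError(f"outcome column {outcome!r} not present")
    if summaries["participant"].nunique() < 2:
        raise AnalysisError("need at least 2 participants")
    data = center_design(summaries)
    data = data[np.isfinite(data[outcome].astype(float))].copy()
    fallback = per_participant_slopes(data, outcome)
    return _fit_mixedlm(f"{outcome} ~ session_c * run_c", data, outcome,
                        "MixedLM(ML), random intercept", fallback)


def moderation_analysis(summaries: pd.DataFrame, outcome: str,
                        reference: str = REFERENCE_GROUP) -> FitResult:
    """Group moderation of the session/run effects.

    With the reference (experimental) group coding, session/run main
    effects are that group's effects; each interaction term is another
    group's departure from them.
    """
    if "group" not in summaries.columns:
        raise AnalysisError("summaries need a 'group' column for moderation")
    groups = set(summaries["group"].unique())
    if reference not in groups:
        raise AnalysisError(f"reference group {reference!r} absent from data")
    if len(groups) < 2:
        raise AnalysisError("moderation requires at least two groups")
    data = center_design(summaries)
    data = data[np.isfinite(data[outcome].astype(float))].copy()
    formula = (f"{outcome} ~ (session_c + run_c + session_c:run_c) * "
               f"C(group, Treatment('{reference}'))")
    return _fit_mixedlm(formula, data, outcome, "MixedLM(ML), moderation",
                        fallback=None)


def brain_behavior_model(trial_records: pd.DataFrame) -> dict[str, FitResult]:
    """Trial-level links from points and window dACC signal to behavior.

    Two models over regulation trials: reaction time (correct trials,
    linear two-level model) and correctness (logistic link, exchangeable
    within-participant correlation via GEE). The dACC predictor is the
    trial's feedback-window dACC/global ratio.
    """
    need = {"participant", "block_kind", "rt", "correct",
            "displayed_points", "window_dacc", "window_global"}
    missing = need - set(trial_records.columns)
    if missing:
        raise AnalysisError(f"trial records are missing columns {sorted(missing)}")
    reg = trial_records[trial_records["block_kind"] == "regulation"].copy()
    reg["dacc_sig"] = reg["window_dacc"] / reg["window_global"]
    out: dict[str, FitResult] = {}

    rt_data = reg[reg["correct"].astype(bool) & np.isfinite(reg["rt"])].copy()
    fallback = per_participant_slopes(
        rt_data, "rt", terms=("Intercept", "displayed_points", "dacc_sig"))
    out["rt"] = _fit_mixedlm("rt ~ displayed_points + dacc_sig", rt_data,
                             "rt", "MixedLM(ML), trial-level", fallback)

    acc_data = reg[reg["responded"].astype(bool)].copy() \
        if "responded" in reg.columns else reg
    acc_data["correct"] = acc_data["correct"].astype(int)
    notes: list[str] = []
    if acc_data["correct"].nunique() < 2:
        # complete separation at the dataset level: nothing to estimate
        fixed = pd.DataFrame({
            "term": ["Intercept", "displayed_points", "dacc_sig"],
            "estimate": np.nan, "se": np.nan, "z": np.nan, "p": np.nan})
        out["accuracy"] = FitResult(
            outcome="correct", method="GEE logit (degenerate)", fixed=fixed,
            converged=False, n_obs=len(acc_data),
            n_participants=acc_data["participant"].nunique(),
            warnings_=["all trials share one outcome; accuracy model flagged"])
        return out
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        gee = smf.gee("correct ~ displayed_points + dacc_sig",
                      groups=acc_data["participant"], data=acc_data,
                      family=sm.families.Binomial(),
                      cov_struct=sm.cov_struct.Exchangeable())
        res = gee.fit()
    notes.extend(str(w.message) for w in wlist)
    out["accuracy"] = FitResult(
        outcome="correct", method="GEE logit, exchangeable",
        fixed=_wald_table(res.params, res.bse), converged=True,
        n_obs=int(res.nobs), n_participants=acc_data["participant"].nunique(),
        warnings_=notes)
    return out


def motivation_model(summaries: pd.DataFrame,
                     reference: str = REFERENCE_GROUP) -> FitResult:
    """Session/run model of the post-run motivation reports.

    With multiple groups present this is the moderation model (reference
    = experimental); with a single group, the within-group model.
    """
    if "motivation" not in summaries.columns:
        raise AnalysisError("summaries need a 'motivation' column")
    vals = summaries["motivation"].astype(float)
    if not ((vals >= 0) & (vals <= 100)).all():
        raise AnalysisError("motivation must lie in [0, 100]")
    by_part = summaries.groupby("participant")["motivation"].nunique()
    if (by_part <= 1).all():
        raise AnalysisError("motivation is constant within every participant; "
                            "fit is degenerate")
    if "group" in summaries.columns and summaries["group"].nunique() > 1:
        return moderation_analysis(summaries, "motivation", reference)
    return fit_training_model(summaries, "motivation")
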