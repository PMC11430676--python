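"""File formats, configuration, and run manifests.

All tables are plain tab-separated text with fixed headers and fixed
float formatting, so byte-identical reruns produce byte-identical files
(no timestamps ever enter a data artifact). Sessions, runs, blocks and
trials are 1-based throughout; TR indices are 0-based on the scan grid.

Formats
-------
ROI stream   : time, dacc_l, dacc_r, pac_l, pac_r, global (one row per TR)
events       : onset, duration, trial_type, block_kind, session, run,
               stimulus, face_overlay  (BIDS-style events table)
trial table  : one row per trial with behavior + scoring (see TRIAL_COLUMNS)
run summary  : one row per run with the four outcomes + motivation
coefficients : term, estimate, se, z, p (one model per file)
config       : YAML mapping; unknown keys are rejected
manifest     : JSON with config hash, seed, version and file checksums
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .protocol import (
    CANONICAL_RUNS_PER_SESSION,
    RunSpec,
    TrainingProtocol,
    TrialTiming,
    build_protocol,
    trial_timeline,
)

__all__ = [
    "ConfigError",
    "FLOAT_FMT",
    "read_roi_stream",
    "write_roi_stream",
    "write_table",
    "read_table",
    "events_table",
    "load_config",
    "protocol_from_config",
    "config_hash",
    "write_manifest",
]


class ConfigError(ValueError):
    """Invalid configuration file."""


FLOAT_FMT = "%.6f"

STREAM_COLUMNS = ["time", "dacc_l", "dacc_r", "pac_l", "pac_r", "global"]


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a TSV with stable float formatting (lossless at 1e-6)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_roi_stream(stream: pd.DataFrame, path: str | Path) -> Path:
    missing = [c for c in STREAM_COLUMNS if c not in stream.columns]
    if missing:
        raise ConfigError(f"ROI stream is missing columns {missing}")
    return write_table(stream[STREAM_COLUMNS], path)


def read_roi_stream(path: str | Path) -> pd.DataFrame:
    """Read a delimited ROI stream (TSV or CSV), validating the header."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(
            f"{path.name}: ROI stream is missing columns {missing}")
    bad = df[STREAM_COLUMNS].apply(
        lambda col: ~np.isfinite(pd.to_numeric(col, errors="coerce")))
    if bad.any().any():
        line = int(np.argwhere(bad.to_numpy())[0][0]) + 2  # 1 header line
        raise ConfigError(f"{path.name}: malformed or non-finite value at "
                          f"line {line}")
    return df


def events_table(run: RunSpec, timing: TrialTiming) -> pd.DataFrame:
    """BIDS-style events for one run (stimulus presentation events)."""
    rows = []
    for e in trial_timeline(run, timing):
        block = run.blocks[e.block_number - 1]
        trial = block.trials[e.trial_in_block - 1]
        stim = trial.stimulus
        rows.append({
            "onset": e.onset + timing.fixation,
            "duration": timing.stimulus,
            "trial_type": trial.trial_type,
            "block_kind": e.block_kind,
            "session": run.session_index,
            "run": run.run_index_within_session,
            "stimulus": stim.as_string() if stim else "n/a",
            "face_overlay": stim.face_overlay if stim else "n/a",
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: default config: every printed protocol constant, as overridable keys
DEFAULT_CONFIG: dict = {
    "condition": "up",
    "runs_per_session": list(CANONICAL_RUNS_PER_SESSION),
    "blocks_per_run": 4,
    "trials_per_block": 12,
    "inter_block_interval": 7.5,
    "timing": {
        "fixation": 1.5,
        "stimulus": 1.0,
        "blank": 3.5,
        "feedback": 1.5,
        "tr": 1.5,
        "feedback_window_trs": 2,
        "hemodynamic_lag_trs": 0,
    },
    "points_clamp": [0.0, 10.0],
    "bonus_rate": 0.008,
    "bonus_cap": 100.0,
}


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config merged over the defaults; unknown keys error."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError("config root must be a mapping")
    for key, val in user.items():
        if key not in cfg:
            raise ConfigError(f"unknown config key: {key}")
        if key == "timing":
            if not isinstance(val, dict):
                raise ConfigError("config key 'timing' must be a mapping")
            for tk, tv in val.items():
                if tk not in cfg["timing"]:
                    raise ConfigError(f"unknown config key: timing.{tk}")
                cfg["timing"][tk] = tv
        else:
            cfg[key] = val
    return cfg


def protocol_from_config(cfg: dict) -> TrainingProtocol:
    timing = TrialTiming(**cfg["timing"])
    return build_protocol(
        cfg["condition"],
        runs_per_session=tuple(cfg["runs_per_session"]),
        blocks_per_run=cfg["blocks_per_run"],
        trials_per_block=cfg["trials_per_block"],
        inter_block_interval=cfg["inter_block_interval"],
        timing=timing,
        points_clamp=tuple(cfg["points_clamp"]),
        bonus_rate=cfg["bonus_rate"],
        bonus_cap=cfg["bonus_cap"],
    )


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, cfg: dict, seed: int,
                   files: list[str | Path]) -> Path:
    """Write the reproducibility manifest for a directory of outputs.

    The manifest pins config (by value and hash), seed, package version
    and a checksum per file; identical manifests imply byte-identical
    deterministic outputs.
    """
    out_dir = Path(out_dir)
    manifest = {
        "tool": "nfbtrain",
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "config_hash": config_hash(cfg),
        "files": {
            str(Path(f).relative_to(out_dir)): _sha256(Path(f))
            for f in sorted(map(str, files))
        },
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
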