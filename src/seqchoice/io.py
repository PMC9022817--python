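"""Readers/writers for the trial-log CSV schema and run configs.

The trial log is a plain UTF-8, comma-separated file with a mandatory
header and one row per trial; ``choice`` is one of SN, LF, TIMEOUT.
Configs are flat YAML/JSON mappings; every emitted report embeds the seed
and a hash of the resolved config.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "TRIAL_LOG_COLUMNS",
    "read_trial_log",
    "write_trial_log",
    "load_config",
    "save_config",
    "config_hash",
]

TRIAL_LOG_COLUMNS = [
    "run_id",
    "sequence_id",
    "trial_index",
    "v_s",
    "v_l",
    "d_n",
    "d_f",
    "iti_seconds",
    "choice",
    "rt_cycles",
    "category",
    "first_choice",
]

_CHOICE_CODES = {"SN", "LF", "TIMEOUT"}


def write_trial_log(trials: pd.DataFrame, path) -> None:
    """Write a trial log; columns are emitted in the canonical order."""
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial log missing columns: {missing}")
    trials[TRIAL_LOG_COLUMNS].to_csv(path, index=False)


def read_trial_log(path) -> pd.DataFrame:
    """Read and validate a trial log.

    Raises on an empty file, a header that does not match the schema, or a
    choice code outside {SN, LF, TIMEOUT} (reported with its row number).
    Reading back a written log reproduces it row for row.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty trial log: {path}")
    df = pd.read_csv(path, dtype={"category": str, "choice": str, "first_choice": str})
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log {path} missing columns: {missing}")
    df["category"] = df["category"].fillna("")
    bad = ~df["choice"].isin(_CHOICE_CODES)
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(
            f"trial log {path}: invalid choice code {df.loc[row, 'choice']!r} "
            f"at data row {row}"
        )
    if len(df) == 0:
        raise ValueError(f"trial log {path} contains a header but no rows")
    return df[TRIAL_LOG_COLUMNS]


def load_config(path) -> dict:
    """Load a YAML or JSON config mapping (by file extension)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg, indent=2, sort_keys=True), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=True), encoding="utf-8")


def config_hash(cfg: dict) -> str:
    """Stable short hash of a resolved config, for report provenance."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
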