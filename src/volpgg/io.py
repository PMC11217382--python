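"""Readers/writers for the canonical tidy table, configs, and results documents.

Tabular files are comma-separated UTF-8 text with a header row; configs
are YAML mappings that round-trip exactly; results documents are JSON
trees.  A column-mapping layer adapts externally deposited tables (whose
schema is not standardized) to the canonical schema.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .cohort import RECORD_COLUMNS

__all__ = [
    "read_records",
    "write_records",
    "apply_column_mapping",
    "load_config",
    "save_config",
    "write_results",
    "config_hash",
]

_DTYPES = {
    "participant_id": str,
    "session_id": str,
    "regime": str,
    "threshold": int,
    "est_C": int,
    "est_D": int,
    "est_L": int,
    "confidence": int,
    "action": str,
    "condition_order": int,
}


def read_records(path: str | Path, mapping: Mapping[str, Any] | None = None) -> pd.DataFrame:
    """Read a tidy participant-level table, optionally through a column mapping."""
    df = pd.read_csv(path)
    if mapping is not None:
        df = apply_column_mapping(df, mapping)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[RECORD_COLUMNS]
    for col, dtype in _DTYPES.items():
        df[col] = df[col].astype(dtype)
    df["rho"] = pd.to_numeric(df["rho"], errors="coerce")
    return df


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, index=False)


def apply_column_mapping(df: pd.DataFrame, mapping: Mapping[str, Any]) -> pd.DataFrame:
    """Translate an external table to the canonical schema.

    ``mapping`` supports three keys: ``columns`` (external name ->
    canonical name), ``values`` (canonical column -> {external value ->
    canonical value}) and ``defaults`` (canonical column -> constant for
    columns absent from the source, e.g. ``rho``).
    """
    out = df.rename(columns=dict(mapping.get("columns", {})))
    for col, values in mapping.get("values", {}).items():
        if col in out.columns:
            out[col] = out[col].map(lambda v, m=values: m.get(v, v))
    for col, value in mapping.get("defaults", {}).items():
        if col not in out.columns:
            out[col] = value
    return out


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(config: Mapping[str, Any], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)


def config_hash(config: Mapping[str, Any]) -> str:
    """Stable short hash of a config for output metadata."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_results(results: Mapping[str, Any], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
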