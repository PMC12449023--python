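"""Delimited-table I/O with schema validation and provenance headers.

All artifacts are comma-separated text with a header row; files written
here carry ``#``-prefixed metadata lines (seed, config hash, package
version) so every output embeds what produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional, Tuple

import pandas as pd

__all__ = ["SCHEMAS", "config_hash", "write_table", "read_table"]

#: Required columns per payload kind.
SCHEMAS = {
    "schedule": ["trial", "option_a", "option_b", "gen_mean", "gen_sd",
                 "block_id", "is_switch"],
    "trace": ["trial", "outcome", "p", "pe_signed", "pe_abs", "eta", "model_id"],
    "choices": ["trial", "m_a", "m_b", "choice", "outcome"],
    "fit": ["subject", "model_id", "objective", "n_params", "aic",
            "n_starts", "converged_frac", "method"],
    "report": [],
    "pupil_samples": ["time_ms", "pupil", "is_gap"],
    "pupil_events": ["trial", "onset_ms"],
}


def config_hash(config: dict) -> str:
    """Stable short hash of a flat configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, kind: str = "report",
                meta: Optional[Dict] = None) -> None:
    """Write a table with ``# key: value`` provenance header lines."""
    if kind not in SCHEMAS:
        raise ValueError(f"unknown payload kind {kind!r}")
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"payload {kind!r} missing columns: {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path, kind: str = "report") -> Tuple[pd.DataFrame, Dict[str, str]]:
    """Read a table written by :func:`write_table`; validates the schema.

    Returns the frame and the parsed metadata.  Missing required columns
    raise a :class:`ValueError` naming them; malformed rows raise with
    the offending row number (via the CSV parser).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SCHEMAS.get(kind, []) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: payload {kind!r} missing columns: {missing}")
    return df, meta
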