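"""Deterministic artifact serialization with provenance stamping.

Every table/JSON artifact written by the pipeline declares the hash of the
resolved configuration that produced it, so a run directory is self-
describing and re-runs are byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import os

import pandas as pd

__all__ = ["config_hash", "write_table", "write_json", "read_table", "read_json"]


def config_hash(config: dict) -> str:
    """SHA-256 of the canonical JSON form of a resolved configuration."""
    canonical = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_table(df: pd.DataFrame, path: str | os.PathLike, cfg_hash: str,
                float_format: str = "%.6f") -> None:
    """CSV with a leading ``# config_hash=`` comment line; 6-decimal floats."""
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False, float_format=float_format)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(obj: dict, path: str | os.PathLike, cfg_hash: str) -> None:
    payload = {"_config_hash": cfg_hash, **obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_json(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)
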