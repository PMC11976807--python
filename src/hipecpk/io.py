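"""Tabular interchange: frozen CSV schemas with provenance headers.

Every CSV written by the pipeline starts with ``#``-prefixed comment lines
recording the package version, the seed, and a hash of the configuration
that produced it, so outputs are self-describing and reruns are checkable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = ["write_table", "read_table", "config_hash", "OBSERVATION_COLUMNS", "CALIBRATION_COLUMNS"]

OBSERVATION_COLUMNS = [
    "animal_id",
    "tissue",
    "organ",
    "catheter_id",
    "t_start_min",
    "t_end_min",
    "c_dialysate_ug_ml",
    "censored",
]
CALIBRATION_COLUMNS = [
    "animal_id",
    "catheter_id",
    "tissue",
    "sample_label",
    "c_perfusate_ug_ml",
    "c_dialysate_ug_ml",
]


def config_hash(config) -> str:
    """Short stable hash of any JSON-serializable (or repr-able) config."""
    try:
        text = json.dumps(config, sort_keys=True, default=repr)
    except TypeError:
        text = repr(config)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, *, seed=None, config=None, extra: dict | None = None) -> Path:
    """Write a CSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# hipecpk {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV, ignoring the provenance header."""
    return pd.read_csv(path, comment="#")
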