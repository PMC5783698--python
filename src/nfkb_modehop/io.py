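"""Delimited-text readers/writers for trajectories, trace tables and configs.

All artifacts are plain TSV/CSV with '#'-prefixed metadata comment lines, so
every file carries enough provenance (engine, dt or seed, volume, parameter
hash) to re-run the stage that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .deterministic import Trajectory
from .errors import InvalidInputError, SchemaError
from .model import STATE_NAMES, TNFSignal

__all__ = ["read_trace_table", "write_trajectory", "read_trajectory",
           "write_table", "load_config"]


def _sniff_sep(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") else ","


def read_trace_table(path: str | Path):
    """Read a delimited trace table: a 'time' column plus per-cell columns.

    Comma or tab separated (sniffed from the header), '#' lines ignored.
    Returns (times, frame-of-value-columns).  Raises SchemaError if no time
    column exists; ragged rows surface as a parse error with line context.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    with open(path) as fh:
        header = ""
        for line in fh:
            if line.strip() and not line.lstrip().startswith("#"):
                header = line
                break
    if not header:
        raise SchemaError(f"{path}: empty table")
    sep = _sniff_sep(header)
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: ragged or malformed rows ({exc})") from exc
    time_cols = [c for c in df.columns if c.strip().lower() == "time"]
    if not time_cols:
        raise SchemaError(f"{path}: missing required 'time' column "
                          f"(found: {list(df.columns)})")
    times = df[time_cols[0]].to_numpy(dtype=float)
    values = df.drop(columns=time_cols)
    return times, values


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None,
                sep: str = "\t") -> None:
    """Write a DataFrame as TSV with '#' metadata lines on top."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {json.dumps(v) if not isinstance(v, str) else v}\n")
        df.to_csv(fh, sep=sep, index=False)


def write_trajectory(traj: Trajectory, path: str | Path, sep: str = "\t") -> None:
    """Trajectory as delimited text: time, Nn, Im, I, IKKa, IKKi, TNF."""
    conc = traj.concentrations()
    df = pd.DataFrame({"time": traj.times})
    for k, name in enumerate(STATE_NAMES):
        df[name] = conc[:, k]
    df["TNF"] = traj.tnf()
    meta = {k: v for k, v in traj.meta.items() if k != "params"}
    meta["params"] = json.dumps(traj.meta.get("params", {}))
    meta["is_counts"] = traj.is_counts
    meta["conversion_factor"] = traj.f
    write_table(df, path, meta, sep)


def read_trajectory(path: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    """Round-trip reader for trajectory files (concentration view)."""
    times, values = read_trace_table(path)
    missing = [n for n in STATE_NAMES if n not in values.columns]
    if missing:
        raise SchemaError(f"{path}: missing state columns {missing}")
    return times, values


def load_config(path: str | Path) -> dict:
    """Flat YAML/JSON config file (JSON is a YAML subset)."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg


def signal_from_config(block: dict) -> TNFSignal:
    """Build a TNFSignal from a config block with defaulted keys."""
    return TNFSignal(
        period=float(block.get("period", 90.0)),
        amplitude=float(block.get("amplitude", 0.0)),
        baseline=float(block.get("baseline", 1.0)),
        duty=float(block.get("duty", 0.5)),
        constant_flag=bool(block.get("constant", False)),
    )
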