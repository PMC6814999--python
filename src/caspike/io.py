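"""Readers and writers for the pipeline's plain-text formats.

Spike tables are tab-delimited (unit_id, time_s, header line); trace tables
are comma-delimited with frame_time_s first and one column per ROI; movies
and masks are TIFF; the manifest and stats digest are JSON.  Every table we
write carries a provenance header of ``# key: value`` comment lines (config
hash, seed, package version) so outputs are auditable and reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import DataError, FormatError


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a canonical JSON rendering of the config."""
    payload = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def provenance_lines(seed: Optional[int] = None, cfg_hash: str = "",
                     extra: Optional[dict] = None) -> list[str]:
    items = {"caspike_version": __version__}
    if cfg_hash:
        items["config_hash"] = cfg_hash
    if seed is not None:
        items["seed"] = seed
    items.update(extra or {})
    return [f"# {k}: {v}" for k, v in items.items()]


def write_table(df: pd.DataFrame, path: Path | str, sep: str = ",",
                seed: Optional[int] = None, cfg_hash: str = "",
                extra: Optional[dict] = None) -> Path:
    """Write a DataFrame with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in provenance_lines(seed, cfg_hash, extra):
            fh.write(line + "\n")
        df.to_csv(fh, sep=sep, index=False, lineterminator="\n")
    return path


def read_table(path: Path | str, sep: str = ",") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"missing table {path}")
    return pd.read_csv(path, sep=sep, comment="#")


def write_spike_table(df: pd.DataFrame, path: Path | str, **kw) -> Path:
    if not {"unit_id", "time_s"} <= set(df.columns):
        raise FormatError("spike table needs unit_id and time_s columns")
    return write_table(df[["unit_id", "time_s"]], path, sep="\t", **kw)


def read_spike_table(path: Path | str) -> pd.DataFrame:
    df = read_table(path, sep="\t")
    if not {"unit_id", "time_s"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns unit_id, time_s")
    return df


def write_trace_table(frame_times: np.ndarray, traces: dict[str, np.ndarray],
                      path: Path | str, **kw) -> Path:
    df = pd.DataFrame({"frame_time_s": frame_times})
    for roi_id, values in traces.items():
        df[roi_id] = values
    return write_table(df, path, sep=",", **kw)


def read_trace_table(path: Path | str) -> pd.DataFrame:
    """Trace table as a frames × ROIs DataFrame indexed by frame_time_s."""
    df = read_table(path, sep=",")
    if "frame_time_s" not in df.columns:
        raise FormatError(f"{path}: expected a frame_time_s column")
    return df.set_index("frame_time_s")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def write_manifest(manifest: dict, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, sort_keys=True, indent=1,
                               default=_jsonable) + "\n")
    return path


def read_manifest(path: Path | str) -> dict:
    path = Path(path)
    if not path.exists():
        raise DataError(f"missing manifest {path}")
    return json.loads(path.read_text())


def write_tiff(stack: np.ndarray, path: Path | str) -> Path:
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack)
    return path


def read_tiff(path: Path | str) -> np.ndarray:
    import tifffile

    path = Path(path)
    if not path.exists():
        raise DataError(f"missing TIFF {path}")
    return tifffile.imread(path)


__all__ = [
    "config_hash",
    "provenance_lines",
    "write_table",
    "read_table",
    "write_spike_table",
    "read_spike_table",
    "write_trace_table",
    "read_trace_table",
    "write_manifest",
    "read_manifest",
    "write_tiff",
    "read_tiff",
]
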