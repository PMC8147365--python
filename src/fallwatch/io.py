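"""File-format contracts: sensor CSV, trajectory CSV, model JSON, manifests.

All CSV files are comma-separated UTF-8 with a mandatory header row and
'.' decimals.  Model JSON files carry ``schema_version`` (readers reject
unknown major versions) and a ``kind`` tag.  See docs/formats.md.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .sensor_sim import SENSOR_CSV_COLUMNS, STAGES
from .fusion import TRAJECTORY_CSV_COLUMNS

_SENSOR_NUMERIC = ["t", "u", "v", "d1", "d2", "d3"]
_SENSOR_BOOL = ["face_valid", "r1_valid", "r2_valid", "r3_valid"]


def write_sensor_csv(frames: pd.DataFrame, path) -> None:
    frames.to_csv(path, index=False, columns=SENSOR_CSV_COLUMNS)


def read_sensor_csv(path, require_stage: bool = False) -> pd.DataFrame:
    """Read and validate a sensor frame table.

    Malformed rows raise FormatError with the offending 1-based data
    line number.
    """
    path = Path(path)
    try:
        frames = pd.read_csv(path)
    except Exception as e:
        raise FormatError(f"{path}: cannot parse CSV: {e}") from e
    required = [c for c in SENSOR_CSV_COLUMNS if c != "stage"]
    missing = [c for c in required if c not in frames.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if require_stage and "stage" not in frames.columns:
        raise FormatError(f"{path}: ground-truth 'stage' column required")
    for col in _SENSOR_NUMERIC:
        coerced = pd.to_numeric(frames[col], errors="coerce")
        if col in ("u", "v"):  # legitimately empty on face dropout
            bad = coerced.isna() & frames[col].notna()
        else:
            bad = coerced.isna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise FormatError(f"{path}: non-numeric '{col}' at data line {line}")
        frames[col] = coerced
    for col in _SENSOR_BOOL:
        vals = frames[col]
        if vals.dtype != bool:
            mapped = vals.astype(str).str.strip().str.lower().map(
                {"true": True, "false": False, "1": True, "0": False})
            if mapped.isna().any():
                line = int(mapped.isna().idxmax()) + 1
                raise FormatError(f"{path}: non-boolean '{col}' at data line {line}")
            frames[col] = mapped.astype(bool)
    if "stage" in frames.columns:
        bad = ~frames["stage"].isin(STAGES)
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise FormatError(f"{path}: unknown stage at data line {line}")
    return frames


def write_trajectory_csv(events: list[pd.DataFrame], path) -> None:
    table = pd.concat(events, ignore_index=True)
    cols = [c for c in TRAJECTORY_CSV_COLUMNS if c in table.columns]
    table.to_csv(path, index=False, columns=cols)


def read_json(path, expected_kind: str | None = None) -> dict:
    with open(path) as fh:
        d = json.load(fh)
    if expected_kind is not None and d.get("kind") != expected_kind:
        raise FormatError(f"{path}: expected kind={expected_kind!r}, "
                          f"got {d.get('kind')!r}")
    return d


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, config_dict: dict, seed: int, outputs: list[str],
                   ) -> None:
    manifest = {
        "schema_version": "1.0",
        "kind": "manifest",
        "config_hash": config_hash(config_dict),
        "seed": int(seed),
        "config": config_dict,
        "outputs": outputs,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)


def write_surface_csv(surfaces, path) -> None:
    """Export 2D energy surfaces as CSV: x, y, rho, t, u, H, L."""
    pts = np.atleast_2d(surfaces.points)
    if pts.shape[1] != 2:
        raise FormatError("surface export is defined for 2D maps")
    pd.DataFrame({
        "x": pts[:, 0], "y": pts[:, 1], "rho": surfaces.rho,
        "t": surfaces.t, "u": surfaces.u, "H": surfaces.H, "L": surfaces.L,
    }).to_csv(path, index=False)
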