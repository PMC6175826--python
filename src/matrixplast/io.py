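"""Table and image-stack I/O with schema checking.

CSV schemas (column -> meaning):
  rheology trace:  t_s, stress_Pa, strain
  track table:     cell_id, t_min, x_um, y_um, z_um [, motile_truth]
  displacement:    x_um, y_um, u_um, v_um, valid
  protrusions:     cell_id, protrusion_id, t_min, length_um [, width_um]
Image stacks are multi-frame TIFF via tifffile.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .displacement import DisplacementField
from .rheology import RheoTrace

__all__ = ["save_table", "load_table", "save_stack", "load_stack",
           "save_trace", "load_trace", "save_field", "load_field",
           "save_json", "load_json", "SCHEMAS"]

SCHEMAS: dict[str, list[str]] = {
    "rheo_trace": ["t_s", "stress_Pa", "strain"],
    "tracks": ["cell_id", "t_min", "x_um", "y_um", "z_um"],
    "displacement": ["x_um", "y_um", "u_um", "v_um", "valid"],
    "protrusions": ["cell_id", "protrusion_id", "t_min", "length_um"],
}


def save_table(df: pd.DataFrame, path: str | Path,
               schema: str | None = None) -> Path:
    path = Path(path)
    if schema is not None:
        _check_schema(df, schema)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def load_table(path: str | Path, schema: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if schema is not None:
        _check_schema(df, schema)
    return df


def _check_schema(df: pd.DataFrame, schema: str) -> None:
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise ValueError(f"table does not match schema {schema!r}: "
                         f"missing columns {missing}")


def save_stack(frames: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(frames), photometric="minisblack")
    return path


def load_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def save_trace(trace: RheoTrace, path: str | Path) -> Path:
    df = pd.DataFrame({"t_s": trace.time, "stress_Pa": trace.applied_stress,
                       "strain": trace.strain})
    out = save_table(df, path, schema="rheo_trace")
    sidecar = Path(path).with_suffix(".json")
    save_json({"protocol": {"creep_stress_Pa": trace.protocol[0],
                            "load_duration_s": trace.protocol[1],
                            "recovery_duration_s": trace.protocol[2]}}, sidecar)
    return out


def load_trace(path: str | Path) -> RheoTrace:
    df = load_table(path, schema="rheo_trace")
    meta = load_json(Path(path).with_suffix(".json"))["protocol"]
    return RheoTrace(time=df["t_s"].to_numpy(),
                     applied_stress=df["stress_Pa"].to_numpy(),
                     strain=df["strain"].to_numpy(),
                     protocol=(meta["creep_stress_Pa"], meta["load_duration_s"],
                               meta["recovery_duration_s"]))


def save_field(field: DisplacementField, path: str | Path) -> Path:
    df = pd.DataFrame({
        "x_um": field.grid_x.ravel(), "y_um": field.grid_y.ravel(),
        "u_um": field.u.ravel(), "v_um": field.v.ravel(),
        "valid": field.valid_mask.ravel().astype(int)})
    out = save_table(df, path, schema="displacement")
    save_json({"shape": list(field.u.shape), "window": field.window,
               "mesh_size": field.mesh_size, "pixel_size": field.pixel_size},
              Path(path).with_suffix(".json"))
    return out


def load_field(path: str | Path) -> DisplacementField:
    df = load_table(path, schema="displacement")
    meta = load_json(Path(path).with_suffix(".json"))
    shape = tuple(meta["shape"])
    return DisplacementField(
        grid_x=df["x_um"].to_numpy().reshape(shape),
        grid_y=df["y_um"].to_numpy().reshape(shape),
        u=df["u_um"].to_numpy().reshape(shape),
        v=df["v_um"].to_numpy().reshape(shape),
        valid_mask=df["valid"].to_numpy().astype(bool).reshape(shape),
        window=meta["window"], mesh_size=meta["mesh_size"],
        pixel_size=meta["pixel_size"])


def save_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")
    return path


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
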