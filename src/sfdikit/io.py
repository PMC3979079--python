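"""Standard-format I/O: multi-frame TIFF stacks with JSON sidecars, CSV tables.

Every image-like intermediate (raw stacks, demodulated amplitudes,
reflectance, optical-property and spectral-parameter maps, label masks) is a
multi-frame TIFF whose axis semantics, physical units and acquisition
metadata live in a JSON sidecar next to it (``<name>.tif`` +
``<name>.json``). Round trips are lossless: arrays are stored at their native
dtype and metadata is validated against the payload on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = ["write_stack", "read_stack", "write_table", "read_table", "sidecar_path"]

FORMAT_VERSION = 1


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_stack(path, data: np.ndarray, meta: dict) -> None:
    """Write an N-D array as multi-frame TIFF plus a JSON sidecar.

    ``meta`` must include ``axes`` (a list naming each axis); axis-length
    metadata lists (e.g. ``wavelengths_nm``) are checked against the payload
    shape on read. The sidecar records shape and dtype for validation.
    """
    path = Path(path)
    data = np.asarray(data)
    if "axes" not in meta:
        raise ValueError("meta must declare 'axes'")
    if len(meta["axes"]) != data.ndim:
        raise ValueError("axes list must name every array axis")
    full = {
        "format_version": FORMAT_VERSION,
        "shape": list(data.shape),
        "dtype": str(data.dtype),
        **meta,
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, data.reshape(-1, *data.shape[-2:]), photometric="minisblack"
    )
    sidecar_path(path).write_text(json.dumps(_jsonable(full), indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


_AXIS_META = {
    "wavelength": "wavelengths_nm",
    "frequency": "frequencies_mm",
    "phase": "phases_rad",
    "parameter": "parameter_names",
}


def read_stack(path):
    """Read a TIFF + sidecar stack; returns (array, meta) after validation."""
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"missing sidecar {side}")
    try:
        meta = json.loads(side.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed sidecar {side}: {e}") from e
    if meta.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported stack format version {meta.get('format_version')!r}"
        )
    flat = tifffile.imread(path)
    shape = tuple(meta["shape"])
    if int(np.prod(shape)) != int(np.prod(flat.shape)):
        raise ValueError(f"payload of {path} does not match sidecar shape {shape}")
    data = np.asarray(flat).reshape(shape).astype(meta["dtype"], copy=False)
    for axis_name, key in _AXIS_META.items():
        if key in meta and axis_name in meta["axes"]:
            n = len(meta[key])
            ax = meta["axes"].index(axis_name)
            if shape[ax] != n:
                raise ValueError(
                    f"axis mismatch in {path}: axis {axis_name!r} has {shape[ax]} "
                    f"frames but sidecar lists {n} entries in {key!r}"
                )
    return data, meta


def write_table(path, df: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path, required_columns=()) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is missing required column(s): {missing}")
    return df
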