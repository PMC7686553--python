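"""Reading and writing: TIFF stacks, provenance-stamped CSV tables, YAML
configs for simulation parameters and layer layouts."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import CortexLayout, ImageStack
from .imgsim import SimParams

__all__ = [
    "write_stack",
    "read_stack",
    "write_table",
    "read_table",
    "save_params",
    "load_params",
    "save_layout",
    "load_layout",
]


def write_stack(path, stack: ImageStack) -> None:
    """Multi-page TIFF with voxel size and channel names in the image
    description (JSON)."""
    meta = {
        "voxel_size_um": list(stack.voxel_size_um),
        "channel_names": list(stack.channel_names),
        "is_3d": stack.is_3d,
    }
    tifffile.imwrite(
        str(path),
        stack.data.astype(np.float32),
        photometric="minisblack",
        description=json.dumps(meta),
    )


def read_stack(path) -> ImageStack:
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc)
    return ImageStack(
        data, tuple(meta["voxel_size_um"]), tuple(meta["channel_names"])
    )


def write_table(path, df: pd.DataFrame, provenance: dict | None = None) -> None:
    """CSV with a commented provenance header (``# key=value`` lines)."""
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> tuple[pd.DataFrame, dict]:
    prov = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("# ") and "=" in line:
                k, _, v = line[2:].strip().partition("=")
                prov[k] = v
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, prov


def save_params(path, params: SimParams) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(dataclasses.asdict(params)), fh, sort_keys=False)


def load_params(path) -> SimParams:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("intensity_mean_sd", "area_mean_sd_um2"):
        raw[key] = {k: tuple(v) for k, v in raw[key].items()}
    return SimParams(**raw)


def save_layout(path, layout: CortexLayout) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(dataclasses.asdict(layout)), fh, sort_keys=False)


def load_layout(path) -> CortexLayout:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["layer_widths"] = [tuple(p) for p in raw["layer_widths"]]
    raw["field_size_um"] = tuple(raw["field_size_um"])
    raw["voxel_size_um"] = tuple(raw["voxel_size_um"])
    return CortexLayout(**raw)


def _plain(obj):
    """Recursively convert tuples/arrays so YAML round-trips cleanly."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
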