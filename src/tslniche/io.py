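"""Readers and writers for the pipeline's on-disk formats.

Channel stacks are stored as multi-page TIFF (channel-major pages) with a
JSON sidecar (``<name>.json``) carrying channel names and voxel dimensions;
label volumes as integer TIFF with the same sidecar convention; spillover
matrices as CSV with channel names on both header axes; gates as JSON;
tables as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .containers import ChannelStack, LabelVolume, SpilloverMatrix
from .histocytometry import GateDef

__all__ = [
    "write_channel_stack",
    "read_channel_stack",
    "write_label_volume",
    "read_label_volume",
    "read_spillover_csv",
    "write_spillover_csv",
    "read_gates_json",
    "write_gates_json",
    "load_yaml_config",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_channel_stack(path: str | Path, stack: ChannelStack) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.intensities.astype(np.float32))
    meta = {
        "channel_names": stack.channel_names,
        "voxel_dims_um": list(stack.voxel_dims),
        "axes": "CZYX",
        "bit_depth": stack.bit_depth,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_channel_stack(path: str | Path) -> ChannelStack:
    path = Path(path)
    data = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    if data.ndim == 3:  # single channel
        data = data[None]
    return ChannelStack(
        data,
        meta["channel_names"],
        tuple(meta["voxel_dims_um"]),
        meta.get("bit_depth"),
    )


def write_label_volume(path: str | Path, vol: LabelVolume) -> None:
    path = Path(path)
    nmax = int(vol.labels.max()) if vol.labels.size else 0
    dtype = np.uint16 if nmax < 2**16 else np.uint32
    tifffile.imwrite(path, vol.labels.astype(dtype))
    meta = {"voxel_dims_um": list(vol.voxel_dims), "axes": "ZYX"}
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_label_volume(path: str | Path) -> LabelVolume:
    path = Path(path)
    data = tifffile.imread(path).astype(np.int64)
    meta = json.loads(_sidecar(path).read_text())
    return LabelVolume(data, tuple(meta["voxel_dims_um"]))


def write_spillover_csv(path: str | Path, spill: SpilloverMatrix) -> None:
    df = pd.DataFrame(spill.coefficients, index=spill.channel_names, columns=spill.channel_names)
    df.to_csv(path)


def read_spillover_csv(path: str | Path) -> SpilloverMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(
            f"spillover CSV row/column channel names differ: {list(df.index)} vs {list(df.columns)}"
        )
    return SpilloverMatrix(df.to_numpy(dtype=float), list(df.columns))


def write_gates_json(path: str | Path, gates: list[GateDef]) -> None:
    payload = [
        {
            "name": g.name,
            "x_feature": g.x_feature,
            "y_feature": g.y_feature,
            "vertices": [list(v) for v in g.vertices],
            "parent": g.parent,
        }
        for g in gates
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_gates_json(path: str | Path) -> list[GateDef]:
    payload = json.loads(Path(path).read_text())
    return [
        GateDef(
            name=g["name"],
            x_feature=g["x_feature"],
            y_feature=g["y_feature"],
            vertices=[tuple(v) for v in g["vertices"]],
            parent=g.get("parent"),
        )
        for g in payload
    ]


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
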