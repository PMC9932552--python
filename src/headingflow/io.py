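"""File formats: flow-sample containers, Middlebury .flo export, configs.

Flow samples are stored one per HDF5 file (flow array, validity mask, and
the trial spec JSON-encoded in an attribute) with a checksum for corruption
detection.  Individual frames can be exported to the Middlebury ``.flo``
dense-flow format for interoperability with standard visualization tools;
``.flo`` carries no metadata, so it is export-only.  Model parameters and
scene configs round-trip through YAML using the conventional short
parameter names (rMT, sigmaMT, rMST, sigmaMST, A, B, c).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import struct
import warnings
from pathlib import Path

import h5py
import numpy as np
import yaml

from .flow import FlowSample, SceneConfig, TrialSpec
from .model import ModelParams

__all__ = [
    "write_sample",
    "read_sample",
    "export_flo",
    "read_flo",
    "write_manifest",
    "load_params_yaml",
    "dump_params_yaml",
    "CorruptSampleError",
]

FLO_MAGIC = 202021.25


class CorruptSampleError(IOError):
    """A stored flow sample failed its checksum or is structurally invalid."""


def _spec_to_json(spec: TrialSpec) -> str:
    d = dataclasses.asdict(spec)
    d["blackout_frames"] = sorted(d["blackout_frames"])
    return json.dumps(d)


def _spec_from_json(payload: str) -> TrialSpec:
    d = json.loads(payload)
    d["blackout_frames"] = frozenset(d["blackout_frames"])
    return TrialSpec(**d)


def _digest(flow: np.ndarray, mask: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(flow).tobytes())
    h.update(np.ascontiguousarray(mask).tobytes())
    return h.hexdigest()


def write_sample(path, sample: FlowSample) -> None:
    """Write one flow sample losslessly to an HDF5 container."""
    with h5py.File(path, "w") as f:
        # track_times=False keeps the container byte-deterministic
        f.create_dataset("flow", data=sample.flow, track_times=False)
        f.create_dataset("valid_mask", data=sample.valid_mask, track_times=False)
        f.attrs["spec"] = _spec_to_json(sample.spec)
        f.attrs["sha256"] = _digest(sample.flow, sample.valid_mask)


def read_sample(path) -> FlowSample:
    """Read a flow sample back; raises :class:`CorruptSampleError` on damage."""
    try:
        with h5py.File(path, "r") as f:
            flow = f["flow"][...]
            mask = f["valid_mask"][...]
            spec = _spec_from_json(f.attrs["spec"])
            stored = f.attrs["sha256"]
    except (OSError, KeyError) as exc:
        raise CorruptSampleError(f"unreadable sample file {path}: {exc}") from exc
    if _digest(flow, mask) != stored:
        raise CorruptSampleError(f"checksum mismatch in {path}")
    return FlowSample(flow=flow, valid_mask=mask.astype(bool), spec=spec)


def export_flo(sample: FlowSample, frame: int, path) -> None:
    """Export one frame (1-based) as a Middlebury .flo file.

    Layout: float32 magic 202021.25, little-endian int32 width and height,
    then row-major interleaved (u, v) float32 pairs.  Blackout frames are
    exported as zeros with a warning.
    """
    if frame < 1 or frame > sample.n_frames:
        raise ValueError(f"frame {frame} outside [1, {sample.n_frames}]")
    if not sample.valid_mask[frame - 1]:
        warnings.warn(f"frame {frame} is a blackout frame; exporting zeros")
    grid = sample.flow[frame - 1].astype("<f4")
    h, w = grid.shape[:2]
    with open(path, "wb") as f:
        f.write(struct.pack("<f", FLO_MAGIC))
        f.write(struct.pack("<ii", w, h))
        f.write(np.ascontiguousarray(grid).tobytes())


def read_flo(path) -> np.ndarray:
    """Read a Middlebury .flo file into an (H, W, 2) float32 array."""
    with open(path, "rb") as f:
        (magic,) = struct.unpack("<f", f.read(4))
        if abs(magic - FLO_MAGIC) > 1e-3:
            raise IOError(f"bad .flo magic in {path}: {magic}")
        w, h = struct.unpack("<ii", f.read(8))
        data = np.frombuffer(f.read(h * w * 2 * 4), dtype="<f4")
        if data.size != h * w * 2:
            raise IOError(f"truncated .flo file {path}")
    return data.reshape(h, w, 2).copy()


def write_manifest(path, specs, paths, extra: dict | None = None) -> None:
    """CSV manifest mapping trial specs to their sample files."""
    import pandas as pd

    rows = []
    for spec, p in zip(specs, paths):
        row = dataclasses.asdict(spec)
        row["blackout_frames"] = ";".join(str(f) for f in sorted(spec.blackout_frames))
        row["path"] = str(p)
        if extra:
            row.update(extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def dump_params_yaml(path, params: ModelParams, scene: SceneConfig | None = None) -> None:
    doc = {"model": params.to_dict()}
    if scene is not None:
        doc["scene"] = dataclasses.asdict(scene)
        doc["scene"]["depth_range"] = list(scene.depth_range)
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)


def load_params_yaml(path) -> tuple[ModelParams, SceneConfig | None]:
    with open(path) as f:
        doc = yaml.safe_load(f)
    params = ModelParams.from_dict(doc.get("model", {}))
    scene = None
    if "scene" in doc:
        sd = dict(doc["scene"])
        if "depth_range" in sd:
            sd["depth_range"] = tuple(sd["depth_range"])
        scene = SceneConfig(**sd)
    return params, scene
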