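"""NIfTI and table I/O.

A :class:`~ctperf.core.DynamicSeries` travels as a 4D NIfTI file (voxel
dims in ``pixdim[1:4]``, time step in ``pixdim[4]``) plus a JSON sidecar
carrying acquisition metadata NIfTI has no field for (tube load, label,
time origin).  Label volumes are 3D integer NIfTI; AIFs are two-column
CSV (time_s, delta_hu) with the baseline index in a comment line.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import AcquisitionProtocol, DynamicSeries, InvalidInputError
from .quant import AIFCurve, ParametricMaps

__all__ = [
    "FormatError",
    "MetadataError",
    "sidecar_path",
    "write_series",
    "read_series",
    "write_label_volume",
    "read_label_volume",
    "write_aif",
    "read_aif",
    "write_maps",
]

SIDECAR_SCHEMA_VERSION = 1


class FormatError(ValueError):
    """File content does not match the expected image format."""


class MetadataError(ValueError):
    """Required acquisition metadata is missing or invalid."""


def sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def write_series(series: DynamicSeries, path: str | Path) -> Path:
    """Write a 4D NIfTI plus JSON sidecar; round-trips bit-exactly."""
    path = Path(path)
    img = nib.Nifti1Image(series.data.astype(np.float64), affine=np.eye(4))
    img.header.set_zooms(series.voxel_dims + (series.protocol.sampling_interval,))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, path)
    meta = {
        "schema_version": SIDECAR_SCHEMA_VERSION,
        "tube_load_mas": series.protocol.tube_load,
        "sampling_interval_s": series.protocol.sampling_interval,
        "n_frames": series.protocol.n_frames,
        "label": series.protocol.label,
        "time_start_s": float(series.time[0]),
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")
    return path


def read_series(
    path: str | Path, protocol: AcquisitionProtocol | None = None
) -> DynamicSeries:
    """Read a 4D NIfTI series; protocol from the sidecar unless given."""
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 4D series, got {data.ndim}D")
    zooms = img.header.get_zooms()
    if any(z <= 0 for z in zooms[:3]):
        raise MetadataError(f"{path}: non-positive pixdim {zooms[:3]}")
    time_start = 0.0
    if protocol is None:
        sp = sidecar_path(path)
        if not sp.exists():
            raise MetadataError(f"{path}: no sidecar {sp.name} and no protocol given")
        meta = json.loads(sp.read_text())
        try:
            protocol = AcquisitionProtocol(
                tube_load=meta["tube_load_mas"],
                sampling_interval=meta["sampling_interval_s"],
                n_frames=meta["n_frames"],
                label=meta.get("label", ""),
            )
        except KeyError as exc:
            raise MetadataError(f"{path}: sidecar missing field {exc}") from exc
        time_start = float(meta.get("time_start_s", 0.0))
    if protocol.n_frames != data.shape[3]:
        raise MetadataError(
            f"{path}: sidecar says {protocol.n_frames} frames, file has {data.shape[3]}"
        )
    return DynamicSeries(
        data,
        protocol.time_vector(start=time_start),
        tuple(float(z) for z in zooms[:3]),
        protocol,
    )


def write_label_volume(labels: np.ndarray, voxel_dims, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine=np.eye(4))
    img.header.set_zooms(tuple(voxel_dims))
    nib.save(img, path)
    return path


def read_label_volume(path: str | Path) -> np.ndarray:
    img = nib.load(Path(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D label volume, got {data.ndim}D")
    return data.astype(np.int16)


def write_aif(aif: AIFCurve, path: str | Path) -> Path:
    path = Path(path)
    lines = [f"# t0_index: {aif.t0}", "time_s,delta_hu"]
    lines += [f"{t:.9g},{c:.9g}" for t, c in zip(aif.time, aif.concentration)]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_aif(path: str | Path) -> AIFCurve:
    path = Path(path)
    t0 = 0
    times, concs = [], []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "t0_index" in line:
                t0 = int(line.split(":")[1])
            continue
        if line.startswith("time"):
            continue
        a, b = line.split(",")
        times.append(float(a))
        concs.append(float(b))
    if len(times) < 2:
        raise FormatError(f"{path}: AIF needs at least two samples")
    return AIFCurve(np.array(times), np.array(concs), t0)


def write_maps(maps: ParametricMaps, voxel_dims, out_prefix: str | Path) -> list[Path]:
    """One 3D NIfTI per parametric map plus the valid mask."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for name in maps.map_names:
        p = Path(f"{out_prefix}{name}.nii.gz")
        img = nib.Nifti1Image(maps[name].astype(np.float64), affine=np.eye(4))
        img.header.set_zooms(tuple(voxel_dims))
        nib.save(img, p)
        written.append(p)
    p = Path(f"{out_prefix}valid_mask.nii.gz")
    img = nib.Nifti1Image(maps.valid_mask.astype(np.uint8), affine=np.eye(4))
    img.header.set_zooms(tuple(voxel_dims))
    nib.save(img, p)
    written.append(p)
    return written
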