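"""Reading and writing of on-disk artifacts.

The canonical dataset layout is a single self-describing HDF5 container::

    /velocity            (nt, nz, ny, nx, 3) float, cm/s
    /masks/lv            (nt, nz, ny, nx) uint8        [optional]
    /meta                attrs: spacing (dz,dy,dx) mm, timeframe_duration ms,
                         venc cm/s, origin (x,y,z) mm, ed_index, es_index

A NIfTI volume-series importer is provided for interoperability with
scanner exports that store one 3-D volume per component per timeframe.
Metric tables are written as CSV with a JSON run-metadata sidecar.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any, Iterable, Mapping

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .datamodel import PlanarROI, SegmentationSet, ValvePlane, VelocityField4D

__all__ = [
    "write_dataset",
    "read_dataset",
    "import_nifti_series",
    "load_geometry",
    "write_results",
]


def write_dataset(
    path: str | Path,
    field: VelocityField4D,
    seg: SegmentationSet | None = None,
    overwrite: bool = False,
) -> None:
    """Write a velocity field (and optional segmentation) to an HDF5 container."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    with h5py.File(path, "w") as f:
        f.create_dataset("velocity", data=field.velocities)
        meta = f.create_group("meta")
        meta.attrs["spacing"] = np.asarray(field.spacing, dtype=np.float64)
        meta.attrs["timeframe_duration"] = float(field.timeframe_duration)
        meta.attrs["venc"] = float(field.venc)
        meta.attrs["origin"] = np.asarray(field.origin, dtype=np.float64)
        meta.attrs["velocity_units"] = "cm/s"
        if seg is not None:
            g = f.create_group("masks")
            g.create_dataset("lv", data=seg.lv_masks.astype(np.uint8))
            meta.attrs["ed_index"] = int(seg.ed_index)
            meta.attrs["es_index"] = int(seg.es_index)


def read_dataset(
    path: str | Path,
) -> tuple[VelocityField4D, SegmentationSet | None]:
    """Read a velocity field (and segmentation, if present) from a container.

    Raises
    ------
    KeyError
        If a required metadata field is missing (the error names it).
    ValueError
        If mask and velocity grids disagree (both shapes reported).
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "velocity" not in f:
            raise KeyError("container is missing the /velocity dataset")
        vel = f["velocity"][()]
        if "meta" not in f:
            raise KeyError("container is missing the /meta group")
        meta = f["meta"].attrs
        for key in ("spacing", "timeframe_duration", "venc"):
            if key not in meta:
                raise KeyError(f"container metadata is missing required field '{key}'")
        origin = tuple(meta.get("origin", (0.0, 0.0, 0.0)))
        field = VelocityField4D(
            vel,
            tuple(meta["spacing"]),
            float(meta["timeframe_duration"]),
            float(meta["venc"]),
            origin,
        )
        seg = None
        if "masks" in f and "lv" in f["masks"]:
            masks = f["masks/lv"][()].astype(bool)
            if masks.shape != vel.shape[:4]:
                raise ValueError(
                    f"mask grid {masks.shape} does not match velocity grid "
                    f"{vel.shape[:4]}"
                )
            if "ed_index" in meta and "es_index" in meta:
                seg = SegmentationSet(masks, int(meta["ed_index"]), int(meta["es_index"]))
            else:
                seg = SegmentationSet.from_masks(masks)
    return field, seg


def import_nifti_series(
    paths_per_component: Mapping[str, Iterable[str | Path]],
    timeframe_duration: float,
    venc: float,
    flip_axes: tuple[bool, bool, bool] = (False, False, False),
) -> VelocityField4D:
    """Build a :class:`VelocityField4D` from per-component NIfTI volume series.

    Parameters
    ----------
    paths_per_component
        Mapping with keys ``"vx", "vy", "vz"``; each value is the ordered
        list of per-timeframe NIfTI files for that component, in cm/s.
    flip_axes
        Explicit (x, y, z) axis flips, for scanner exports whose world
        handedness differs from this package's convention.  The exporting
        scanner's convention cannot be inferred reliably, so the caller
        states it.
    """
    comps = {}
    nt_ref: int | None = None
    for comp in ("vx", "vy", "vz"):
        if comp not in paths_per_component:
            raise KeyError(f"missing component series '{comp}'")
        files = [Path(p) for p in paths_per_component[comp]]
        missing = [i for i, p in enumerate(files) if not p.exists()]
        if missing:
            raise FileNotFoundError(
                f"component '{comp}' is missing timeframe file(s) at index "
                f"{missing}: {[str(files[i]) for i in missing]}"
            )
        vols, affine = [], None
        for p in files:
            img = nib.load(str(p))
            affine = img.affine
            # NIfTI stores (x, y, z); internal order is (z, y, x)
            vols.append(np.transpose(np.asarray(img.dataobj, dtype=np.float64)))
        comps[comp] = np.stack(vols, axis=0)
        if nt_ref is None:
            nt_ref = len(vols)
        elif len(vols) != nt_ref:
            raise ValueError(
                f"component '{comp}' has {len(vols)} timeframes, expected {nt_ref}"
            )
        zooms = nib.affines.voxel_sizes(affine)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = tuple(float(v) for v in affine[:3, 3])
    vel = np.stack([comps["vx"], comps["vy"], comps["vz"]], axis=-1)
    flip_x, flip_y, flip_z = flip_axes
    if flip_x:
        vel = vel[:, :, :, ::-1]
        vel[..., 0] *= -1
    if flip_y:
        vel = vel[:, :, ::-1]
        vel[..., 1] *= -1
    if flip_z:
        vel = vel[:, ::-1]
        vel[..., 2] *= -1
    return VelocityField4D(vel, spacing, timeframe_duration, venc, origin)


def load_geometry(path: str | Path) -> dict[str, Any]:
    """Load valve planes and ROI geometry from a YAML config.

    Expected keys: ``valve_planes`` (list of {label, point, normal}) and
    optionally ``rois`` (list of {point, normal, contours}), plus free-form
    preprocessing options which are passed through untouched.
    """
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    out: dict[str, Any] = dict(cfg)
    if "valve_planes" in cfg:
        out["valve_planes"] = {
            vp["label"]: ValvePlane(
                np.asarray(vp["point"], dtype=float),
                _normalized(vp["normal"]),
                vp["label"],
            )
            for vp in cfg["valve_planes"]
        }
    if "rois" in cfg:
        out["rois"] = [
            PlanarROI(
                np.asarray(r["point"], dtype=float),
                np.asarray(r["normal"], dtype=float),
                [np.asarray(c, dtype=float) for c in r["contours"]],
            )
            for r in cfg["rois"]
        ]
    return out


def _normalized(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


RESULT_COLUMNS = ["subject", "condition", "metric", "value", "units"]


def write_results(
    out_dir: str | Path,
    records: Iterable[Mapping[str, Any]],
    config: Mapping[str, Any] | None = None,
    seed: int | None = None,
    basename: str = "metrics",
    overwrite: bool = False,
) -> tuple[Path, Path]:
    """Write metric records to CSV plus a JSON run-metadata sidecar.

    Each record carries subject id, condition (sequence) label, metric name,
    value and units.  Column order is fixed so reruns produce byte-identical
    CSVs; the JSON sidecar records a config hash, the seed and the package
    version (its timestamp field is the only rerun-varying output).
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{basename}.csv"
    json_path = out_dir / f"{basename}.run.json"
    for p in (csv_path, json_path):
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists; pass overwrite=True to replace")
    df = pd.DataFrame(list(records), columns=RESULT_COLUMNS)
    df.to_csv(csv_path, index=False)
    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    meta = {
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": seed,
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    json_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return csv_path, json_path
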