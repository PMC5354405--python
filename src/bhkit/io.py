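"""File I/O helpers: NIfTI volumes, CSV/JSON tables, config hashing."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np


def save_nifti(data: np.ndarray, voxel_mm, path) -> None:
    """Write an array as NIfTI with an isotropic (or per-axis) mm affine."""
    voxel = np.broadcast_to(np.asarray(voxel_mm, dtype=float), (3,))
    affine = np.diag([voxel[0], voxel[1], voxel[2], 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI file; returns (data, voxel sizes in mm)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), np.asarray(img.header.get_zooms()[:3])


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_coerce))


def _coerce(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=_coerce)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def save_dynamics(dynamics, out_dir) -> None:
    """Write complex MR dynamics as paired phase/magnitude 4D NIfTI files.

    One ``<slice>_phase.nii.gz`` / ``<slice>_magnitude.nii.gz`` pair per
    thermometry slice, shaped (rows, cols, 1, dynamics), plus a
    ``dynamics.json`` sidecar carrying the timing, geometry and in-plane
    coordinates needed to reconstruct temperature.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geom = dynamics.geometry
    voxel = (geom.inplane_voxel_mm, geom.inplane_voxel_mm, geom.slice_thickness_mm)
    for name, img in dynamics.slices.items():
        arr = np.moveaxis(img, 0, -1)[:, :, None, :]  # (r, c, 1, t)
        save_nifti(np.angle(arr), voxel, out / f"{name}_phase.nii.gz")
        save_nifti(np.abs(arr), voxel, out / f"{name}_magnitude.nii.gz")
    write_json(
        {
            "slices": sorted(dynamics.slices),
            "times_s": dynamics.times,
            "baseline_temp_c": dynamics.baseline_temp,
            "coords_mm": {k: [r, c] for k, (r, c) in dynamics.coords.items()},
            "geometry": {
                "coronal_offsets_mm": list(geom.coronal_offsets_mm),
                "inplane_voxel_mm": geom.inplane_voxel_mm,
                "slice_thickness_mm": geom.slice_thickness_mm,
                "dynamic_time_s": geom.dynamic_time_s,
                "te_s": geom.te_s,
                "b0_t": geom.b0_t,
                "alpha_ppm_per_c": geom.alpha_ppm_per_c,
                "gamma_mhz_per_t": geom.gamma_mhz_per_t,
            },
        },
        out / "dynamics.json",
    )


def load_dynamics(in_dir):
    """Inverse of :func:`save_dynamics`."""
    from .synthetic import ComplexDynamics, ThermometryGeometry

    src = Path(in_dir)
    meta = json.loads((src / "dynamics.json").read_text())
    gm = meta["geometry"]
    gm["coronal_offsets_mm"] = tuple(gm["coronal_offsets_mm"])
    geom = ThermometryGeometry(**gm)
    slices, coords = {}, {}
    for name in meta["slices"]:
        phase, _ = load_nifti(src / f"{name}_phase.nii.gz")
        mag, _ = load_nifti(src / f"{name}_magnitude.nii.gz")
        img = mag * np.exp(1j * phase)
        slices[name] = np.moveaxis(img[:, :, 0, :], -1, 0)
        r, c = meta["coords_mm"][name]
        coords[name] = (np.asarray(r), np.asarray(c))
    return ComplexDynamics(
        slices=slices,
        coords=coords,
        geometry=geom,
        times=np.asarray(meta["times_s"]),
        baseline_temp=meta["baseline_temp_c"],
    )


def save_series(series, out_dir) -> None:
    """Write a temperature series as per-slice 4D NIfTI + sidecar JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geom = series.geometry
    voxel = (geom.inplane_voxel_mm, geom.inplane_voxel_mm, geom.slice_thickness_mm)
    for name, temps in series.slices.items():
        arr = np.moveaxis(temps, 0, -1)[:, :, None, :]
        save_nifti(arr, voxel, out / f"{name}_temperature.nii.gz")
    write_json(
        {
            "slices": sorted(series.slices),
            "times_s": series.times,
            "baseline_temp_c": series.baseline_temp,
            "coords_mm": {k: [r, c] for k, (r, c) in series.coords.items()},
            "pixel_area_mm2": geom.pixel_area_mm2,
            "inplane_voxel_mm": geom.inplane_voxel_mm,
        },
        out / "temperature.json",
    )


def load_series(in_dir):
    """Inverse of :func:`save_series` (geometry restored with defaults except
    pixel size)."""
    from .synthetic import ThermometryGeometry
    from .thermometry import ThermometrySeries

    src = Path(in_dir)
    meta = json.loads((src / "temperature.json").read_text())
    slices, coords = {}, {}
    for name in meta["slices"]:
        arr, _ = load_nifti(src / f"{name}_temperature.nii.gz")
        slices[name] = np.moveaxis(arr[:, :, 0, :], -1, 0)
        r, c = meta["coords_mm"][name]
        coords[name] = (np.asarray(r), np.asarray(c))
    geom = ThermometryGeometry(inplane_voxel_mm=meta["inplane_voxel_mm"])
    return ThermometrySeries(
        slices=slices,
        coords=coords,
        geometry=geom,
        times=np.asarray(meta["times_s"]),
        baseline_temp=meta["baseline_temp_c"],
    )
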