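"""NIfTI / JSON / CSV input-output.

Image stacks are stored as one 4D NIfTI volume whose contrast order matches
the schedule with the full-recovery image last, plus a JSON sidecar::

    {"finite_ts_ms": [...], "full_recovery": true, "hr_bpm": 60}

T1 maps are stored as a 5-volume 4D NIfTI (T1, amplitude, efficiency,
residual, converged mask) with a small JSON metadata sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError
from .fitting import T1Map
from .phantom import DigitalPhantom
from .signal_model import SaturationSchedule, WeightedImageStack


def _affine(voxel_size) -> np.ndarray:
    return np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])


def _default_sidecar(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".schedule.json")
    return path.with_suffix(".schedule.json")


def schedule_to_dict(schedule: SaturationSchedule) -> dict:
    return {
        "finite_ts_ms": list(schedule.finite_ts),
        "full_recovery": schedule.has_full_recovery,
        "hr_bpm": schedule.hr_bpm,
    }


def schedule_from_dict(d: dict) -> SaturationSchedule:
    try:
        return SaturationSchedule(
            finite_ts=tuple(d["finite_ts_ms"]),
            has_full_recovery=bool(d["full_recovery"]),
            hr_bpm=float(d.get("hr_bpm", 60.0)),
        )
    except KeyError as e:
        raise FormatError(f"schedule sidecar missing key {e}") from e


def write_stack(stack: WeightedImageStack, path, schedule_path=None) -> None:
    path = Path(path)
    schedule_path = Path(schedule_path) if schedule_path else _default_sidecar(path)
    img = nib.Nifti1Image(np.asarray(stack.data, dtype=np.float32), _affine(stack.voxel_size))
    nib.save(img, str(path))
    meta = schedule_to_dict(stack.schedule)
    meta["noise_sigma"] = stack.noise_sigma
    if stack.seed is not None:
        meta["seed"] = int(stack.seed)
    schedule_path.write_text(json.dumps(meta, indent=1))


def read_stack(path, schedule_path=None) -> WeightedImageStack:
    path = Path(path)
    schedule_path = Path(schedule_path) if schedule_path else _default_sidecar(path)
    meta = json.loads(schedule_path.read_text())
    schedule = schedule_from_dict(meta)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim == 3:
        # single-contrast dialect: only valid when the sidecar says one image
        if schedule.n_images == 1:
            data = data[..., None]
        else:
            raise FormatError(
                f"3D file but the sidecar defines {schedule.n_images} images"
            )
    if data.ndim != 4:
        raise FormatError(f"expected a 4D stack, got {data.ndim}D")
    if data.shape[3] != schedule.n_images:
        raise FormatError(
            f"file has {data.shape[3]} volumes but the sidecar defines "
            f"{schedule.n_images} images"
        )
    vox = tuple(float(v) for v in img.header.get_zooms()[:3])
    return WeightedImageStack(
        data=data,
        schedule=schedule,
        voxel_size=vox,
        noise_sigma=float(meta.get("noise_sigma", 0.0)),
        seed=meta.get("seed"),
    )


_T1MAP_VOLUMES = ("t1", "amplitude", "efficiency", "residual", "converged")


def write_t1map(t1map: T1Map, path) -> None:
    path = Path(path)
    stacked = np.stack(
        [
            t1map.t1_volume,
            t1map.amplitude_volume,
            t1map.efficiency_volume,
            t1map.residual_volume,
            t1map.converged_mask.astype(float),
        ],
        axis=3,
    ).astype(np.float32)
    nib.save(nib.Nifti1Image(stacked, _affine(t1map.voxel_size)), str(path))
    meta = {"volumes": list(_T1MAP_VOLUMES), "voxel_size_mm": list(t1map.voxel_size)}
    _default_sidecar(path).with_name(
        _default_sidecar(path).name.replace(".schedule.json", ".meta.json")
    ).write_text(json.dumps(meta, indent=1))


def read_t1map(path) -> T1Map:
    img = nib.load(str(Path(path)))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[3] != len(_T1MAP_VOLUMES):
        raise FormatError(f"expected a {len(_T1MAP_VOLUMES)}-volume T1 map file")
    vox = tuple(float(v) for v in img.header.get_zooms()[:3])
    return T1Map(
        t1_volume=data[..., 0],
        amplitude_volume=data[..., 1],
        efficiency_volume=data[..., 2],
        residual_volume=data[..., 3],
        converged_mask=data[..., 4] > 0.5,
        voxel_size=vox,
    )


def write_phantom(phantom: DigitalPhantom, out_dir) -> None:
    """Write label map, ground-truth parameter volumes and the region table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(phantom.voxel_size)
    nib.save(nib.Nifti1Image(phantom.labels.astype(np.int16), aff), str(out / "labels.nii.gz"))
    t1, m0, eff = phantom.parameter_volumes()
    for name, vol in (("t1", t1), ("m0", m0), ("efficiency", eff)):
        nib.save(nib.Nifti1Image(vol.astype(np.float32), aff), str(out / f"{name}.nii.gz"))
    phantom.region_table().to_csv(out / "regions.csv", index=False)
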