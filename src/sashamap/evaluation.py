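"""Accuracy/precision evaluation of T1 maps.

The ROI mean T1 serves as the accuracy measure (compared against the known
ground truth or a reference map) and the ROI standard deviation as the
surrogate for precision.  Agreement between two mapping variants (e.g. raw
vs denoised) is summarized with Bland-Altman bias and 1.96-SD limits of
agreement.  Spatial uniformity over the left ventricle is summarized with
the AHA 17-segment model (6 basal + 6 mid + 4 apical sectors, segment 17 =
blood pool).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DataError
from .fitting import T1Map


@dataclass(frozen=True)
class ROIStats:
    mean_t1: float
    sd_t1: float
    n_voxels: int
    roi_label: object = None


@dataclass(frozen=True)
class BlandAltmanSummary:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n_pairs: int


@dataclass
class AHASummary:
    """17-row table: segments 1-16 (myocardium) plus 17 (blood pool)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.table) != 17:
            raise DataError("AHA summary must have exactly 17 segments")


def eroded_mask(mask: np.ndarray, erode_vox: int = 2) -> np.ndarray:
    """Erode a 3D mask in-plane by ``erode_vox`` voxels.

    Erosion is applied slice by slice (2D), the reproducible analogue of a
    manual ROI drawn inside a region's border on each short-axis slice.
    """
    mask = np.asarray(mask, dtype=bool)
    if erode_vox <= 0:
        return mask.copy()
    out = np.zeros_like(mask)
    for z in range(mask.shape[2]):
        out[:, :, z] = ndimage.binary_erosion(mask[:, :, z], iterations=erode_vox)
    return out


def roi_stats(t1map: T1Map, roi_mask: np.ndarray, label=None) -> ROIStats:
    """Mean and SD of fitted T1 over an ROI, excluding non-converged voxels."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != t1map.shape:
        raise DataError("ROI mask shape does not match the T1 map")
    eff = roi_mask & t1map.converged_mask
    n = int(eff.sum())
    if n == 0:
        raise DataError("ROI is empty after intersecting with the converged mask")
    vals = t1map.t1_volume[eff]
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return ROIStats(mean_t1=float(vals.mean()), sd_t1=sd, n_voxels=n, roi_label=label)


def bland_altman(values_a, values_b) -> BlandAltmanSummary:
    """Bland-Altman agreement of paired measurements (differences a - b)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("inputs must be equal-length 1D vectors")
    if len(a) < 2:
        raise DataError("at least 2 pairs are required")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanSummary(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        sd_diff=sd, n_pairs=len(a),
    )


def precision_improvement(sd_before: float, sd_after: float) -> float:
    """Signed percent reduction of the precision surrogate (ROI SD)."""
    if not sd_before > 0:
        raise DataError("sd_before must be positive")
    return 100.0 * (sd_before - sd_after) / sd_before


def line_profile(volume: np.ndarray, start_voxel, end_voxel, n_samples: int) -> np.ndarray:
    """Linearly interpolated intensity profile between two voxel coordinates."""
    volume = np.asarray(volume, dtype=float)
    start = np.asarray(start_voxel, dtype=float)
    end = np.asarray(end_voxel, dtype=float)
    if n_samples < 2:
        raise DataError("n_samples must be >= 2")
    if start.shape != (volume.ndim,) or end.shape != (volume.ndim,):
        raise DataError("endpoints must have one coordinate per volume axis")
    for p in (start, end):
        if np.any(p < 0) or np.any(p > np.asarray(volume.shape) - 1):
            raise DataError(f"endpoint {tuple(p)} lies outside the volume")
    frac = np.linspace(0.0, 1.0, n_samples)
    coords = start[:, None] + (end - start)[:, None] * frac[None, :]
    return ndimage.map_coordinates(volume, coords, order=1, mode="nearest")


# AHA band layout: (band name, first segment number, sector count)
_AHA_BANDS = (("base", 1, 6), ("mid", 7, 6), ("apex", 13, 4))


def aha_summary(
    t1map: T1Map,
    lv_center,
    rv_insertion_angle: float,
    slice_bands,
    myo_mask: np.ndarray,
    blood_mask: np.ndarray,
) -> AHASummary:
    """AHA 16+1-segment mean/SD summary of a short-axis T1 map.

    Parameters
    ----------
    lv_center : (cx, cy) or array of shape (nz, 2)
        In-plane LV center, either shared by all slices or per slice.
    rv_insertion_angle : float
        Zero-angle reference in degrees, in [0, 360); sectors are counted
        counterclockwise (increasing atan2 angle) from this direction.
    slice_bands : ((z0, z1), (z0, z1), (z0, z1))
        Half-open slice index ranges for base, mid and apex.
    myo_mask, blood_mask : 3D bool
        Myocardial and blood-pool voxel sets.

    Basal and mid bands are split into 6 sectors of 60 degrees, the apical
    band into 4 of 90 degrees; segment 17 is the blood pool.  Empty segments
    are reported with n_voxels = 0 and NaN statistics, not raised.
    """
    if not 0 <= rv_insertion_angle < 360:
        raise DataError("rv_insertion_angle must be in [0, 360)")
    myo_mask = np.asarray(myo_mask, dtype=bool)
    blood_mask = np.asarray(blood_mask, dtype=bool)
    if myo_mask.shape != t1map.shape or blood_mask.shape != t1map.shape:
        raise DataError("mask shapes must match the T1 map")
    if not myo_mask.any() or not blood_mask.any():
        raise DataError("myocardial and blood-pool masks must be nonempty")
    nz = t1map.shape[2]
    centers = np.asarray(lv_center, dtype=float)
    if centers.shape == (2,):
        centers = np.tile(centers, (nz, 1))
    if centers.shape != (nz, 2):
        raise DataError("lv_center must be (cx, cy) or an (nz, 2) array")
    if len(slice_bands) != 3:
        raise DataError("slice_bands must give (base, mid, apex) ranges")

    valid = t1map.converged_mask
    t1 = t1map.t1_volume
    seg_values: dict[int, list[float]] = {s: [] for s in range(1, 18)}

    for (band, seg0, n_sec), (z0, z1) in zip(_AHA_BANDS, slice_bands):
        width = 360.0 / n_sec
        for z in range(int(z0), int(z1)):
            sl = myo_mask[:, :, z] & valid[:, :, z]
            if not sl.any():
                continue
            xs, ys = np.nonzero(sl)
            cx, cy = centers[z]
            theta = (np.degrees(np.arctan2(ys - cy, xs - cx)) - rv_insertion_angle) % 360.0
            sector = np.minimum((theta // width).astype(int), n_sec - 1)
            for s in range(n_sec):
                seg_values[seg0 + s].extend(t1[xs[sector == s], ys[sector == s], z])

    blood_eff = blood_mask & valid
    seg_values[17] = list(t1[blood_eff])

    rows = []
    band_of = {s: b for b, s0, n in _AHA_BANDS for s in range(s0, s0 + n)}
    band_of[17] = "blood"
    for s in range(1, 18):
        vals = np.asarray(seg_values[s], dtype=float)
        n = len(vals)
        rows.append(
            {
                "segment": s,
                "band": band_of[s],
                "mean_t1": float(vals.mean()) if n else np.nan,
                "sd_t1": (float(vals.std(ddof=1)) if n > 1 else (0.0 if n else np.nan)),
                "n_voxels": n,
            }
        )
    return AHASummary(table=pd.DataFrame(rows))
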