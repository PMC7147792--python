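"""Pixel-wise three-parameter saturation-recovery fitting.

Each voxel's signals along the recovery curve are fit to

    S(TS) = A * (1 - B * exp(-TS / T1))

by bounded trust-region nonlinear least squares.  The full-recovery sample
enters as an exact model point with the exponential term equal to zero
(residual A - S_fullrec) rather than as a large finite saturation time, so no
arbitrary sentinel delay is involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DataError
from .signal_model import SaturationSchedule, WeightedImageStack

#: Parameter bounds: T1 in ms, B dimensionless (slack above 1 absorbs noise).
T1_BOUNDS = (1.0, 5000.0)
B_BOUNDS = (0.0, 1.2)

#: Convergence gates: relative RMS residual and minimum saturation efficiency.
MAX_REL_RESIDUAL = 0.2
MIN_EFFICIENCY = 0.05


@dataclass(frozen=True)
class FitResult:
    """Per-voxel fit outcome.

    ``converged`` is False for degenerate voxels (background, flat curves,
    poor fits); such voxels are excluded from all downstream ROI statistics.
    """

    t1: float
    amplitude: float
    efficiency: float
    residual_norm: float
    converged: bool
    n_points: int


@dataclass
class T1Map:
    """Volumes of fitted parameters; non-converged voxels are NaN/False."""

    t1_volume: np.ndarray
    amplitude_volume: np.ndarray
    efficiency_volume: np.ndarray
    residual_volume: np.ndarray
    converged_mask: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        shapes = {
            a.shape
            for a in (
                self.t1_volume,
                self.amplitude_volume,
                self.efficiency_volume,
                self.residual_volume,
                self.converged_mask,
            )
        }
        if len(shapes) != 1:
            raise DataError(f"T1Map volumes must share one shape, got {shapes}")

    @property
    def shape(self):
        return self.t1_volume.shape


def fit_voxel(
    schedule: SaturationSchedule,
    signals,
    init: tuple[float, float, float] | None = None,
) -> FitResult:
    """Fit one voxel's recovery curve.

    Parameters
    ----------
    schedule : SaturationSchedule
        Sample times; signal order must match (full-recovery last).
    signals : array-like
        Non-negative magnitudes, one per schedule image.
    init : (A, B, T1), optional
        Custom initialization; the default uses the full-recovery signal (or
        the maximum signal), B = 1 and T1 = median finite saturation time.
    """
    s = np.asarray(signals, dtype=float)
    if s.ndim != 1 or len(s) != schedule.n_images:
        raise DataError(
            f"expected {schedule.n_images} signals matching the schedule, got {s.shape}"
        )
    if len(s) < 3:
        raise DataError("at least 3 samples are required for a three-parameter fit")
    if np.any(s < 0) or not np.all(np.isfinite(s)):
        raise DataError("signals must be finite and non-negative")

    n_points = len(s)
    smax = float(s.max())
    if smax <= 0:
        # background voxel: flagged, not an exception
        return FitResult(
            t1=np.nan, amplitude=np.nan, efficiency=np.nan,
            residual_norm=0.0, converged=False, n_points=n_points,
        )

    ts = np.asarray(schedule.finite_ts, dtype=float)
    has_fr = schedule.has_full_recovery
    s_fin = s[: len(ts)]
    s_fr = float(s[-1]) if has_fr else smax

    if init is None:
        a0 = s_fr if s_fr > 0 else smax
        x0 = np.array([a0, 1.0, float(np.median(ts))])
    else:
        x0 = np.asarray(init, dtype=float)
    lo = np.array([0.0, B_BOUNDS[0], T1_BOUNDS[0]])
    hi = np.array([10.0 * smax, B_BOUNDS[1], T1_BOUNDS[1]])
    x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)

    def residuals(p):
        a, b, t1 = p
        e = np.exp(-ts / t1)
        r = a * (1.0 - b * e) - s_fin
        if has_fr:
            r = np.append(r, a - s_fr)
        return r

    def jacobian(p):
        a, b, t1 = p
        e = np.exp(-ts / t1)
        j = np.empty((len(ts) + (1 if has_fr else 0), 3))
        j[: len(ts), 0] = 1.0 - b * e
        j[: len(ts), 1] = -a * e
        j[: len(ts), 2] = -a * b * e * ts / t1**2
        if has_fr:
            j[-1] = (1.0, 0.0, 0.0)
        return j

    res = least_squares(
        residuals, x0, jac=jacobian, bounds=(lo, hi), method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=200,
    )
    a, b, t1 = res.x
    residual_norm = float(np.sqrt(np.mean(res.fun**2)))
    rel_resid = residual_norm / max(float(s.mean()), 1e-30)
    converged = bool(res.success) and rel_resid < MAX_REL_RESIDUAL and b >= MIN_EFFICIENCY
    return FitResult(
        t1=float(t1), amplitude=float(a), efficiency=float(b),
        residual_norm=residual_norm, converged=converged, n_points=n_points,
    )


def fit_volume(stack: WeightedImageStack, mask: np.ndarray | None = None) -> T1Map:
    """Fit every (masked) voxel of a stack, producing a T1 map.

    The default mask keeps voxels with any positive signal; all-zero
    (background) voxels come back non-converged either way.
    """
    data = np.asarray(stack.data, dtype=float)
    spatial = data.shape[:3]
    if mask is None:
        mask = data.max(axis=3) > 0
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != spatial:
            raise DataError(f"mask shape {mask.shape} does not match stack {spatial}")

    t1 = np.full(spatial, np.nan)
    amp = np.full(spatial, np.nan)
    eff = np.full(spatial, np.nan)
    resid = np.full(spatial, np.nan)
    conv = np.zeros(spatial, dtype=bool)
    for idx in np.argwhere(mask):
        i, j, k = idx
        r = fit_voxel(stack.schedule, data[i, j, k, :])
        t1[i, j, k] = r.t1
        amp[i, j, k] = r.amplitude
        eff[i, j, k] = r.efficiency
        resid[i, j, k] = r.residual_norm
        conv[i, j, k] = r.converged
    return T1Map(
        t1_volume=t1, amplitude_volume=amp, efficiency_volume=eff,
        residual_volume=resid, converged_mask=conv, voxel_size=stack.voxel_size,
    )


def subset_schedule(stack: WeightedImageStack, n_images: int) -> WeightedImageStack:
    """Retrospectively reduce a stack to ``n_images`` contrasts.

    Keeps the full-recovery image plus (n_images - 1) finite-TS images chosen
    by rounding a linspace over the finite indices, so the retained delays
    are maximally evenly spread and always include the first and last finite
    saturation times.  The schedule is updated consistently.
    """
    total = stack.n_images
    if not 3 <= n_images <= total:
        raise DataError(f"n_images must be in [3, {total}], got {n_images}")
    sched = stack.schedule
    nf = len(sched.finite_ts)
    k = n_images - (1 if sched.has_full_recovery else 0)
    idx = np.round(np.linspace(0, nf - 1, k)).astype(int)
    keep = list(idx) + ([total - 1] if sched.has_full_recovery else [])
    new_sched = SaturationSchedule(
        finite_ts=tuple(sched.finite_ts[i] for i in idx),
        has_full_recovery=sched.has_full_recovery,
        hr_bpm=sched.hr_bpm,
    )
    return WeightedImageStack(
        data=stack.data[..., keep],
        schedule=new_sched,
        voxel_size=stack.voxel_size,
        noise_sigma=stack.noise_sigma,
        seed=stack.seed,
    )
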