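"""Saturation schedules, the SASHA forward signal model and stack simulation.

A saturation-recovery acquisition samples the longitudinal recovery curve at
a set of saturation times (TS) plus one unprepared image measuring the fully
recovered magnetization.  The three-parameter signal model is

    S(TS) = A * (1 - B * exp(-TS / T1))

with A the equilibrium signal, B the saturation efficiency (1 for ideal
saturation) and T1 the relaxation time.  The full-recovery image is treated
analytically as TS = infinity, i.e. S = A, never as a large finite delay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ScheduleError
from .phantom import DigitalPhantom, DEFAULT_VOXEL_SIZE

#: Sentinel saturation time of the unprepared (fully recovered) image.
FULL_RECOVERY = math.inf

#: Default shortest saturation time, ms.
DEFAULT_TS_MIN = 54.0

#: Margin subtracted from the RR interval to obtain the longest saturation
#: time; 60 bpm (RR = 1000 ms) then gives ts_max = 740 ms.
TS_MAX_RR_MARGIN = 260.0

#: Nominal acquisition time per T1-weighted image, seconds, calibrated from a
#: 9-image protocol with a 4:14 (254 s) nominal scan time.
DEFAULT_PER_IMAGE_SECONDS = 254.0 / 9.0


@dataclass(frozen=True)
class SaturationSchedule:
    """Ordered saturation delays plus an optional full-recovery sample.

    ``finite_ts`` are strictly increasing delays in ms.  The full-recovery
    image, when present, is by convention the LAST contrast of an image
    stack aligned to this schedule.
    """

    finite_ts: tuple[float, ...]
    has_full_recovery: bool = True
    hr_bpm: float = 60.0

    def __post_init__(self) -> None:
        ts = tuple(float(t) for t in self.finite_ts)
        object.__setattr__(self, "finite_ts", ts)
        if any(t <= 0 for t in ts):
            raise ScheduleError("all saturation times must be > 0 ms")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ScheduleError("saturation times must be strictly increasing")
        if self.n_images < 1:
            raise ScheduleError("schedule defines no images")
        if not self.hr_bpm > 0:
            raise ScheduleError("heart rate must be positive")

    @property
    def n_images(self) -> int:
        return len(self.finite_ts) + (1 if self.has_full_recovery else 0)

    def ts_values(self) -> tuple[float, ...]:
        """All sample times in contrast order (full recovery last, as inf)."""
        return self.finite_ts + ((FULL_RECOVERY,) if self.has_full_recovery else ())


@dataclass
class WeightedImageStack:
    """4D magnitude stack (x, y, z, contrast) aligned to a schedule."""

    data: np.ndarray
    schedule: SaturationSchedule
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise DataError(f"stack data must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] != self.schedule.n_images:
            raise DataError(
                f"stack has {self.data.shape[3]} contrasts but the schedule "
                f"defines {self.schedule.n_images} images"
            )

    @property
    def n_images(self) -> int:
        return self.data.shape[3]


def generate_schedule(
    n_images: int,
    hr_bpm: float,
    ts_min: float = DEFAULT_TS_MIN,
    ts_max: float | None = None,
) -> SaturationSchedule:
    """Equally spaced saturation times plus one full-recovery image.

    The (n_images - 1) finite delays are linearly spaced on
    [ts_min, ts_max].  When ``ts_max`` is omitted it is derived from the
    heart rate as RR - 260 ms, so a 60 bpm acquisition spans 54-740 ms.
    """
    if n_images < 3:
        raise ScheduleError(f"n_images must be >= 3, got {n_images}")
    if not hr_bpm > 0:
        raise ScheduleError("heart rate must be positive")
    if ts_max is None:
        ts_max = 60000.0 / hr_bpm - TS_MAX_RR_MARGIN
    if ts_min >= ts_max:
        raise ScheduleError(f"ts_min ({ts_min}) must be < ts_max ({ts_max})")
    finite = np.linspace(ts_min, ts_max, n_images - 1)
    return SaturationSchedule(finite_ts=tuple(finite), has_full_recovery=True, hr_bpm=hr_bpm)


def sasha_signal(t1, m0, efficiency, ts):
    """Forward saturation-recovery signal S(TS) = m0 (1 - eff exp(-TS/T1)).

    ``ts`` may be :data:`FULL_RECOVERY` (infinity), giving S = m0.
    Accepts array-valued ``t1``/``m0``/``efficiency`` for vectorized use.
    """
    ts = np.asarray(ts, dtype=float) if np.ndim(ts) else float(ts)
    if np.any(np.asarray(ts) < 0):
        raise DataError("saturation time must be non-negative")
    if np.any(np.asarray(t1) <= 0):
        raise DataError("t1 must be > 0")
    if np.any(np.asarray(m0) < 0):
        raise DataError("m0 must be >= 0")
    with np.errstate(over="ignore"):
        decay = np.exp(-np.asarray(ts, dtype=float) / np.asarray(t1, dtype=float))
    out = np.asarray(m0, dtype=float) * (1.0 - np.asarray(efficiency, dtype=float) * decay)
    if np.ndim(out) == 0:
        return float(out)
    return out


def sigma_for_snr(phantom: DigitalPhantom, snr: float) -> float:
    """Noise SD giving the requested SNR on the foreground full-recovery image.

    SNR is defined as the mean equilibrium (full-recovery) signal over all
    labeled voxels divided by the Gaussian noise SD.
    """
    if not snr > 0:
        raise DataError("SNR must be positive")
    _, m0, _ = phantom.parameter_volumes()
    fg = phantom.labels > 0
    if not fg.any():
        raise DataError("phantom has no foreground voxels")
    return float(m0[fg].mean() / snr)


def simulate_stack(
    phantom: DigitalPhantom,
    schedule: SaturationSchedule,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> WeightedImageStack:
    """Simulate a magnitude image stack from a phantom and schedule.

    The noiseless forward model is evaluated per voxel and schedule entry;
    zero-mean Gaussian noise of SD ``noise_sigma`` is added independently per
    voxel and contrast and the magnitude (absolute value) is taken — the
    high-SNR Gaussian approximation of Rician magnitude noise, exact
    half-normal in the zero-signal background.
    """
    if noise_sigma < 0:
        raise DataError("noise_sigma must be >= 0")
    t1, m0, eff = phantom.parameter_volumes()
    fg = phantom.labels > 0
    n = schedule.n_images
    clean = np.zeros(phantom.shape + (n,), dtype=float)
    # safe T1 for the vectorized exponent; background stays at zero signal
    t1_safe = np.where(fg, t1, 1.0)
    for i, ts in enumerate(schedule.ts_values()):
        if math.isinf(ts):
            clean[..., i] = m0
        else:
            clean[..., i] = np.where(fg, m0 * (1.0 - eff * np.exp(-ts / t1_safe)), 0.0)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data = np.abs(clean + rng.normal(0.0, noise_sigma, size=clean.shape))
    else:
        data = clean
    return WeightedImageStack(
        data=data,
        schedule=schedule,
        voxel_size=phantom.voxel_size,
        noise_sigma=float(noise_sigma),
        seed=seed,
    )


def nominal_scan_time(
    n_images: int, per_image_seconds: float = DEFAULT_PER_IMAGE_SECONDS
) -> int:
    """Nominal scan time in whole seconds, linear in the image count."""
    if n_images < 1:
        raise DataError("n_images must be >= 1")
    if not per_image_seconds > 0:
        raise DataError("per_image_seconds must be > 0")
    return int(round(n_images * per_image_seconds))
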