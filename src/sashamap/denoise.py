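"""Joint Beltrami regularization of multi-contrast T1-weighted stacks.

The T1-weighted images of a saturation-recovery acquisition are highly
redundant: edges (vial walls, myocardium/blood interfaces) sit at the same
spatial location in every contrast, only the intensities along the recovery
curve differ.  The denoiser therefore treats the stack as a single
vector-valued volume and minimizes one Beltrami energy in which all
contrasts share the manifold metric:

    E(u) = sum_voxels sqrt(1 + beta^2 * sum_c |grad u_c|^2)
           + (lambda/2) * sum_c ||u_c - f_c||^2

The square-root term is the area element of the image-graph manifold; for
small gradients it behaves like isotropic (Tikhonov) smoothing and for large
gradients like total variation, preserving edges without staircasing.
Coupling the contrasts under one metric means an edge supported by all
saturation times suppresses smoothing across it in every contrast.

Spatial gradients use forward finite differences divided by the physical
voxel spacing, so strongly anisotropic voxels (e.g. 8 mm slices vs 1.4 mm
in-plane) are smoothed correspondingly less through-plane.

Intensities are normalized to the stack's 99th percentile before the solve
and restored afterwards, making ``beta`` and ``lam`` data-scale invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DataError, SolverError
from .signal_model import WeightedImageStack


@dataclass(frozen=True)
class DenoiseConfig:
    """Solver parameters for :func:`beltrami_denoise`.

    Parameters
    ----------
    beta : float
        Gradient-scale parameter on the normalized [0, 1] intensity scale;
        larger values push the regularizer toward total-variation behaviour
        (stronger edge preservation).
    lam : float
        Fidelity weight; larger values keep the output closer to the input.
        The effective edge-stopping smoothing weight is roughly beta/lam.
    max_iter : int
        Iteration cap for the descent.
    tol : float
        Relative energy-decrease stopping threshold.
    step : float or None
        Initial descent step; None picks a conservative estimate from beta,
        lam and the voxel spacing (backtracking adapts it thereafter).
    """

    beta: float = 100.0
    lam: float = 2400.0
    max_iter: int = 200
    tol: float = 1e-4
    step: float | None = None

    def __post_init__(self) -> None:
        if not (self.beta > 0 and self.lam > 0 and self.max_iter > 0 and self.tol > 0):
            raise DataError("beta, lam, max_iter and tol must all be positive")
        if not self.tol < 1:
            raise DataError("tol must be < 1")
        if self.step is not None and not self.step > 0:
            raise DataError("step must be positive when given")


def _forward_diffs(u: np.ndarray, spacing) -> list[np.ndarray]:
    """Forward differences of a 4D stack along the 3 spatial axes.

    Neumann boundary: the difference at the last index of each axis is 0.
    """
    grads = []
    for ax in range(3):
        g = np.zeros_like(u)
        sl_hi = [slice(None)] * 4
        sl_lo = [slice(None)] * 4
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(None, -1)
        g[tuple(sl_lo)] = (u[tuple(sl_hi)] - u[tuple(sl_lo)]) / spacing[ax]
        grads.append(g)
    return grads


def _divergence_adjoint(p: list[np.ndarray], spacing) -> np.ndarray:
    """Adjoint of :func:`_forward_diffs` (negative divergence)."""
    out = np.zeros_like(p[0])
    for ax in range(3):
        h = spacing[ax]
        sl_lo = [slice(None)] * 4
        sl_lo[ax] = slice(None, -1)
        sl_hi = [slice(None)] * 4
        sl_hi[ax] = slice(1, None)
        out[tuple(sl_lo)] -= p[ax][tuple(sl_lo)] / h
        out[tuple(sl_hi)] += p[ax][tuple(sl_lo)] / h
    return out


def beltrami_energy(u: np.ndarray, f: np.ndarray, beta: float, lam: float, voxel_size) -> float:
    """Evaluate the joint Beltrami objective E(u) for a candidate stack.

    ``u`` and ``f`` are 4D (x, y, z, contrast) arrays of identical shape.
    Each voxel contributes sqrt(1 + beta^2 * sum over contrasts and axes of
    squared spacing-scaled gradients), plus the (lambda/2) quadratic
    fidelity to ``f``.  A spatially constant stack of N voxels has energy N.
    """
    u = np.asarray(u, dtype=float)
    f = np.asarray(f, dtype=float)
    if u.shape != f.shape:
        raise DataError(f"shape mismatch: u {u.shape} vs f {f.shape}")
    if u.ndim != 4:
        raise DataError("stacks must be 4D (x, y, z, contrast)")
    grads = _forward_diffs(u, voxel_size)
    g2 = sum((g**2).sum(axis=3) for g in grads)  # per-voxel, summed over contrasts
    reg = np.sqrt(1.0 + beta**2 * g2).sum()
    fid = 0.5 * lam * ((u - f) ** 2).sum()
    return float(reg + fid)


def _energy_and_gradient(u, f, beta, lam, spacing):
    grads = _forward_diffs(u, spacing)
    g2 = sum((g**2).sum(axis=3) for g in grads)
    root = np.sqrt(1.0 + beta**2 * g2)
    energy = float(root.sum() + 0.5 * lam * ((u - f) ** 2).sum())
    w = (beta**2 / root)[..., None]
    grad = _divergence_adjoint([w * g for g in grads], spacing)
    grad += lam * (u - f)
    return energy, grad


def beltrami_denoise(
    stack: WeightedImageStack,
    config: DenoiseConfig = DenoiseConfig(),
    return_trace: bool = False,
):
    """Denoise a T1-weighted stack by minimizing the joint Beltrami energy.

    Runs monotone gradient descent with backtracking line search on the
    normalized intensities, stopping when the relative energy decrease per
    iteration falls below ``config.tol`` or after ``config.max_iter``
    iterations.  The output stack keeps the input's schedule, voxel size and
    noise provenance.

    With ``return_trace=True`` also returns the per-iteration energies
    (index 0 is the energy of the input).
    """
    f = np.asarray(stack.data, dtype=float)
    if not np.all(np.isfinite(f)):
        raise DataError("input stack contains non-finite values")
    spacing = stack.voxel_size
    beta, lam = config.beta, config.lam

    scale = float(np.percentile(f, 99.0))
    if scale <= 0:
        # all-(near-)zero stack: fixed point of the energy
        out = replace(stack, data=f.copy())
        return (out, [beltrami_energy(f, f, beta, lam, spacing)]) if return_trace else out
    fn = f / scale
    u = fn.copy()

    if config.step is not None:
        step = config.step
    else:
        # worst-case curvature: fidelity lam plus the flat-region diffusion
        # limit beta^2 * ||D^T D|| with 4/h^2 per axis
        step = 1.0 / (lam + 4.0 * beta**2 * sum(1.0 / h**2 for h in spacing))

    energy, grad = _energy_and_gradient(u, fn, beta, lam, spacing)
    if not np.isfinite(energy):
        raise SolverError("non-finite initial energy")
    trace = [energy]
    fails = 0
    for _ in range(config.max_iter):
        accepted = False
        while step > 1e-18:
            u_new = u - step * grad
            e_new = beltrami_energy(u_new, fn, beta, lam, spacing)
            if not np.isfinite(e_new):
                raise SolverError("energy diverged to a non-finite value")
            if e_new <= energy:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            fails += 1
            if fails >= 5:
                raise SolverError("descent failed to decrease the energy 5 times in a row")
            break
        fails = 0
        rel = (energy - e_new) / max(abs(energy), 1e-30)
        u = u_new
        energy, grad = _energy_and_gradient(u, fn, beta, lam, spacing)
        trace.append(energy)
        step *= 1.5
        if rel < config.tol:
            break

    out = replace(stack, data=u * scale)
    if return_trace:
        return out, trace
    return out
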