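"""Viscous-fluid-style non-rigid registration (greedy compositional flow).

The solver treats the coordinate mapping between a pre-aligned pair of
scans as the flow of a viscous fluid: at each iteration the intensity
force ``(fixed - warped) * grad(warped)`` is regularised by a Gaussian
filter of width ``sigma_fluid`` (regularising the velocity rather than the
displacement, so large diffeomorphic deformations can accumulate), scaled
so the largest update is at most ``max_step`` voxels, and composed onto
the running displacement field. When the minimum Jacobian of the field
drops below the regrid threshold the partially warped image becomes the
new source and the field is reset (classic fluid regridding); the final
field is the composition of all regrids. SSD decreases monotonically over
accepted steps (step-halving backtracking), and divergence raises
``SolverError`` with the iteration trace.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..types import SolverError
from .jacobian import jacobian_determinant


@dataclass(frozen=True)
class FluidParams:
    """Solver constants of the fluid registration."""

    n_levels: int = 2
    sigma_fluid: float = 2.0  # voxels; Gaussian width of the fluid regulariser
    max_step: float = 0.4  # voxels; largest displacement update per iteration
    regrid_threshold: float = 0.5  # regrid when min Jacobian falls below this
    max_iter: int = 150  # per pyramid level
    tol: float = 1e-5  # relative SSD change considered converged
    n_backtrack: int = 4  # step halvings before declaring no progress

    def __post_init__(self):
        if not 0.0 < self.regrid_threshold < 1.0:
            raise ValueError("regrid threshold must lie in (0, 1)")
        if self.max_step <= 0:
            raise ValueError("step bound must be positive")


@dataclass
class DisplacementField:
    """Dense per-voxel displacement (voxel units), fixed grid -> moving."""

    disp: np.ndarray  # (ndim, *shape)
    spacing: tuple[float, ...] = ()

    @property
    def ndim(self) -> int:
        return int(self.disp.shape[0])

    @property
    def shape(self):
        return self.disp.shape[1:]


@dataclass
class ConvergenceReport:
    converged: bool
    n_iterations: int
    initial_ssd: float
    final_ssd: float
    n_regrids: int
    trace: list = field(default_factory=list)


def _identity_grid(shape):
    return np.mgrid[tuple(slice(n) for n in shape)].astype(float)


def warp_image(image: np.ndarray, disp: np.ndarray, order: int = 1) -> np.ndarray:
    """Sample ``image`` at identity + displacement (linear by default,
    cubic for final resampling)."""
    coords = _identity_grid(image.shape) + disp
    return ndimage.map_coordinates(image, coords, order=order, mode="nearest")


def compose_displacements(outer: np.ndarray, inner: np.ndarray) -> np.ndarray:
    """Displacement of the composed map x -> x + inner(x) + outer(x + inner(x))."""
    coords = _identity_grid(inner.shape[1:]) + inner
    warped_outer = np.stack([
        ndimage.map_coordinates(outer[d], coords, order=1, mode="nearest")
        for d in range(outer.shape[0])
    ])
    return inner + warped_outer


def _min_jacobian(disp: np.ndarray) -> float:
    return float(jacobian_determinant(DisplacementField(disp)).min())


def _fluid_level(moving, fixed, disp, params: FluidParams, trace, order=1):
    """Run the greedy flow at one resolution; returns (disp, regrid stack)."""
    shape = fixed.shape
    regrids: list[np.ndarray] = []
    src = moving
    ssd_prev = None
    stall = 0
    for it in range(params.max_iter):
        warped = warp_image(src, disp, order=order)
        ssd = float(((warped - fixed) ** 2).sum())
        if ssd_prev is None:
            ssd0 = ssd
        else:
            rel = (ssd_prev - ssd) / max(ssd_prev, 1e-30)
            if 0 <= rel < params.tol:
                stall += 1
                if stall >= 3:
                    break
            else:
                stall = 0
        ssd_prev = ssd
        grad = np.stack(np.gradient(warped))
        force = (fixed - warped) * grad
        vel = np.stack([
            ndimage.gaussian_filter(force[d], params.sigma_fluid)
            for d in range(force.shape[0])
        ])
        vmax = float(np.abs(vel).max())
        if vmax < 1e-12:
            break
        step = params.max_step / vmax
        accepted = False
        for _ in range(params.n_backtrack):
            delta = vel * step
            trial = compose_displacements(disp, delta)
            trial_ssd = float(((warp_image(src, trial, order=order) - fixed) ** 2).sum())
            if trial_ssd < ssd:
                accepted = True
                break
            step *= 0.5
        trace.append({"iter": it, "ssd": ssd, "accepted": accepted})
        if not accepted:
            break
        disp = trial
        if _min_jacobian(disp) < params.regrid_threshold:
            src = warp_image(src, disp, order=3)
            regrids.append(disp)
            disp = np.zeros((len(shape), *shape))
    if ssd_prev is not None and ssd_prev > 1.5 * ssd0 + 1e-12:
        raise SolverError("fluid registration diverged", trace)
    return disp, regrids, ssd0 if ssd_prev is not None else 0.0, ssd_prev or 0.0


def register_fluid(
    moving: np.ndarray,
    fixed: np.ndarray,
    params: FluidParams = FluidParams(),
    spacing: tuple[float, ...] | None = None,
) -> tuple[DisplacementField, ConvergenceReport]:
    """Fluid-register a pre-aligned pair; returns (field, report).

    The returned field maps fixed-grid coordinates to moving-image
    coordinates (``warp_image(moving, field.disp)`` reproduces the fixed
    image); its Jacobian therefore measures moving-image volume per unit
    fixed-image volume.
    """
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    if moving.shape != fixed.shape:
        raise ValueError("fluid registration expects equal shapes (pre-aligned)")
    ndim = fixed.ndim
    trace: list = []
    disp = None
    total_regrids = 0
    ssd0_full = ssd1_full = 0.0
    for level in range(params.n_levels - 1, -1, -1):
        f = 2**level
        if f > 1:
            mov_l = ndimage.zoom(ndimage.gaussian_filter(moving, f / 2), 1 / f, order=1)
            fix_l = ndimage.zoom(ndimage.gaussian_filter(fixed, f / 2), 1 / f, order=1)
        else:
            mov_l, fix_l = moving, fixed
        if disp is None:
            disp = np.zeros((ndim, *fix_l.shape))
        else:
            disp = np.stack([
                ndimage.zoom(disp[d], np.array(fix_l.shape) / np.array(disp.shape[1:]),
                             order=1) for d in range(ndim)
            ]) * 2.0
        disp, regrids, ssd0, ssd1 = _fluid_level(mov_l, fix_l, disp, params, trace)
        # fold the regrid stack back into one field: the field active at the
        # time of a regrid is applied *after* (outside) everything composed
        # since, so walk the stack newest-first
        for outer in reversed(regrids):
            disp = compose_displacements(outer, disp)
        total_regrids += len(regrids)
        if level == params.n_levels - 1:
            ssd0_full = ssd0
        ssd1_full = ssd1
    report = ConvergenceReport(
        converged=True, n_iterations=len(trace),
        initial_ssd=ssd0_full, final_ssd=ssd1_full,
        n_regrids=total_regrids, trace=trace)
    return DisplacementField(disp, spacing or (1.0,) * ndim), report
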