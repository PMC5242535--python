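"""Linear (rigid / rigid+scale) intensity-based registration.

Dimension-generic (2-D and 3-D). A transform maps fixed-image voxel
coordinates to moving-image voxel coordinates about the grid centre:
``y = R @ S @ (x - c) + c + t``. dof=6 is rigid (rotations +
translations; scales pinned to 1), dof=9 adds per-axis scales, and a
uniform-scale variant (7 dof) is available for sensitivity analysis.
The similarity metric is SSD after z-score intensity normalisation,
optimised with Powell's method over a Gaussian pyramid.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from ..types import SolverError


def _n_angles(ndim: int) -> int:
    return 1 if ndim == 2 else 3


def rotation_matrix(angles, ndim: int) -> np.ndarray:
    """Compose plane rotations; angles in radians (1 angle in 2-D, 3 in 3-D
    for the (0,1), (0,2) and (1,2) index planes)."""
    R = np.eye(ndim)
    planes = [(0, 1)] if ndim == 2 else [(0, 1), (0, 2), (1, 2)]
    for (i, j), a in zip(planes, np.atleast_1d(angles)):
        P = np.eye(ndim)
        c, s = np.cos(a), np.sin(a)
        P[i, i], P[i, j], P[j, i], P[j, j] = c, -s, s, c
        R = R @ P
    return R


@dataclass
class LinearTransform:
    """Parametric linear transform (voxel units, centre-anchored)."""

    ndim: int
    angles: np.ndarray
    translation: np.ndarray
    scales: np.ndarray
    dof: int = 6
    center: np.ndarray = field(default=None)

    @classmethod
    def identity(cls, ndim: int, dof: int = 6, center=None):
        return cls(ndim, np.zeros(_n_angles(ndim)), np.zeros(ndim),
                   np.ones(ndim), dof, center)

    @property
    def matrix(self) -> np.ndarray:
        M = getattr(self, "_matrix_override", None)
        if M is not None:
            return M
        return rotation_matrix(self.angles, self.ndim) @ np.diag(self.scales)

    def volume_ratio(self) -> float:
        """Determinant of the linear part; exactly 1 for rigid (dof=6)."""
        return float(np.prod(self.scales))

    def apply_to_points(self, pts: np.ndarray) -> np.ndarray:
        c = self.center
        return (pts - c) @ self.matrix.T + c + self.translation

    def inverse(self) -> "LinearTransform":
        """Matrix-exact inverse (same centre anchor)."""
        M = np.linalg.inv(self.matrix)
        inv = LinearTransform(
            self.ndim, -np.asarray(self.angles), -M @ self.translation,
            1.0 / self.scales, self.dof, self.center)
        inv._matrix_override = M
        return inv

    def resample(self, moving: np.ndarray, order: int = 1) -> np.ndarray:
        """Pull the moving image onto the fixed grid."""
        A = self.matrix
        c = self.center
        offset = c + self.translation - A @ c
        return ndimage.affine_transform(
            moving, A, offset=offset, order=order, mode="constant", cval=0.0)


def _params_to_transform(p, ndim, dof, uniform_scale, center):
    na = _n_angles(ndim)
    angles = p[:na]
    trans = p[na:na + ndim]
    if dof <= 6:
        scales = np.ones(ndim)
    elif uniform_scale:
        scales = np.exp(np.full(ndim, p[na + ndim]))
    else:
        scales = np.exp(p[na + ndim:na + 2 * ndim])
    return LinearTransform(ndim, np.asarray(angles, float),
                           np.asarray(trans, float), scales, dof,
                           np.asarray(center, float))


def _normalize(img: np.ndarray) -> np.ndarray:
    # scale by the foreground spread only: the zero background must stay
    # at zero so border fill (cval=0) is intensity-neutral
    m = img[img > img.max() * 0.05] if img.max() > 0 else img
    sd = m.std() if m.size else 1.0
    return img / (sd if sd > 0 else 1.0)


def register_linear(
    moving: np.ndarray,
    fixed: np.ndarray,
    dof: int = 6,
    uniform_scale: bool = False,
    n_levels: int = 3,
    init: np.ndarray | None = None,
) -> LinearTransform:
    """Estimate the linear transform aligning ``moving`` to ``fixed``.

    Returns the transform that, applied via :meth:`LinearTransform.resample`,
    pulls the moving image onto the fixed grid. Raises ``SolverError`` if
    the optimiser returns a non-finite misfit.
    """
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    ndim = fixed.ndim
    na = _n_angles(ndim)
    n_scale = 0 if dof <= 6 else (1 if uniform_scale else ndim)
    center = (np.array(fixed.shape) - 1) / 2.0
    p = np.zeros(na + ndim + n_scale) if init is None else np.array(init, float)

    mov_n = _normalize(moving)
    fix_n = _normalize(fixed)
    for level in range(n_levels - 1, -1, -1):
        f = 2**level
        if f > 1:
            mov_l = ndimage.zoom(ndimage.gaussian_filter(mov_n, f / 2), 1 / f, order=1)
            fix_l = ndimage.zoom(ndimage.gaussian_filter(fix_n, f / 2), 1 / f, order=1)
        else:
            mov_l, fix_l = mov_n, fix_n
        center_l = (np.array(fix_l.shape) - 1) / 2.0

        def cost(q):
            t = _params_to_transform(q, ndim, dof, uniform_scale, center_l)
            warped = t.resample(mov_l)
            return float(((warped - fix_l) ** 2).mean())

        p_l = p.copy()
        p_l[na:na + ndim] /= f
        res = optimize.minimize(
            cost, p_l, method="Powell",
            options={"xtol": 1e-4 if level else 1e-6,
                     "ftol": 1e-8, "maxiter": 4000})
        if not np.isfinite(res.fun):
            raise SolverError(f"linear registration diverged (misfit={res.fun})")
        p = res.x.copy()
        p[na:na + ndim] *= f
    return _params_to_transform(p, ndim, dof, uniform_scale, center)
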