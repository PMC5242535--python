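"""Jacobian-determinant maps of displacement fields.

The Jacobian of the deformation ``phi(x) = x + u(x)`` is
``det(I + Du)``, the local volume ratio of the mapping: 1 means no
volume change, >1 expansion and <1 contraction of the moving image
relative to the fixed grid. Gradients use central differences in the
interior and one-sided differences at the boundaries (``np.gradient``).
"""
from __future__ import annotations

import numpy as np


def jacobian_determinant(field) -> np.ndarray:
    """Per-voxel determinant of (I + Du) for a DisplacementField or a raw
    ``(ndim, *shape)`` displacement array in voxel units."""
    disp = np.asarray(getattr(field, "disp", field), float)
    if not np.all(np.isfinite(disp)):
        raise ValueError("displacement field contains non-finite values")
    ndim = disp.shape[0]
    grads = [np.gradient(disp[d]) for d in range(ndim)]
    if ndim == 2:
        (u_y, u_x), (v_y, v_x) = grads
        return (1 + u_y) * (1 + v_x) - u_x * v_y
    J = np.empty(disp.shape[1:] + (ndim, ndim))
    for i in range(ndim):
        gi = grads[i] if isinstance(grads[i], list) else list(grads[i])
        for j in range(ndim):
            J[..., i, j] = gi[j] + (1.0 if i == j else 0.0)
    return np.linalg.det(J)
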