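"""2-D slice phantoms for fast tensor-based-morphometry studies.

A soft-edged disk "brain" with an embedded higher-intensity subregion
whose area can be scaled per subject — the 2-D analogue of the 3-D
phantom, small enough that the full fluid + Jacobian + permutation-FDR
pipeline runs in seconds.
"""
from __future__ import annotations

import numpy as np


def brain_slice(
    shape: tuple[int, int] = (64, 64),
    brain_radius: float = 22.0,
    region_center: tuple[float, float] = (-5.0, 6.0),
    region_radius: float = 8.0,
    region_area_scale: float = 1.0,
    edge_softness: float = 1.5,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one slice; returns ``(image, region_mask)``.

    ``region_area_scale`` scales the subregion *area* (radius by its
    square root), so 0.8 plants a 20% regional volume loss. The returned
    mask is the unscaled (template-sized) region footprint.
    """
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(float)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    d_brain = np.hypot(yy - cy, xx - cx)
    img = 1.0 / (1.0 + np.exp((d_brain - brain_radius) / edge_softness * 4))
    ry, rx = cy + region_center[0], cx + region_center[1]
    d_reg = np.hypot(yy - ry, xx - rx)
    r_eff = region_radius * np.sqrt(region_area_scale)
    img += 0.8 / (1.0 + np.exp((d_reg - r_eff) / edge_softness * 4))
    if noise_sd > 0:
        img += np.random.default_rng(seed).normal(0.0, noise_sd, shape)
    return img, d_reg <= region_radius


def slice_cohort(
    n_per_group: int = 10,
    region_loss: float = 0.2,
    subject_sd: float = 0.03,
    noise_sd: float = 0.02,
    seed: int = 0,
    **kwargs,
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray, np.ndarray]:
    """Two groups of slices: controls at full region area, cases with a
    planted fractional region-area loss. Returns
    ``(control_images, case_images, template, region_mask)`` where the
    template is the noise-free control anatomy.
    """
    rng = np.random.default_rng(seed)
    template, region_mask = brain_slice(**kwargs)
    controls, cases = [], []
    for _ in range(n_per_group):
        s = float(np.exp(rng.normal(0.0, subject_sd)))
        img, _ = brain_slice(region_area_scale=s, noise_sd=noise_sd,
                             seed=int(rng.integers(2**31)), **kwargs)
        controls.append(img)
    for _ in range(n_per_group):
        s = float((1.0 - region_loss) * np.exp(rng.normal(0.0, subject_sd)))
        img, _ = brain_slice(region_area_scale=s, noise_sd=noise_sd,
                             seed=int(rng.integers(2**31)), **kwargs)
        cases.append(img)
    return controls, cases, template, region_mask
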