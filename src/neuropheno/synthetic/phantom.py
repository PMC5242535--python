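"""Analytic brain phantom: labelled ellipsoid regions on a voxel grid.

Each region is an ellipsoid whose semi-axes are scaled isotropically so its
analytic volume matches the growth/atrophy trajectory's target at the
requested age. Voxels are labelled by centre-point inclusion, so the
voxel-count volume tracks the analytic target to within a surface-shell
discretisation error.
"""
from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from ..types import ConfigurationError, DegenerateRegionError, LabelVolume
from .config import (
    BRAIN_SUBREGIONS,
    COMPOSITE_REGIONS,
    PhantomSpec,
    RegionSpec,
    TrajectoryConfig,
)


def ellipsoid_volume(semiaxes_mm) -> float:
    """Analytic ellipsoid volume 4/3*pi*a*b*c in mm^3."""
    a, b, c = semiaxes_mm
    return 4.0 / 3.0 * math.pi * a * b * c


def _region_mask(shape, spacing, center_mm, semiaxes_mm) -> np.ndarray:
    """Boolean centre-point-inclusion mask of an ellipsoid, evaluated on a
    bounding box only and pasted into the full grid."""
    grid_center = [(n - 1) / 2.0 * s for n, s in zip(shape, spacing)]
    mask = np.zeros(shape, dtype=bool)
    lo, hi = [], []
    for ax in range(3):
        c = grid_center[ax] + center_mm[ax]
        lo.append(max(0, int(math.floor((c - semiaxes_mm[ax]) / spacing[ax])) - 1))
        hi.append(min(shape[ax], int(math.ceil((c + semiaxes_mm[ax]) / spacing[ax])) + 2))
    if any(l >= h for l, h in zip(lo, hi)):
        return mask
    coords = [
        (np.arange(lo[ax], hi[ax]) * spacing[ax] - grid_center[ax] - center_mm[ax])
        / semiaxes_mm[ax]
        for ax in range(3)
    ]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij", sparse=True)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = zz**2 + yy**2 + xx**2 <= 1.0
    return mask


def region_targets(
    spec: PhantomSpec,
    age_weeks: float,
    trajectory: TrajectoryConfig,
    genotype: str,
    sex: str,
) -> dict[str, float]:
    """Per-region analytic target volumes (mm^3) at an age."""
    return {
        r.name: trajectory.volume_target(r.name, genotype, sex, age_weeks)
        for r in spec.regions
    }


def generate_phantom(
    spec: PhantomSpec,
    age_weeks: float,
    trajectory: TrajectoryConfig,
    genotype: str,
    sex: str,
    *,
    subject_scale: float = 1.0,
    volume_jitter: Mapping[str, float] | None = None,
    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> LabelVolume:
    """Render the labelled phantom for one subject at one age.

    Deterministic given identical arguments: all randomness (per-subject
    allometric scale, per-observation jitter, sub-voxel position shifts)
    enters through the explicit ``subject_scale`` / ``volume_jitter`` /
    ``shift_mm`` arguments drawn at the cohort level.

    Raises ``ConfigurationError`` if scaled regions overlap or a brain
    subregion escapes the brain envelope, and ``DegenerateRegionError`` if
    a target volume falls below one voxel.
    """
    if not 8.0 <= age_weeks <= 94.0:
        raise ConfigurationError(f"age {age_weeks} outside the study window [8, 94]")
    targets = region_targets(spec, age_weeks, trajectory, genotype, sex)
    jitter = volume_jitter or {}
    # anatomy scales with the whole brain: region centre offsets follow the
    # brain's own linear scale so relative geometry is preserved as the
    # brain grows or atrophies
    brain_ref = spec.region("brain")
    brain_target = targets["brain"] * subject_scale * jitter.get("brain", 1.0)
    brain_scale = (brain_target / brain_ref.reference_volume) ** (1.0 / 3.0)
    masks: dict[str, np.ndarray] = {}
    for r in spec.regions:
        target = targets[r.name] * subject_scale * jitter.get(r.name, 1.0)
        if target < spec.voxel_volume:
            raise DegenerateRegionError(
                f"region {r.name!r} target volume {target:.4g} mm^3 is below one voxel")
        scale = (target / r.reference_volume) ** (1.0 / 3.0)
        center = tuple(brain_scale * c + d for c, d in zip(r.center_mm, shift_mm))
        semi = tuple(a * scale for a in r.semiaxes_mm)
        masks[r.name] = _region_mask(spec.shape, spec.spacing, center, semi)

    brain = masks["brain"]
    data = np.zeros(spec.shape, dtype=np.int16)
    labels: dict[str, int] = {}
    occupied = np.zeros(spec.shape, dtype=bool)
    for name in BRAIN_SUBREGIONS:
        m = masks[name]
        if np.any(m & ~brain):
            raise ConfigurationError(f"subregion {name!r} extends outside the brain")
        if np.any(m & occupied):
            raise ConfigurationError(f"region {name!r} overlaps another region")
        lab = spec.region(name).label
        data[m] = lab
        labels[name] = lab
        occupied |= m
    shell = brain & ~occupied
    data[shell] = spec.region("brain").label
    labels["brain_shell"] = spec.region("brain").label

    muscle = masks["muscle"]
    if np.any(muscle & brain):
        raise ConfigurationError("muscle block overlaps the brain")
    lab = spec.region("muscle").label
    data[muscle] = lab
    labels["muscle"] = lab

    return LabelVolume(
        data=data, spacing=spec.spacing, labels=labels,
        composites=dict(COMPOSITE_REGIONS),
    )
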