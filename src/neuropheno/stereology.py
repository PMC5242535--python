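"""Design-based stereology: Cavalieri volumes, the optical fractionator,
and the Gundersen-Jensen coefficient of error.

Cavalieri: on systematically spaced sections (period d), points of a grid
with area-per-point a/p are counted inside the structure;
``V = sum(P) * (a/p) * d`` is unbiased over random grid/section offsets.

Optical fractionator: neurons are counted with unique-point dissectors in
counting frames laid out on a sampling grid within systematically sampled
sections; ``N = sum(Q-) / (ssf * asf * tsf)`` where ssf, asf and tsf are
the section, area and thickness sampling fractions. The study design uses
a 65 x 35 um frame, 200 x 200 um (cortex) or 400 x 400 um (striatum)
grids, 50 um sections with a 450 um gap (ssf = 1/10), 18 um measured
thickness and 0.5 um guard zones (17 um dissector height).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .types import ConfigurationError, InsufficientDataError
from .synthetic.config import HistoGroundTruth


@dataclass(frozen=True)
class CavalieriDesign:
    """Point-counting design: area per point (um^2), section period (um),
    per-section point counts."""

    area_per_point_um2: float
    section_period_um: float
    point_counts: tuple[int, ...] = ()

    def __post_init__(self):
        if self.area_per_point_um2 <= 0 or self.section_period_um <= 0:
            raise ConfigurationError("a/p and section period must be positive")
        if any(c < 0 for c in self.point_counts):
            raise ConfigurationError("point counts must be non-negative")


@dataclass(frozen=True)
class FractionatorDesign:
    """Optical-fractionator sampling fractions and counting geometry (um)."""

    section_sampling_fraction: float
    frame_size_um: tuple[float, float]
    grid_size_um: tuple[float, float]
    section_thickness_um: float
    guard_zone_um: float

    def __post_init__(self):
        for f in (self.section_sampling_fraction, self.area_sampling_fraction,
                  self.thickness_sampling_fraction):
            if not 0.0 < f <= 1.0:
                raise ConfigurationError("sampling fractions must lie in (0, 1]")

    @property
    def area_sampling_fraction(self) -> float:
        fa = self.frame_size_um[0] * self.frame_size_um[1]
        ga = self.grid_size_um[0] * self.grid_size_um[1]
        return fa / ga

    @property
    def dissector_height_um(self) -> float:
        return dissector_height(self.section_thickness_um, self.guard_zone_um)

    @property
    def thickness_sampling_fraction(self) -> float:
        return self.dissector_height_um / self.section_thickness_um


def dissector_height(thickness_um: float, guard_um: float) -> float:
    """Optical dissector height = section thickness - 2 x guard zone."""
    if thickness_um <= 2 * guard_um:
        raise ConfigurationError("guard zones leave no dissector height")
    return thickness_um - 2.0 * guard_um


#: the study's striatal and cortical fractionator designs
STRIATUM_DESIGN = FractionatorDesign(0.1, (65.0, 35.0), (400.0, 400.0), 18.0, 0.5)
CORTEX_DESIGN = FractionatorDesign(0.1, (65.0, 35.0), (200.0, 200.0), 18.0, 0.5)


def cavalieri_volume(design: CavalieriDesign) -> float:
    """Cavalieri volume estimate in mm^3: sum(P) x a/p x d."""
    total = sum(design.point_counts)
    if len(design.point_counts) < 1:
        raise ConfigurationError("need at least one section with counts")
    if total == 0:
        warnings.warn("zero points counted: volume 0 with no precision",
                      RuntimeWarning)
    v_um3 = total * design.area_per_point_um2 * design.section_period_um
    return v_um3 * 1e-9


def optical_fractionator(design: FractionatorDesign, total_count: float) -> float:
    """Estimated particle number N = sum(Q-) / (ssf * asf * tsf)."""
    if total_count < 0:
        raise ConfigurationError("counted particles must be non-negative")
    return (total_count
            / design.section_sampling_fraction
            / design.area_sampling_fraction
            / design.thickness_sampling_fraction)


def gundersen_ce(point_counts, smoothness: int = 1) -> float:
    """Gundersen-Jensen coefficient of error for systematic sections.

    With per-section counts p_i, A = sum p_i^2, B = sum p_i p_{i+1},
    C = sum p_i p_{i+2} and noise = sum p_i (Poisson point noise), the
    m = 1 systematic variance is ``(3(A - noise) - 4B + C) / 240``
    (floored at 0, since a negative estimate just means the systematic
    component is indistinguishable from point noise) and
    ``CE = sqrt(noise + var_sys) / sum p_i``. Constant count sequences of
    modest counts hit the floor and give the pure Poisson-noise CE.
    """
    p = np.asarray(point_counts, float)
    if p.size < 3:
        raise InsufficientDataError("Gundersen CE needs at least 3 sections")
    if smoothness != 1:
        raise ConfigurationError("only the m=1 smoothness class is implemented")
    total = p.sum()
    if total == 0:
        return float("inf")
    noise = total
    A = float((p * p).sum())
    B = float((p[:-1] * p[1:]).sum())
    C = float((p[:-2] * p[2:]).sum())
    var_sys = max(0.0, (3.0 * (A - noise) - 4.0 * B + C) / 240.0)
    return math.sqrt(noise + var_sys) / total


# ---------------------------------------------------------------------------
# sampling simulators: apply a design to known ground truth


def sample_cavalieri_ellipsoid(
    semiaxes_um,
    design: CavalieriDesign,
    rng: np.random.Generator,
) -> CavalieriDesign:
    """Point-count an analytic ellipsoid with random grid/section offsets.

    Sections are planes z = z0 + k*d (z0 uniform in [0, d)); on each
    section a square point grid of spacing sqrt(a/p) with a uniform random
    offset is counted inside the elliptical cross-section. Returns a copy
    of the design carrying the per-section counts.
    """
    az, ay, ax = semiaxes_um
    d = design.section_period_um
    s = math.sqrt(design.area_per_point_um2)
    z0 = rng.uniform(0.0, d) - az
    oy = rng.uniform(0.0, s)
    ox = rng.uniform(0.0, s)
    counts = []
    z = z0
    while z <= az:
        w2 = 1.0 - (z / az) ** 2
        if w2 <= 0:
            counts.append(0)
            z += d
            continue
        by, bx = ay * math.sqrt(w2), ax * math.sqrt(w2)
        iy = np.arange(math.ceil((-by - oy) / s), math.floor((by - oy) / s) + 1)
        gy = oy + iy * s
        # for each grid row, count columns inside the ellipse
        inside2 = 1.0 - (gy / by) ** 2
        ok = inside2 > 0
        half = bx * np.sqrt(np.clip(inside2, 0, None))
        lo = np.ceil((-half - ox) / s)
        hi = np.floor((half - ox) / s)
        counts.append(int(np.sum((hi - lo + 1)[ok].clip(min=0))))
        z += d
    from dataclasses import replace
    return replace(design, point_counts=tuple(counts))


def sample_fractionator_counts(
    truth: HistoGroundTruth,
    design: FractionatorDesign,
    rng: np.random.Generator,
) -> tuple[int, np.ndarray]:
    """Apply the fractionator design to a synthetic section stack.

    Sections are sampled with period round(1/ssf) from a random start;
    counting frames tile each sampled section with the grid period and a
    uniform random offset; a neuron is counted when its unique point falls
    in a frame (half-open bounds, the unbiased-frame point rule) and its
    depth lies inside the optical dissector (between the guard zones).
    Returns (sum Q-, per-sampled-section counts).
    """
    period = int(round(1.0 / design.section_sampling_fraction))
    start = int(rng.integers(0, period))
    oy = rng.uniform(0.0, design.grid_size_um[0])
    ox = rng.uniform(0.0, design.grid_size_um[1])
    gy, gx = design.grid_size_um
    fy, fx = design.frame_size_um
    guard = design.guard_zone_um
    h = design.dissector_height_um

    coords = truth.neuron_coords
    per_section = []
    for sec in range(start, truth.n_sections, period):
        sel = coords[coords[:, 0] == sec]
        if sel.size == 0:
            per_section.append(0)
            continue
        z, y, x = sel[:, 1], sel[:, 2], sel[:, 3]
        in_dissector = (z >= guard) & (z < guard + h)
        in_frame = (((y - oy) % gy) < fy) & (((x - ox) % gx) < fx)
        per_section.append(int(np.sum(in_dissector & in_frame)))
    return int(np.sum(per_section)), np.asarray(per_section)
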