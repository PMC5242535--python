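"""Threshold-based immunoreactivity quantification and cortical thickness.

Staining is quantified on a 0-255 pixel scale. Two conventions exist for
which end is "stained": the transmitted-light reading used by default here
(``dark_low``: stained pixels transmit less light and take LOW values, so
a threshold admits pixels <= threshold) and the literal optical-density
reading (``dark_high``: stained pixels take HIGH values, threshold admits
pixels >= threshold). The two-level scheme measures dense nuclear
inclusions at threshold 90 and total aggregated staining (nuclear plus
extra-nuclear) at 130; under the default orientation the nuclear mask is a
subset of the total mask, and an orientation that breaks that subset
relation on a calibration image raises an error.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ConfigurationError, SectionImage


@dataclass(frozen=True)
class ThresholdPair:
    """Nuclear / total darkness thresholds with the scale orientation."""

    nuclear: float = 90.0
    total: float = 130.0
    orientation: str = "dark_low"  # or "dark_high" (literal printed scale)

    def __post_init__(self):
        if self.orientation not in ("dark_low", "dark_high"):
            raise ConfigurationError("orientation must be dark_low or dark_high")


def _stain_mask(img: np.ndarray, threshold: float, orientation: str) -> np.ndarray:
    if orientation == "dark_low":
        return img <= threshold
    return img >= threshold


def immunoreactive_area(
    image: SectionImage | np.ndarray,
    threshold: float,
    orientation: str = "dark_low",
) -> float:
    """Percent of the field of view passing the stain threshold."""
    data = np.asarray(getattr(image, "data", image))
    if data.size == 0:
        raise ConfigurationError("empty image")
    return 100.0 * float(_stain_mask(data, threshold, orientation).mean())


def two_level_quantification(
    image: SectionImage | np.ndarray,
    pair: ThresholdPair = ThresholdPair(),
) -> dict[str, float]:
    """Nuclear-inclusion and total-aggregate percent area per FOV.

    Raises ``ConfigurationError`` when the chosen orientation makes the
    nuclear mask exceed the total mask (nuclear staining is by definition
    a subset of total staining).
    """
    data = np.asarray(getattr(image, "data", image))
    nuc = _stain_mask(data, pair.nuclear, pair.orientation)
    tot = _stain_mask(data, pair.total, pair.orientation)
    if np.any(nuc & ~tot):
        raise ConfigurationError(
            "orientation leaves nuclear mask outside the total mask; "
            "thresholds and orientation are inconsistent")
    return {"nuclear_pct": 100.0 * float(nuc.mean()),
            "total_pct": 100.0 * float(tot.mean())}


def tiled_quantification(
    image: SectionImage | np.ndarray,
    pair: ThresholdPair = ThresholdPair(),
    tile: tuple[int, int] | None = None,
) -> list[dict[str, float]]:
    """Per-tile two-level percentages (fixed-size non-overlapping FOVs)."""
    data = np.asarray(getattr(image, "data", image))
    if tile is None:
        return [two_level_quantification(data, pair)]
    ty, tx = tile
    out = []
    for y0 in range(0, data.shape[0] - ty + 1, ty):
        for x0 in range(0, data.shape[1] - tx + 1, tx):
            out.append(two_level_quantification(data[y0:y0 + ty, x0:x0 + tx], pair))
    return out


@dataclass(frozen=True)
class ThicknessRuler:
    """Vertical-line cortical thickness design: measurement lines dropped
    from an inner boundary (dorsal corpus-callosum horn) to the outer
    (pial) boundary, averaged over consecutive sections."""

    n_lines: int = 10
    n_sections: int = 3

    def __post_init__(self):
        if self.n_lines < 1:
            raise ConfigurationError("need at least one measurement line")


def cortical_thickness(
    inner_boundary_um,
    outer_boundary_um,
    ruler: ThicknessRuler = ThicknessRuler(),
) -> tuple[float, int]:
    """Mean vertical distance between two boundary polylines.

    Boundaries are given as ``(x_um, y_um)`` sampled polylines (functions
    of x). ``ruler.n_lines`` vertical lines are spread evenly across the
    overlapping x-range; each line's segment length is the outer minus the
    inner boundary height at that x (linear interpolation). Lines where a
    boundary is missing or the segment is degenerate are excluded with a
    warning; returns ``(mean_length_um, n_excluded)``.
    """
    import warnings

    inner = np.asarray(inner_boundary_um, float)
    outer = np.asarray(outer_boundary_um, float)
    if inner.ndim != 2 or outer.ndim != 2:
        raise ConfigurationError("boundaries must be (n, 2) polylines")
    x_lo = max(inner[:, 0].min(), outer[:, 0].min())
    x_hi = min(inner[:, 0].max(), outer[:, 0].max())
    if x_hi <= x_lo:
        raise ConfigurationError("boundaries do not overlap in x")
    xs = np.linspace(x_lo, x_hi, ruler.n_lines + 2)[1:-1]
    yi = np.interp(xs, inner[:, 0], inner[:, 1])
    yo = np.interp(xs, outer[:, 0], outer[:, 1])
    lengths = yo - yi
    ok = lengths > 0
    if not np.all(ok):
        warnings.warn(f"{int((~ok).sum())} lines failed to span both boundaries",
                      RuntimeWarning)
    if not ok.any():
        raise ConfigurationError("no measurement line intersects both boundaries")
    return float(lengths[ok].mean()), int((~ok).sum())


def mean_thickness_over_sections(per_section_boundaries, ruler=ThicknessRuler()):
    """Mean thickness over consecutive sections: iterable of
    (inner, outer) polyline pairs -> mean of per-section means (um)."""
    means = [cortical_thickness(i, o, ruler)[0] for i, o in per_section_boundaries]
    return float(np.mean(means))
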