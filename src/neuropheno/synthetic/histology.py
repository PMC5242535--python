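"""Synthetic histology sections with exact ground truth.

Sections emulate DAB-stained material: a light background, neuron somata
(NeuN-like disks) and aggregate inclusions in two darkness classes
(dense nuclear vs diffuse). Pixel values use the transmitted-light
convention of the quantification stage: value = 255 - darkness, so darker
stain means a LOWER pixel value. Ground truth (coordinates, class masks)
is attached to every image.
"""
from __future__ import annotations

import numpy as np

from ..types import ConfigurationError, SectionImage
from .config import HistoGroundTruth


def random_histo_truth(
    n_sections: int,
    neurons_per_section: int,
    section_size_um: tuple[float, float] = (1000.0, 1000.0),
    section_thickness_um: float = 18.0,
    inclusions_per_section: int = 0,
    nuclear_fraction: float = 0.5,
    seed: int = 0,
    neuron_radius_um: float = 5.0,
    inclusion_radius_um: float = 3.0,
    non_overlapping: bool = True,
    margin_um: float | None = None,
) -> HistoGroundTruth:
    """Uniformly place neurons (and inclusion blobs) in a section stack."""
    rng = np.random.default_rng(seed)
    # default margin keeps painted disks strictly inside the raster even
    # after pixel rounding at typical (<= 3 um) pixel sizes
    margin = 1.2 * neuron_radius_um + 3.0 if margin_um is None else margin_um

    def _place(n_per_sec, radius):
        coords = []
        for sec in range(n_sections):
            placed: list[tuple[float, float]] = []
            tries = 0
            while len(placed) < n_per_sec:
                y = rng.uniform(margin, section_size_um[0] - margin)
                x = rng.uniform(margin, section_size_um[1] - margin)
                if non_overlapping and any(
                        (y - py) ** 2 + (x - px) ** 2 < (2.2 * radius) ** 2
                        for py, px in placed):
                    tries += 1
                    if tries > 200 * n_per_sec:
                        raise ConfigurationError(
                            "cannot place non-overlapping objects at this density")
                    continue
                placed.append((y, x))
                z = rng.uniform(0.0, section_thickness_um)
                coords.append((sec, z, y, x))
        return np.asarray(coords, dtype=float).reshape(-1, 4)

    neuron_coords = _place(neurons_per_section, neuron_radius_um)
    inclusion_coords = _place(inclusions_per_section, inclusion_radius_um)
    classes = np.array(
        ["nuclear" if rng.random() < nuclear_fraction else "diffuse"
         for _ in range(len(inclusion_coords))], dtype=object)
    return HistoGroundTruth(
        n_sections=n_sections,
        section_thickness_um=section_thickness_um,
        section_size_um=section_size_um,
        neuron_coords=neuron_coords,
        neuron_radius_um=neuron_radius_um,
        inclusion_coords=inclusion_coords,
        inclusion_classes=classes,
        inclusion_radius_um=inclusion_radius_um,
    )


def _paint_disks(darkmap, coords_px, radius_px, level):
    h, w = darkmap.shape
    for cy, cx in coords_px:
        y0, y1 = int(np.floor(cy - radius_px)), int(np.ceil(cy + radius_px)) + 1
        x0, x1 = int(np.floor(cx - radius_px)), int(np.ceil(cx + radius_px)) + 1
        if y0 < 0 or x0 < 0 or y1 > h or x1 > w:
            raise ConfigurationError("object extends outside the section image")
        yy, xx = np.mgrid[y0:y1, x0:x1]
        m = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2
        region = darkmap[y0:y1, x0:x1]
        region[m] = np.maximum(region[m], level)


def generate_sections(
    truth: HistoGroundTruth,
    pixel_size_um: float = 2.0,
    seed: int | None = None,
) -> list[SectionImage]:
    """Render each section of the stack to a SectionImage.

    The rendered darkness levels are exactly the configured class levels
    (darkest class wins where blobs touch), so pixel histograms have modes
    at those levels and the attached annotations equal the painted masks.
    """
    if truth.neuron_radius_um < pixel_size_um:
        raise ConfigurationError("blob radii must be at least one pixel")
    h = int(round(truth.section_size_um[0] / pixel_size_um))
    w = int(round(truth.section_size_um[1] / pixel_size_um))
    images = []
    for sec in range(truth.n_sections):
        dark = np.full((h, w), truth.darkness["background"], dtype=np.int16)
        ann: dict = {"section": sec, "neurons": [], "inclusions": []}

        n_sel = truth.neuron_coords[truth.neuron_coords[:, 0] == sec]
        n_px = [(c[2] / pixel_size_um, c[3] / pixel_size_um) for c in n_sel]
        _paint_disks(dark, n_px, truth.neuron_radius_um / pixel_size_um,
                     truth.darkness["neuron"])
        ann["neurons"] = n_sel.copy()

        for cls in ("diffuse", "nuclear"):  # nuclear painted last (darker)
            sel = truth.inclusion_coords[
                (truth.inclusion_classes == cls)
                & (truth.inclusion_coords[:, 0] == sec)]
            px = [(c[2] / pixel_size_um, c[3] / pixel_size_um) for c in sel]
            before = dark.copy()
            _paint_disks(dark, px, truth.inclusion_radius_um / pixel_size_um,
                         truth.darkness[cls])
            ann[f"{cls}_mask"] = dark != before
            ann["inclusions"].append((cls, sel.copy()))

        value = (255 - dark).astype(np.uint8)  # transmitted light: dark = low
        ann["darkness"] = dict(truth.darkness)
        images.append(SectionImage(
            data=value, pixel_size_um=pixel_size_um, annotations=ann))
    return images
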