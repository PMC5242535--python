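"""Core containers shared across the pipeline.

Axis convention (used everywhere in this package): voxel indices are
0-based, arrays are ordered ``(z, y, x)`` (or ``(y, x)`` in 2-D), and world
coordinates are ``index * spacing`` in millimetres.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


class ConfigurationError(ValueError):
    """A generator or design configuration is internally inconsistent."""


class DegenerateRegionError(ConfigurationError):
    """A region's target volume fell below a single voxel."""


class RegionLookupError(KeyError):
    """A requested region is not present in a label volume."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


class SolverError(RuntimeError):
    """An iterative solver diverged; carries its iteration trace."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class LabelVolume:
    """Integer region-label grid with physical voxel spacing.

    ``labels`` maps region name -> label integer; background is 0.
    ``composites`` maps a derived region name to the set of names whose
    union it denotes (e.g. ``whole_brain``).
    """

    data: np.ndarray
    spacing: tuple[float, ...]
    labels: Mapping[str, int]
    composites: Mapping[str, Sequence[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError("voxel spacing must be strictly positive")
        if len(self.spacing) != self.data.ndim:
            raise ConfigurationError("spacing length must match array rank")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (mm^2 in 2-D)."""
        return float(np.prod(self.spacing))

    def region_names(self):
        return list(self.labels) + list(self.composites)

    def region_mask(self, region: str) -> np.ndarray:
        """Boolean mask of a named region (composites are unions)."""
        if region in self.composites:
            ids = [self.labels[name] for name in self.composites[region]]
            return np.isin(self.data, ids)
        if region not in self.labels:
            raise RegionLookupError(region)
        return self.data == self.labels[region]


@dataclass
class MultiEchoImage:
    """4-D multi-echo stack ordered (echo, z, y, x) with echo times in ms."""

    data: np.ndarray
    echo_times: np.ndarray
    spacing: tuple[float, ...]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.data.shape[0] != self.echo_times.size:
            raise ConfigurationError("echo axis length must match echo_times")
        if np.any(np.diff(self.echo_times) <= 0) or np.any(self.echo_times <= 0):
            raise ConfigurationError("echo times must be positive and strictly increasing")

    @property
    def n_echoes(self) -> int:
        return int(self.echo_times.size)


@dataclass
class SectionImage:
    """2-D grayscale stain image on a 0-255 scale with known pixel size (um).

    ``annotations`` carries the rendered ground truth (object coordinates,
    class masks) when the image came from the synthetic generator.
    """

    data: np.ndarray
    pixel_size_um: float
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ConfigurationError("section image must be non-empty 2-D")
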