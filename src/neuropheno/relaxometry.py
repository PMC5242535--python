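"""Multi-echo T2 relaxometry.

A multi-echo spin-echo stack decays mono-exponentially,
``S(TE) = S0 * exp(-TE/T2)``, at each voxel. This module sums echoes into
a structural image, fits per-voxel (S0, T2) maps, extracts ROI mean T2
(with the cheek-muscle region serving as an internal control), and checks
protocol-derived geometry/timing arithmetic.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .types import ConfigurationError, MultiEchoImage, LabelVolume, RegionLookupError

#: T2 values outside this window (ms) are flagged invalid (background and
#: divergent fits), never silently zeroed.
T2_VALID_RANGE = (1.0, 2000.0)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Multi-echo multi-slice protocol parameters."""

    tr_ms: float
    first_te_ms: float
    n_echoes: int
    averages: int
    matrix: tuple[int, int]  # (phase, read)
    fov_mm: tuple[float, float]
    n_slices: int = 30
    slice_thickness_mm: float = 0.5

    def __post_init__(self):
        vals = (self.tr_ms, self.first_te_ms, self.n_echoes, self.averages,
                *self.matrix, *self.fov_mm, self.n_slices, self.slice_thickness_mm)
        if any(v <= 0 for v in vals):
            raise ConfigurationError("all protocol parameters must be positive")

    @property
    def echo_times_ms(self) -> np.ndarray:
        return self.first_te_ms * np.arange(1, self.n_echoes + 1, dtype=float)


#: the study's in vivo and ex vivo MEMS protocols
IN_VIVO_PROTOCOL = AcquisitionProtocol(
    tr_ms=2500, first_te_ms=10, n_echoes=8, averages=4,
    matrix=(128, 128), fov_mm=(20.0, 20.0), n_slices=30)
EX_VIVO_PROTOCOL = AcquisitionProtocol(
    tr_ms=3000, first_te_ms=10, n_echoes=8, averages=22,
    matrix=(192, 192), fov_mm=(19.2, 19.2), n_slices=35)


@dataclass
class T2Map:
    """Per-voxel T2 (ms) and S0 with a per-voxel validity flag."""

    t2_ms: np.ndarray
    s0: np.ndarray
    valid: np.ndarray
    spacing: tuple[float, ...] = field(default_factory=tuple)


def sum_echoes(img: MultiEchoImage) -> np.ndarray:
    """Sum all echoes into a single structural image (shape preserved)."""
    if img.n_echoes < 1:
        raise ConfigurationError("need at least one echo")
    return img.data.sum(axis=0)


def fit_t2_map(img: MultiEchoImage, echo_times=None) -> T2Map:
    """Per-voxel mono-exponential fit by log-linear least squares.

    Exact on noiseless data. Voxels with any non-positive signal, or a
    fitted T2 outside ``T2_VALID_RANGE``, are flagged invalid (their fitted
    values are retained, never silently zeroed). An all-invalid map emits
    a warning rather than failing.
    """
    te = np.asarray(img.echo_times if echo_times is None else echo_times, float)
    if te.size < 2:
        raise ConfigurationError("need at least two echoes to fit T2")
    data = img.data
    positive = np.all(data > 0, axis=0)
    safe = np.where(data > 0, data, 1.0)
    logs = np.log(safe)
    # least squares for log S = log S0 - TE/T2
    te_c = te - te.mean()
    denom = float((te_c**2).sum())
    slope = np.tensordot(te_c, logs, axes=(0, 0)) / denom
    intercept = logs.mean(axis=0) - slope * te.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = np.where(slope < 0, -1.0 / slope, np.inf)
    s0 = np.exp(intercept)
    valid = positive & (t2 > T2_VALID_RANGE[0]) & (t2 < T2_VALID_RANGE[1])
    if not valid.any():
        warnings.warn("T2 fit produced no valid voxels", RuntimeWarning)
    return T2Map(t2_ms=t2, s0=s0, valid=valid, spacing=tuple(img.spacing))


def refine_t2_map(img: MultiEchoImage, t2map: T2Map, n_iter: int = 3) -> T2Map:
    """Optional Gauss-Newton refinement of the log-linear fit in the
    signal domain (reduces the noise-floor bias of log-domain fitting)."""
    te = img.echo_times
    t2 = t2map.t2_ms.copy()
    s0 = t2map.s0.copy()
    v = t2map.valid
    y = img.data[:, v]
    t2v, s0v = t2[v], s0[v]
    for _ in range(n_iter):
        model = s0v[None] * np.exp(-te[:, None] / t2v[None])
        r = y - model
        d_s0 = model / s0v[None]
        d_t2 = model * (te[:, None] / t2v[None] ** 2)
        a11 = (d_s0 * d_s0).sum(0)
        a12 = (d_s0 * d_t2).sum(0)
        a22 = (d_t2 * d_t2).sum(0)
        b1 = (d_s0 * r).sum(0)
        b2 = (d_t2 * r).sum(0)
        det = a11 * a22 - a12**2
        det = np.where(np.abs(det) < 1e-30, 1e-30, det)
        s0v = s0v + (a22 * b1 - a12 * b2) / det
        t2v = np.clip(t2v + (a11 * b2 - a12 * b1) / det, 0.5, 4000.0)
    t2[v], s0[v] = t2v, s0v
    valid = v & (t2 > T2_VALID_RANGE[0]) & (t2 < T2_VALID_RANGE[1])
    return T2Map(t2_ms=t2, s0=s0, valid=valid, spacing=t2map.spacing)


def roi_mean_t2(t2map: T2Map, labels: LabelVolume, region: str):
    """Mean T2 (ms) over the valid voxels of a region.

    Returns ``(mean_ms, n_excluded)`` where ``n_excluded`` counts region
    voxels dropped by the fit-validity flag.
    """
    mask = labels.region_mask(region)  # raises RegionLookupError if absent
    if not mask.any():
        raise RegionLookupError(region)
    usable = mask & t2map.valid
    n_excluded = int(mask.sum() - usable.sum())
    if not usable.any():
        return float("nan"), n_excluded
    return float(t2map.t2_ms[usable].mean()), n_excluded


def planned_geometry(p: AcquisitionProtocol) -> dict:
    """Protocol-derived geometry and timing.

    In-plane resolution is FOV/matrix per axis (reported rounded to the
    nearest micrometre); nominal scan time is TR x phase-encode steps x
    averages (reported in seconds, with a minutes rounding helper).
    """
    res_um = tuple(fov / n * 1000.0 for fov, n in zip(p.fov_mm, p.matrix))
    scan_s = p.tr_ms / 1000.0 * p.matrix[0] * p.averages
    return {
        "in_plane_resolution_um": tuple(int(round(r)) for r in res_um),
        "scan_time_s": scan_s,
        "scan_time_min": int(round(scan_s / 60.0)),
    }
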