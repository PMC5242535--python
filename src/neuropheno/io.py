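"""File I/O: NIfTI volumes and fields, TIFF sections, CSV tables, JSON sidecars.

Arrays follow the package's (z, y, x) axis order; NIfTI affines are
diagonal with the spacing reversed to (x, y, z) as nibabel expects.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .types import LabelVolume, MultiEchoImage, SectionImage


def _affine(spacing) -> np.ndarray:
    s = list(spacing[::-1]) + [1.0] * max(0, 3 - len(spacing))
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = s[:3]
    return aff


def save_label_volume(vol: LabelVolume, path) -> None:
    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.int16), _affine(vol.spacing))
    nib.save(img, path)
    sidecar = {"labels": dict(vol.labels),
               "composites": {k: list(v) for k, v in vol.composites.items()},
               "spacing_mm": list(vol.spacing)}
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_label_volume(path) -> LabelVolume:
    path = Path(path)
    img = nib.load(path)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    return LabelVolume(
        data=np.asarray(img.dataobj, dtype=np.int16),
        spacing=tuple(meta["spacing_mm"]),
        labels=meta["labels"],
        composites={k: tuple(v) for k, v in meta.get("composites", {}).items()},
    )


def save_multiecho(img: MultiEchoImage, path) -> None:
    """Write a 4-D NIfTI with echoes on the last axis and a JSON sidecar
    with the echo times."""
    path = Path(path)
    data = np.moveaxis(img.data, 0, -1)
    nib.save(nib.Nifti1Image(data.astype(np.float32), _affine(img.spacing)), path)
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps({"echo_times_ms": img.echo_times.tolist(),
                    "spacing_mm": list(img.spacing)}))


def load_multiecho(path) -> MultiEchoImage:
    path = Path(path)
    img = nib.load(path)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    return MultiEchoImage(data=data, echo_times=np.array(meta["echo_times_ms"]),
                          spacing=tuple(meta["spacing_mm"]))


def save_map(data: np.ndarray, spacing, path) -> None:
    """Write a scalar map (T2, t, p, q, Jacobian, mask) as NIfTI."""
    nib.save(nib.Nifti1Image(np.asarray(data, np.float32), _affine(spacing)), path)


def save_displacement_field(field, path) -> None:
    """Write a displacement field as 4-D vector NIfTI (components last)."""
    disp = np.moveaxis(np.asarray(field.disp, np.float32), 0, -1)
    spacing = field.spacing or (1.0,) * (disp.ndim - 1)
    nib.save(nib.Nifti1Image(disp, _affine(spacing)), path)


def save_section(section: SectionImage, path) -> None:
    tifffile.imwrite(Path(path), section.data,
                     resolution=(1e4 / section.pixel_size_um,
                                 1e4 / section.pixel_size_um))


def load_section(path, pixel_size_um: float) -> SectionImage:
    return SectionImage(data=tifffile.imread(Path(path)),
                        pixel_size_um=pixel_size_um)
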