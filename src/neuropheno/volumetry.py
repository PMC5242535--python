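"""ROI volumetry: region volumes, longitudinal trajectories, and
percent-change / genotype-gap summaries.

Volumes are voxel count x voxel volume on label volumes (phantom labels
are exact, so no partial-volume handling is attempted). Missing ages are
never interpolated: summaries use available data only.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .types import InsufficientDataError, LabelVolume, RegionLookupError


def roi_volume(labels: LabelVolume, region: str) -> float:
    """Region volume in mm^3 = voxel count x voxel volume."""
    mask = labels.region_mask(region)
    return float(mask.sum()) * labels.voxel_volume


def percent_change(series, from_age: float, to_age: float) -> float:
    """Signed percent change 100 * (V_to - V_from) / V_from.

    ``series`` maps age (weeks) to volume; both endpoints must be present.
    """
    series = dict(series)
    for age in (from_age, to_age):
        if age not in series:
            raise InsufficientDataError(f"age {age} not present in the series")
    v0, v1 = series[from_age], series[to_age]
    return 100.0 * (v1 - v0) / v0


def mean_trajectory(
    volumes: pd.DataFrame, region: str, genotype: str, sex: str | None = None
) -> dict[float, float]:
    """Group-mean volume at each age for one region x genotype (optionally
    one sex; sexes pooled by default)."""
    sel = (volumes["region"] == region) & (volumes["genotype"] == genotype)
    if sex is not None:
        sel &= volumes["sex"] == sex
    sub = volumes[sel]
    if sub.empty:
        raise InsufficientDataError(f"no data for {region}/{genotype}/{sex}")
    return sub.groupby("age_weeks")["volume_mm3"].mean().to_dict()


def peak_age(trajectory: dict[float, float]) -> float:
    """Age of the trajectory maximum (argmax of the group-mean curve)."""
    return max(trajectory, key=trajectory.get)


def peak_to_final_change(
    volumes: pd.DataFrame, region: str, genotype: str, sex: str | None = None
) -> float:
    """Percent change from the trajectory peak to the last observed age."""
    traj = mean_trajectory(volumes, region, genotype, sex)
    final = max(traj)
    return percent_change(traj, peak_age(traj), final)


def genotype_gap(
    volumes: pd.DataFrame, region: str, age: float,
    reference: str = "WT", contrast: str = "HdhQ150", sex: str | None = None,
) -> float:
    """Percent volume gap 100 * (mean_ref - mean_contrast) / mean_ref at an age."""
    sel = (volumes["region"] == region) & (volumes["age_weeks"] == age)
    if sex is not None:
        sel &= volumes["sex"] == sex
    sub = volumes[sel]
    means = sub.groupby("genotype")["volume_mm3"].mean()
    for g in (reference, contrast):
        if g not in means.index or sub[sub["genotype"] == g].empty:
            raise InsufficientDataError(f"no {g} observations at age {age}")
    return float(100.0 * (means[reference] - means[contrast]) / means[reference])


def behavior_gap(
    table: pd.DataFrame, measure: str, age: float, sex: str,
    reference: str = "WT", contrast: str = "HdhQ150",
) -> float:
    """Percent deficit 100 * (mean_ref - mean_contrast) / mean_ref for a
    behavioural measure at one age within one sex (missing values and
    flagged observations excluded)."""
    sel = ((table["measure"] == measure) & (table["age_weeks"] == age)
           & (table["sex"] == sex) & (~table["missing"]))
    sub = table[sel].dropna(subset=["value"])
    means = sub.groupby("genotype")["value"].mean()
    for g in (reference, contrast):
        if g not in means.index:
            raise InsufficientDataError(f"no {g} observations at age {age}")
    return float(100.0 * (means[reference] - means[contrast]) / means[reference])
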