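"""Configuration objects for the synthetic study generator.

The generator emulates a longitudinal knock-in Huntington's-disease mouse
cohort: two genotypes (WT, HdhQ150) x two sexes, imaged at seven ages from
8 to 94 weeks. Regional brain volumes follow a growth-then-atrophy
trajectory -- a logistic rise to a genotype-dependent plateau, a flat
segment, then (for disease-affected regions in HdhQ150) a linear decline.
Behavioural measures follow age curves with genotype x sex deficits.

Default effect sizes are the study conditions: peak-to-final declines of
27% (striatum), 12% (cortex) and 21% (hippocampus) in HdhQ150, and
final-age locomotor deficits of 34% (males) and 39% (females). Absolute
regional volumes are not published; the defaults below are
order-of-magnitude plausible for adult mouse and otherwise arbitrary.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml

from ..types import ConfigurationError

#: the seven imaging ages (weeks)
IMAGING_AGES = (8, 15, 23, 36, 52, 70, 94)

GENOTYPES = ("WT", "HdhQ150")
SEXES = ("M", "F")

BEHAVIOR_MEASURES = (
    "locomotor_distance",
    "grip_strength",
    "rotarod_latency",
    "tmaze_correct",
    "odor_discrimination",
    "social_interaction",
)


def tmaze_criterion_percent(correct: int = 10, trials: int = 12) -> float:
    """Swimming T-maze learning criterion as a percent-correct rate.

    The criterion is 10 correct choices out of 12 successive trials,
    i.e. 83.3% correct (reported to one decimal place).
    """
    return round(100.0 * correct / trials, 1)


@dataclass(frozen=True)
class RegionSpec:
    """Analytic ellipsoid region: center offset (mm, z/y/x from grid center)
    and reference semi-axes (mm) whose analytic volume anchors scaling."""

    name: str
    label: int
    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]

    @property
    def reference_volume(self) -> float:
        a, b, c = self.semiaxes_mm
        return 4.0 / 3.0 * math.pi * a * b * c


@dataclass(frozen=True)
class PhantomSpec:
    """Grid geometry plus the analytic region set of the brain phantom."""

    shape: tuple[int, int, int] = (64, 96, 64)
    spacing: tuple[float, float, float] = (0.5, 0.15625, 0.15625)
    regions: tuple[RegionSpec, ...] = ()

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError("voxel spacing must be strictly positive")

    def region(self, name: str) -> RegionSpec:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


#: region labels; ``brain_shell`` is brain tissue not in a named subregion
DEFAULT_REGIONS = (
    RegionSpec("brain", 1, (0.0, 0.0, 0.0), (4.0, 6.5, 4.5)),
    RegionSpec("cortex", 2, (-2.1, 0.0, 0.0), (1.25, 4.8, 3.38)),
    RegionSpec("striatum", 3, (0.8, 1.3, 0.0), (1.35, 2.05, 1.81)),
    RegionSpec("hippocampus", 4, (0.5, -2.9, 0.0), (1.2, 2.0, 2.19)),
    RegionSpec("corpus_callosum", 5, (2.75, 0.0, 0.0), (0.45, 2.6, 2.04)),
    RegionSpec("ventricles", 6, (-0.1, 1.3, 3.2), (0.55, 1.8, 0.965)),
    RegionSpec("muscle", 7, (6.5, 0.0, 0.0), (0.95, 2.9, 2.6)),
)

#: names whose label is carved out of the brain ellipsoid
BRAIN_SUBREGIONS = ("cortex", "striatum", "hippocampus", "corpus_callosum", "ventricles")

COMPOSITE_REGIONS = {
    "whole_brain": ("brain_shell",) + BRAIN_SUBREGIONS,
}


def default_phantom_spec() -> PhantomSpec:
    return PhantomSpec(regions=DEFAULT_REGIONS)


@dataclass(frozen=True)
class VolumeTrajectory:
    """Growth-then-atrophy volume model for one region x genotype.

    volume_8wk / plateau_volume in mm^3; ages in weeks. The curve rises
    logistically from the 8-week volume to the plateau at ``plateau_age``,
    stays flat until ``decline_onset``, then declines linearly so that the
    94-week volume equals ``plateau_volume * (1 - decline_fraction)``.
    """

    volume_8wk: float
    plateau_volume: float
    plateau_age: float = 36.0
    decline_onset: float = 94.0
    decline_fraction: float = 0.0

    def __post_init__(self):
        if self.volume_8wk <= 0 or self.plateau_volume <= 0:
            raise ConfigurationError("volumes must be positive at all ages")
        if not 0.0 <= self.decline_fraction < 1.0:
            raise ConfigurationError("decline fraction must lie in [0, 1)")
        if self.decline_onset < self.plateau_age:
            raise ConfigurationError("decline cannot start before the plateau")

    def volume_at(self, age_weeks: float) -> float:
        if not 8.0 <= age_weeks <= 94.0:
            raise ConfigurationError(f"age {age_weeks} outside the study window [8, 94]")
        t0, tp = 8.0, self.plateau_age
        if age_weeks >= self.decline_onset:
            frac = (age_weeks - self.decline_onset) / max(94.0 - self.decline_onset, 1e-9)
            return self.plateau_volume * (1.0 - self.decline_fraction * frac)
        if age_weeks >= tp or tp <= t0:
            return self.plateau_volume
        # logistic rise normalised to pass exactly through both endpoints
        tm = 0.5 * (t0 + tp)
        k = 9.2 / (tp - t0)  # sigma(+-4.6) ~ 0.01/0.99 at the endpoints
        s = 1.0 / (1.0 + math.exp(-k * (age_weeks - tm)))
        s0 = 1.0 / (1.0 + math.exp(-k * (t0 - tm)))
        s1 = 1.0 / (1.0 + math.exp(-k * (tp - tm)))
        w = (s - s0) / (s1 - s0)
        return self.volume_8wk + (self.plateau_volume - self.volume_8wk) * w


@dataclass(frozen=True)
class BehaviorCurve:
    """Age curve of a behavioural measure for the WT reference, plus the
    HdhQ150 deficit ramp: the deficit grows linearly from 0 at
    ``deficit_onset`` to ``final_deficit_fraction`` at 94 weeks."""

    value_8wk: float
    value_94wk: float
    final_deficit_fraction: float = 0.0
    deficit_onset: float = 36.0

    def wt_value(self, age_weeks: float) -> float:
        w = (age_weeks - 8.0) / (94.0 - 8.0)
        return self.value_8wk + (self.value_94wk - self.value_8wk) * w

    def deficit_at(self, age_weeks: float) -> float:
        if age_weeks <= self.deficit_onset or self.final_deficit_fraction == 0.0:
            return 0.0
        w = (age_weeks - self.deficit_onset) / (94.0 - self.deficit_onset)
        return self.final_deficit_fraction * min(w, 1.0)

    def value(self, genotype: str, age_weeks: float) -> float:
        v = self.wt_value(age_weeks)
        if genotype != "WT":
            v *= 1.0 - self.deficit_at(age_weeks)
        return v


@dataclass(frozen=True)
class TrajectoryConfig:
    """Per region x genotype volume trajectories, per measure x sex
    behaviour curves, sex scaling, and the nuisance rates (between-subject
    spread, measurement noise, missingness, outliers)."""

    volumes: Mapping[tuple[str, str], VolumeTrajectory] = field(default_factory=dict)
    behavior: Mapping[tuple[str, str], BehaviorCurve] = field(default_factory=dict)
    sex_volume_factor: Mapping[str, float] = field(
        default_factory=lambda: {"M": 1.0, "F": 0.92}
    )
    subject_cv: float = 0.03
    measurement_cv: float = 0.01
    behavior_subject_cv: float = 0.06
    behavior_measurement_cv: float = 0.05
    missing_rate: float = 0.05
    outlier_rate: float = 0.01
    outlier_sd: float = 4.0

    def volume_target(self, region: str, genotype: str, sex: str, age_weeks: float) -> float:
        traj = self.volumes[(region, genotype)]
        return traj.volume_at(age_weeks) * self.sex_volume_factor.get(sex, 1.0)

    def with_null_effects(self) -> "TrajectoryConfig":
        """Copy with every genotype effect removed (HD curves := WT curves)."""
        vols = {
            (region, gt): self.volumes[(region, "WT")]
            for (region, gt) in self.volumes
        }
        beh = {
            key: replace(curve, final_deficit_fraction=0.0)
            for key, curve in self.behavior.items()
        }
        return replace(self, volumes=vols, behavior=beh)


def default_trajectory_config(
    missing_rate: float = 0.05, outlier_rate: float = 0.01
) -> TrajectoryConfig:
    """The default study conditions.

    HdhQ150 region trajectories: striatum plateaus early (15 wk) and
    declines from 23 wk by 27%; cortex and hippocampus plateau at 23 wk and
    decline from 52 wk by 12% and 21%; corpus callosum declines from 15 wk;
    whole brain shows slow global atrophy from 23 wk. WT regions plateau at
    36 weeks and do not decline. Behaviour: locomotor deficit reaches 34%
    (males) / 39% (females) at the final age; motor measures decline from
    the 36-week clinical horizon; cognitive measures show no deficit.
    """
    V = VolumeTrajectory
    vols = {
        ("brain", "WT"): V(420.0, 470.0, 36.0),
        ("brain", "HdhQ150"): V(420.0, 445.0, 23.0, 23.0, 0.06),
        ("cortex", "WT"): V(72.0, 85.0, 36.0),
        ("cortex", "HdhQ150"): V(70.0, 74.4, 23.0, 52.0, 0.12),
        ("striatum", "WT"): V(17.0, 21.0, 36.0),
        ("striatum", "HdhQ150"): V(16.8, 18.9, 15.0, 23.0, 0.27),
        ("hippocampus", "WT"): V(18.0, 22.0, 36.0),
        ("hippocampus", "HdhQ150"): V(17.8, 19.8, 23.0, 52.0, 0.21),
        ("corpus_callosum", "WT"): V(8.0, 10.0, 36.0),
        ("corpus_callosum", "HdhQ150"): V(7.9, 9.0, 15.0, 15.0, 0.10),
        ("ventricles", "WT"): V(4.0, 4.0, 36.0),
        ("ventricles", "HdhQ150"): V(4.0, 4.4, 36.0),
        ("muscle", "WT"): V(30.0, 30.0, 36.0),
        ("muscle", "HdhQ150"): V(30.0, 30.0, 36.0),
    }
    B = BehaviorCurve
    beh = {}
    for sex, loco_def in (("M", 0.34), ("F", 0.39)):
        scale = 1.0 if sex == "M" else 0.95
        beh[("locomotor_distance", sex)] = B(3200 * scale, 2500 * scale, loco_def, 36.0)
        beh[("grip_strength", sex)] = B(95 * scale, 80 * scale, 0.25, 36.0)
        beh[("rotarod_latency", sex)] = B(220 * scale, 160 * scale, 0.30, 30.0)
        beh[("tmaze_correct", sex)] = B(84.0, 86.0, 0.0)
        beh[("odor_discrimination", sex)] = B(75.0, 72.0, 0.0)
        beh[("social_interaction", sex)] = B(120.0, 100.0, 0.0)
    return TrajectoryConfig(
        volumes=vols, behavior=beh,
        missing_rate=missing_rate, outlier_rate=outlier_rate,
    )


@dataclass(frozen=True)
class TissueSignalModel:
    """Per-region proton density S0 and T2 (ms) for the multi-echo renderer.

    Defaults give a white:grey first-echo signal ratio of ~1.25 and a
    first-echo SNR of ~5 in grey matter at the default noise level.
    """

    s0: Mapping[str, float] = field(default_factory=lambda: {
        "background": 0.0,
        "brain_shell": 1000.0,
        "cortex": 1000.0,
        "striatum": 980.0,
        "hippocampus": 1010.0,
        "corpus_callosum": 1310.0,
        "ventricles": 1400.0,
        "muscle": 900.0,
    })
    t2_ms: Mapping[str, float] = field(default_factory=lambda: {
        "background": 1.0,
        "brain_shell": 40.0,
        "cortex": 42.0,
        "striatum": 40.0,
        "hippocampus": 43.0,
        "corpus_callosum": 35.0,
        "ventricles": 90.0,
        "muscle": 28.0,
    })
    noise_sd: float = 156.0  # ~= grey first-echo signal / 5
    noise_model: str = "gaussian"  # or "rician"

    def __post_init__(self):
        if any(t <= 0 for t in self.t2_ms.values()):
            raise ConfigurationError("T2 must be positive")
        if any(s < 0 for s in self.s0.values()):
            raise ConfigurationError("S0 must be non-negative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ConfigurationError("noise model must be gaussian or rician")


@dataclass(frozen=True)
class HistoGroundTruth:
    """Known content of a synthetic histology section stack.

    Coordinates are (section_index, z_um within section, y_um, x_um).
    Darkness is on the 0-255 stain-darkness scale (255 = fully opaque);
    the nuclear inclusion class must be strictly darker than the diffuse
    class.
    """

    n_sections: int
    section_thickness_um: float
    section_size_um: tuple[float, float]
    neuron_coords: np.ndarray  # (N, 4)
    neuron_radius_um: float = 5.0
    inclusion_coords: np.ndarray = field(
        default_factory=lambda: np.empty((0, 4)))
    inclusion_classes: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=object))  # nuclear|diffuse
    inclusion_radius_um: float = 3.0
    darkness: Mapping[str, int] = field(
        default_factory=lambda: {"neuron": 180, "nuclear": 200, "diffuse": 150,
                                 "background": 10})

    def __post_init__(self):
        if self.darkness["nuclear"] <= self.darkness["diffuse"]:
            raise ConfigurationError(
                "nuclear-class darkness must strictly exceed diffuse-class darkness")
        if self.n_sections < 0:
            raise ConfigurationError("section count must be non-negative")


def trajectory_config_from_yaml(path) -> TrajectoryConfig:
    """Load a TrajectoryConfig from a YAML mapping (volumes/behavior keyed
    by 'region|genotype' and 'measure|sex' strings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    vols = {
        tuple(k.split("|")): VolumeTrajectory(**v)
        for k, v in raw.get("volumes", {}).items()
    }
    beh = {
        tuple(k.split("|")): BehaviorCurve(**v)
        for k, v in raw.get("behavior", {}).items()
    }
    extra = {k: v for k, v in raw.items() if k not in ("volumes", "behavior")}
    return TrajectoryConfig(volumes=vols, behavior=beh, **extra)
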