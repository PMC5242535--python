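"""Longitudinal cohort generator: subjects, behaviour tables, image series.

The cohort crosses 2 genotypes x 2 sexes with ``n_per_cell`` animals per
cell, observed at the seven imaging ages. Behavioural observations are the
measure's age curve times a per-subject allometric factor and a
per-observation noise factor, with configured missingness and occasional
+-4 SD outliers (so an outlier screen has true positives). Imaging series
are labelled phantoms (and optionally their multi-echo renderings) whose
regional volumes follow the same trajectories.
"""
from __future__ import annotations

from typing import Iterator

import numpy as np
import pandas as pd

from ..types import ConfigurationError, LabelVolume
from .config import (
    BEHAVIOR_MEASURES,
    GENOTYPES,
    IMAGING_AGES,
    SEXES,
    PhantomSpec,
    TissueSignalModel,
    TrajectoryConfig,
    default_phantom_spec,
)
from .mri import render_multiecho
from .phantom import generate_phantom

#: measured regions of the phantom (muscle is the relaxometry control)
VOLUME_REGIONS = (
    "whole_brain", "cortex", "striatum", "hippocampus", "corpus_callosum",
    "ventricles",
)


def make_subjects(n_per_cell: int, seed: int) -> pd.DataFrame:
    """Subject registry with per-subject allometric scale and sub-voxel
    position shift (quasi-random imaging offsets)."""
    if n_per_cell < 2:
        raise ConfigurationError("need at least 2 animals per genotype x sex cell")
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for genotype in GENOTYPES:
        for sex in SEXES:
            for k in range(n_per_cell):
                rows.append({
                    "subject": f"{genotype}_{sex}_{k:02d}",
                    "genotype": genotype,
                    "sex": sex,
                    "scale": float(np.exp(rng.normal(0.0, 0.03))),
                    "shift_z": float(rng.uniform(-0.25, 0.25)),
                    "shift_y": float(rng.uniform(-0.08, 0.08)),
                    "shift_x": float(rng.uniform(-0.08, 0.08)),
                })
                i += 1
    return pd.DataFrame(rows)


def generate_cohort(
    trajectory: TrajectoryConfig,
    n_per_cell: int = 10,
    ages=IMAGING_AGES,
    seed: int = 0,
    measures=BEHAVIOR_MEASURES,
) -> pd.DataFrame:
    """Long-format behavioural table: subject, genotype, sex, age_weeks,
    measure, value, missing."""
    ages = list(ages)
    if not ages:
        raise ConfigurationError("age list must be non-empty")
    subjects = make_subjects(n_per_cell, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    rows = []
    for _, s in subjects.iterrows():
        # per-subject, per-measure ability factor
        ability = {
            m: np.exp(rng.normal(0.0, trajectory.behavior_subject_cv))
            for m in measures
        }
        for age in ages:
            for m in measures:
                curve = trajectory.behavior[(m, s.sex)]
                base = curve.value(s.genotype, age)
                noise_cv = trajectory.behavior_measurement_cv
                value = base * ability[m] * np.exp(rng.normal(0.0, noise_cv))
                missing = bool(rng.random() < trajectory.missing_rate)
                if not missing and rng.random() < trajectory.outlier_rate:
                    cell_sd = base * np.sqrt(
                        trajectory.behavior_subject_cv**2 + noise_cv**2)
                    value += float(rng.choice([-1.0, 1.0])) * \
                        trajectory.outlier_sd * cell_sd
                rows.append({
                    "subject": s.subject, "genotype": s.genotype, "sex": s.sex,
                    "age_weeks": age, "measure": m,
                    "value": np.nan if missing else float(value),
                    "missing": missing,
                })
    return pd.DataFrame(rows)


def iter_imaging_series(
    trajectory: TrajectoryConfig,
    spec: PhantomSpec | None = None,
    n_per_cell: int = 10,
    ages=IMAGING_AGES,
    seed: int = 0,
    signal_model: TissueSignalModel | None = None,
    echo_times=None,
    apply_missingness: bool = True,
) -> Iterator[tuple[dict, float, LabelVolume, object]]:
    """Yield ``(subject_record, age, label_volume, multiecho_or_None)`` for
    every observed imaging session.

    The multi-echo rendering is produced only when ``signal_model`` is
    given. Missing sessions (scanner drop-out) are skipped when
    ``apply_missingness`` is set; the final age is always retained.
    """
    ages = list(ages)
    if not ages:
        raise ConfigurationError("age list must be non-empty")
    spec = spec or default_phantom_spec()
    subjects = make_subjects(n_per_cell, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    region_names = [r.name for r in spec.regions]
    for idx, s in subjects.iterrows():
        for age in ages:
            jitter = {
                name: float(np.exp(rng.normal(0.0, trajectory.measurement_cv)))
                for name in region_names
            }
            drop = (apply_missingness and age != ages[-1]
                    and rng.random() < trajectory.missing_rate)
            if drop:
                continue
            vol = generate_phantom(
                spec, age, trajectory, s.genotype, s.sex,
                subject_scale=s.scale, volume_jitter=jitter,
                shift_mm=(s.shift_z, s.shift_y, s.shift_x),
            )
            img = None
            if signal_model is not None:
                img = render_multiecho(
                    vol, signal_model, echo_times,
                    seed=int(rng.integers(0, 2**31 - 1)))
            yield dict(s), float(age), vol, img


def generate_volume_table(
    trajectory: TrajectoryConfig,
    spec: PhantomSpec | None = None,
    n_per_cell: int = 10,
    ages=IMAGING_AGES,
    seed: int = 0,
    regions=VOLUME_REGIONS,
) -> pd.DataFrame:
    """Measure ROI volumes of every generated phantom with the volumetry
    stage; tidy output (subject, genotype, sex, age_weeks, region,
    volume_mm3)."""
    from ..volumetry import roi_volume  # measurement stage, not generation

    rows = []
    for subj, age, vol, _ in iter_imaging_series(
            trajectory, spec, n_per_cell, ages, seed):
        for region in regions:
            rows.append({
                "subject": subj["subject"], "genotype": subj["genotype"],
                "sex": subj["sex"], "age_weeks": age, "region": region,
                "volume_mm3": roi_volume(vol, region),
            })
    return pd.DataFrame(rows)
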