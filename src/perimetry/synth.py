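"""Synthetic perimetric data with known ground truth.

Healthy cohorts follow a "hill of vision" model: sensitivity at a
location falls off linearly with eccentricity from a height ``h0`` at
fixation, declines linearly with age, and carries a between-subject
offset plus within-subject (test-retest) noise.  Longitudinal series add
per-location progression slopes, a per-visit global fluctuation and
measurement noise to a baseline field.  Every generator is a pure
function of its spec (including the seed), so downstream estimators can
be tested against exact generating parameters without any external
data.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field as dfield

import numpy as np

from .fields import VisualField
from .grids import Grid, GridRegistry, default_registry
from .machine import SimulatedObserver

__all__ = [
    "CohortSpec", "SeriesSpec", "SynthError", "synth_healthy_cohort",
    "synth_healthy_field", "synth_series", "observer_from_field",
]

#: Reference age at which the cohort intercept equals ``h0 - k * ecc``.
AGE_REF = 45.0


class SynthError(ValueError):
    pass


@dataclass
class CohortSpec:
    """Generating parameters for a healthy cohort.

    Defaults encode a plausible healthy hill of vision: 33 dB at
    fixation, 0.25 dB/degree eccentricity fall-off, 0.06 dB/year age
    decline, 1 dB between-subject and 1.5 dB test-retest spread.
    """

    grid_name: str = "24-2"
    n_subjects: int = 200
    age_range: tuple[float, float] = (20.0, 80.0)
    h0: float = 33.0  #: dB at fixation, age AGE_REF
    ecc_slope: float = 0.25  #: dB per degree of eccentricity
    age_slope: float = 0.06  #: dB lost per year
    between_sd: float = 1.0  #: between-subject sd (dB)
    within_sd: float = 1.5  #: test-retest sd (dB)
    within_sd_ecc: float = 0.0  #: optional growth of within_sd per degree
    db_range: tuple[float, float] = (0.0, 40.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.between_sd < 0 or self.within_sd < 0 or self.within_sd_ecc < 0:
            raise SynthError("standard deviations must be >= 0")
        if self.age_range[1] <= self.age_range[0]:
            raise SynthError("age range must be non-degenerate")
        if self.n_subjects < 1:
            raise SynthError("need n_subjects >= 1")


@dataclass
class SeriesSpec:
    """Generating parameters for one eye's longitudinal series."""

    baseline: VisualField
    n_visits: int = 10
    spacing_years: float = 0.5
    progressing: dict[int, float] = dfield(default_factory=dict)
    fluctuation_sd: float = 0.0  #: per-visit global (diffuse) noise, dB
    measurement_sd: float = 1.0  #: per-location noise, dB
    db_range: tuple[float, float] = (0.0, 40.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_visits < 4:
            raise SynthError("need n_visits >= 4")
        if self.spacing_years <= 0:
            raise SynthError("visit spacing must be > 0")
        if self.fluctuation_sd < 0 or self.measurement_sd < 0:
            raise SynthError("standard deviations must be >= 0")


def _mean_sensitivity(spec: CohortSpec, grid: Grid, age: float) -> np.ndarray:
    ecc = np.hypot(*grid.coords().T)
    return (spec.h0 - spec.ecc_slope * ecc
            - spec.age_slope * (age - AGE_REF))


def synth_healthy_cohort(
    spec: CohortSpec, registry: GridRegistry | None = None
) -> tuple[list[VisualField], dict]:
    """One field per subject plus the full generating truth.

    Ages are uniform over the spec's range; each subject carries a
    Normal(0, between_sd^2) offset; each location adds Normal within-
    subject noise.  Values are clamped to the dB range after noise (a
    device reports nothing outside its dynamic range) and quantized to
    2 decimals to match the CSV representation.  Blind-spot locations
    are left missing.
    """
    reg = registry if registry is not None else default_registry
    grid = reg[spec.grid_name]
    rng = np.random.default_rng(spec.seed)
    n = len(grid)
    ecc = np.hypot(*grid.coords().T)
    sd_loc = spec.within_sd + spec.within_sd_ecc * ecc
    bs = grid.blind_spot_mask
    lo, hi = spec.db_range
    ages = rng.uniform(*spec.age_range, size=spec.n_subjects)
    offsets = rng.normal(0.0, spec.between_sd, size=spec.n_subjects)
    fields = []
    for k in range(spec.n_subjects):
        mean = _mean_sensitivity(spec, grid, ages[k]) + offsets[k]
        sens = mean + rng.normal(0.0, 1.0, size=n) * sd_loc
        sens = np.round(np.clip(sens, lo, hi), 2)
        sens[bs] = np.nan
        fields.append(VisualField(
            subject_id=f"S{k:04d}", eye="OD", date=dt.date(2000, 1, 1),
            age=float(round(ages[k], 2)), duration=300.0, fpr=0.0,
            fnr=0.0, fl=0.0, grid_name=grid.name, sensitivities=sens,
        ))
    truth = {
        "spec": spec, "ages": ages, "offsets": offsets,
        "expected_slope": -spec.age_slope,
        "expected_intercept_age_ref": spec.h0 - spec.ecc_slope * ecc,
    }
    return fields, truth


def synth_healthy_field(
    spec: CohortSpec,
    age: float,
    rng: np.random.Generator | int | None = None,
    registry: GridRegistry | None = None,
    subject_id: str = "S0000",
) -> VisualField:
    """A single healthy field at a given age from the cohort model."""
    reg = registry if registry is not None else default_registry
    grid = reg[spec.grid_name]
    r = (rng if isinstance(rng, np.random.Generator)
         else np.random.default_rng(spec.seed if rng is None else rng))
    ecc = np.hypot(*grid.coords().T)
    sd_loc = spec.within_sd + spec.within_sd_ecc * ecc
    mean = _mean_sensitivity(spec, grid, age) + r.normal(0, spec.between_sd)
    sens = mean + r.normal(0.0, 1.0, size=len(grid)) * sd_loc
    sens = np.round(np.clip(sens, *spec.db_range), 2)
    sens[grid.blind_spot_mask] = np.nan
    return VisualField(
        subject_id=subject_id, eye="OD", date=dt.date(2000, 1, 1),
        age=float(age), duration=300.0, fpr=0.0, fnr=0.0, fl=0.0,
        grid_name=grid.name, sensitivities=sens,
    )


def synth_series(
    spec: SeriesSpec, registry: GridRegistry | None = None
) -> tuple[list[VisualField], dict]:
    """Longitudinal series from a baseline field with known slopes.

    Visit v at location i takes
    ``baseline_i + slope_i * t_v + global_v + Normal(0, measurement_sd^2)``
    with ``global_v ~ Normal(0, fluctuation_sd^2)``; non-progressing
    locations have slope 0.  Dates advance by the visit spacing; ages
    advance accordingly.
    """
    reg = registry if registry is not None else default_registry
    base = spec.baseline
    grid = reg[base.grid_name]
    n = len(grid)
    for i in spec.progressing:
        if not (0 <= i < n):
            raise SynthError(f"progressing index {i} outside grid of size {n}")
    slopes = np.zeros(n)
    for i, s in spec.progressing.items():
        slopes[i] = s
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.db_range
    bs = grid.blind_spot_mask
    fields = []
    times = np.arange(spec.n_visits) * spec.spacing_years
    globals_ = rng.normal(0.0, spec.fluctuation_sd, size=spec.n_visits)
    for v, t in enumerate(times):
        noise = rng.normal(0.0, spec.measurement_sd, size=n)
        sens = base.sensitivities + slopes * t + globals_[v] + noise
        sens = np.round(np.clip(sens, lo, hi), 2)
        sens[bs] = np.nan
        date = base.date + dt.timedelta(days=round(t * 365.25))
        fields.append(VisualField(
            subject_id=base.subject_id, eye=base.eye, date=date,
            age=float(round(base.age + t, 3)), duration=base.duration,
            fpr=base.fpr, fnr=base.fnr, fl=base.fl,
            grid_name=base.grid_name, sensitivities=sens,
        ))
    truth = {"spec": spec, "slopes": slopes, "times": times,
             "globals": globals_}
    return fields, truth


def observer_from_field(
    field: VisualField,
    fos_sd: float = 1.0,
    fp: float = 0.0,
    fn: float = 0.0,
    registry: GridRegistry | None = None,
    floor_db: float = 0.0,
) -> SimulatedObserver:
    """Turn a field into a simulated observer whose true thresholds are
    the field's sensitivities (blind-spot locations get the dynamic-range
    floor).  Missing non-blind-spot values are an error."""
    reg = registry if registry is not None else default_registry
    grid = reg[field.grid_name]
    bs = grid.blind_spot_mask
    sens = np.asarray(field.sensitivities, dtype=float)
    bad = ~bs & ~np.isfinite(sens)
    if np.any(bad):
        raise SynthError(
            f"field has missing values at non-blind-spot locations "
            f"{np.flatnonzero(bad).tolist()}"
        )
    thresholds = np.where(bs, floor_db, sens)
    return SimulatedObserver(thresholds=thresholds, fos_sd=fos_sd, fp=fp,
                             fn=fn)
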