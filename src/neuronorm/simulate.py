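"""Synthetic brain-morphometry cohorts with graded disease effects.

The generator emulates the statistical structure the normative analysis
assumes: a large healthy reference cohort (ages 47-73, both sexes) plus
smaller clinical cohorts whose disease stages (early MCI, late MCI, AD
analogues) show graded medial-temporal atrophy and ventricular enlargement.

Generative law, per subject and region r::

    volume_r = baseline_r * (tiv / tiv_mean)
               * (1 + slope_r * (age - 60) + sex_offset_r * 1[male])
               * (1 + effect_{stage,r})
               * exp(eps_r),   eps_r ~ Normal(0, noise_sd_r^2)

The multiplicative log-normal noise keeps volumes strictly positive and
gives the right-skewed deviation distributions seen in real morphometry.
Healthy controls have a zero effect map.  Deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .cohort import AGE_MAX, AGE_MIN, N_REGIONS, Cohort, RegionAtlas, SubjectRecord, default_atlas

HC_LABEL = "HC"

# Regions driving the default disease analogue: medial-temporal atrophy and
# ventricular-system enlargement, with fractional change at severity 1.
_AD_EFFECT_PATTERN: Mapping[str, float] = {
    "Left-Hippocampus": -0.25, "Right-Hippocampus": -0.25,
    "lh-entorhinal": -0.25, "rh-entorhinal": -0.25,
    "lh-parahippocampal": -0.20, "rh-parahippocampal": -0.20,
    "Left-Amygdala": -0.20, "Right-Amygdala": -0.20,
    "Left-Lateral-Ventricle": 0.40, "Right-Lateral-Ventricle": 0.40,
    "Left-Inf-Lat-Vent": 0.50, "Right-Inf-Lat-Vent": 0.50,  # temporal horns
    "3rd-Ventricle": 0.30,
}

# Mean volumes (mm^3) for the volumetric structures; plausible mid-life values.
_STRUCTURE_BASELINES: Mapping[str, float] = {
    "Lateral-Ventricle": 7500.0, "Inf-Lat-Vent": 400.0,
    "Cerebellum-White-Matter": 14000.0, "Cerebellum-Cortex": 53000.0,
    "Thalamus-Proper": 7000.0, "Caudate": 3600.0, "Putamen": 5000.0,
    "Pallidum": 1800.0, "Hippocampus": 4000.0, "Amygdala": 1600.0,
    "Accumbens-area": 600.0, "VentralDC": 4000.0, "choroid-plexus": 700.0,
    "3rd-Ventricle": 1000.0, "4th-Ventricle": 1700.0, "Brain-Stem": 21000.0,
    "CSF": 1000.0, "Optic-Chiasm": 200.0, "WM-hypointensities": 2000.0,
    "Corpus-Callosum": 3000.0,
}

_VENTRICULAR = ("Lateral-Ventricle", "Inf-Lat-Vent", "3rd-Ventricle",
                "4th-Ventricle", "CSF", "WM-hypointensities", "choroid-plexus")


@dataclass(frozen=True)
class EffectMap:
    """Per-region fractional volume change for one disease stage.

    ``effects`` holds the change applied at this stage (negative = atrophy,
    positive = enlargement), already scaled by ``severity``.
    """

    stage: str
    severity: float
    effects: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "effects", np.asarray(self.effects, dtype=float))
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError(f"severity must lie in [0, 1], got {self.severity}")
        if self.effects.shape != (N_REGIONS,):
            raise ValueError(f"effect map must have {N_REGIONS} entries")
        if np.any(np.abs(self.effects) >= 0.9):
            raise ValueError("fractional effects must lie in (-0.9, 0.9)")

    @property
    def affected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.effects != 0.0)


def default_ad_effect_map(severity: float, atlas: RegionAtlas | None = None,
                          stage: str = "AD") -> EffectMap:
    """AD-analogue effect map, linear in severity.

    At severity 1: medial-temporal structures (hippocampus, entorhinal and
    parahippocampal cortex, amygdala) lose 20-25% of their volume while the
    ventricular system (lateral ventricles, temporal horns, 3rd ventricle)
    expands 30-50%.  All other regions are untouched.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity must lie in [0, 1], got {severity}")
    atlas = atlas or default_atlas()
    effects = np.zeros(N_REGIONS)
    for name, change in _AD_EFFECT_PATTERN.items():
        effects[atlas.index(name)] = change * severity
    return EffectMap(stage=stage, severity=severity, effects=effects)


def default_baseline(atlas: RegionAtlas) -> np.ndarray:
    """Default per-region mean volumes (mm^3).

    Volumetric structures use the explicit table above; cortical parcels get
    a fixed, reproducible log-uniform spread over [2,000, 22,000] mm^3 drawn
    once from a frozen generator (they are documented free parameters, not
    fitted values).
    """
    rng = np.random.default_rng(20210803)
    baseline = np.empty(N_REGIONS)
    cort = np.exp(rng.uniform(np.log(2000.0), np.log(22000.0), size=N_REGIONS))
    for i, (name, kind) in enumerate(zip(atlas.names, atlas.kinds)):
        if kind == "cortical":
            baseline[i] = cort[i]
        else:
            key = name.removeprefix("Left-").removeprefix("Right-")
            baseline[i] = _STRUCTURE_BASELINES[key]
    return baseline


def default_age_slope(atlas: RegionAtlas) -> np.ndarray:
    """Fractional volume change per year of age, centred at 60.

    Grey matter shrinks slowly (-0.3%/yr cortical, -0.2%/yr subcortical);
    CSF spaces expand (+2%/yr).
    """
    slope = np.empty(N_REGIONS)
    for i, (name, kind) in enumerate(zip(atlas.names, atlas.kinds)):
        key = name.removeprefix("Left-").removeprefix("Right-")
        if key in _VENTRICULAR:
            slope[i] = 0.02
        elif kind == "cortical":
            slope[i] = -0.003
        else:
            slope[i] = -0.002
    return slope


@dataclass
class SimulationSpec:
    """Configuration of the synthetic-cohort generator.

    ``group_sizes`` maps group label to subject count; every non-HC group
    must have an entry in ``effect_maps``.  Scalars for ``noise_sd`` and
    ``sex_offset`` are broadcast over regions.
    """

    group_sizes: Mapping[str, int]
    effect_maps: Mapping[str, EffectMap] = field(default_factory=dict)
    atlas: RegionAtlas = field(default_factory=default_atlas)
    age_range: tuple[int, int] = (AGE_MIN, AGE_MAX)
    male_fraction: float = 0.47
    baseline: np.ndarray | None = None
    tiv_mean: float = 1.5e6
    tiv_sd: float = 1.3e5
    age_slope: np.ndarray | None = None
    sex_offset: float | np.ndarray = 0.01
    noise_sd: float | np.ndarray = 0.10
    seed: int = 0
    name: str = "synthetic"

    def resolved(self) -> "SimulationSpec":
        """Fill derived defaults and validate."""
        lo, hi = self.age_range
        if not (AGE_MIN <= lo <= hi <= AGE_MAX):
            raise ValueError(f"age range must lie within [{AGE_MIN}, {AGE_MAX}]")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0, 1]")
        if self.tiv_sd < 0 or np.any(np.asarray(self.noise_sd) < 0):
            raise ValueError("standard deviations must be non-negative")
        sizes = dict(self.group_sizes)
        for g, n in list(sizes.items()):
            if n < 0:
                raise ValueError(f"group {g!r} must have n >= 0")
            if n == 0:  # requested-but-empty groups are dropped, not an error
                logging.getLogger(__name__).warning(
                    "group %r has n = 0 and is omitted from the cohort", g)
                del sizes[g]
        if not sizes:
            raise ValueError("no group has any subjects")
        baseline = (default_baseline(self.atlas) if self.baseline is None
                    else np.asarray(self.baseline, dtype=float))
        slope = (default_age_slope(self.atlas) if self.age_slope is None
                 else np.asarray(self.age_slope, dtype=float))
        sexoff = np.broadcast_to(np.asarray(self.sex_offset, dtype=float),
                                 (N_REGIONS,)).copy()
        # deterministic age/sex factor must stay positive over the age range
        for age_edge in (lo, hi):
            for male in (0.0, 1.0):
                factor = 1.0 + slope * (age_edge - 60) + sexoff * male
                if np.any(factor <= 0):
                    raise ValueError("age/sex factor non-positive for some region")
        return replace(self, group_sizes=sizes, baseline=baseline,
                       age_slope=slope, sex_offset=sexoff)


@dataclass
class GroundTruth:
    """What the generator actually did: effect maps, affected regions, seed."""

    effect_maps: dict[str, EffectMap]
    affected_indices: dict[str, np.ndarray]
    seed: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "stages": {
                stage: {
                    "severity": em.severity,
                    "effects": em.effects.tolist(),
                    "affected_indices": self.affected_indices[stage].tolist(),
                }
                for stage, em in self.effect_maps.items()
            },
        }


def _generate_group(spec: SimulationSpec, group: str, n: int,
                    effects: np.ndarray, rng: np.random.Generator,
                    id_prefix: str) -> list[SubjectRecord]:
    lo, hi = spec.age_range
    ages = rng.integers(lo, hi + 1, size=n)
    males = rng.random(n) < spec.male_fraction
    tiv = rng.normal(spec.tiv_mean, spec.tiv_sd, size=n)
    while np.any(tiv <= 0):  # pathological spec only; keeps TIV positive
        bad = tiv <= 0
        tiv[bad] = rng.normal(spec.tiv_mean, spec.tiv_sd, size=bad.sum())
    noise = rng.normal(0.0, 1.0, size=(n, N_REGIONS)) * np.asarray(spec.noise_sd)
    records = []
    for i in range(n):
        factor = (1.0 + spec.age_slope * (ages[i] - 60)
                  + spec.sex_offset * float(males[i]))
        vol = (spec.baseline * (tiv[i] / spec.tiv_mean) * factor
               * (1.0 + effects) * np.exp(noise[i]))
        records.append(SubjectRecord(
            subject_id=f"{id_prefix}-{group}-{i:05d}",
            age=int(ages[i]),
            sex="male" if males[i] else "female",
            group=group,
            tiv=float(tiv[i]),
            volumes=vol,
        ))
    return records


def generate_reference_cohort(spec: SimulationSpec) -> Cohort:
    """Generate the healthy reference cohort (HC only)."""
    spec = spec.resolved()
    if set(spec.group_sizes) != {HC_LABEL}:
        raise ValueError("reference cohort spec must declare the HC group only")
    rng = np.random.default_rng(spec.seed)
    zero = np.zeros(N_REGIONS)
    records = _generate_group(spec, HC_LABEL, spec.group_sizes[HC_LABEL],
                              zero, rng, spec.name)
    return Cohort(records=records, atlas=spec.atlas, name=spec.name)


def generate_clinical_cohort(spec: SimulationSpec) -> tuple[Cohort, GroundTruth]:
    """Generate a clinical cohort with an HC group and >=1 disease stage.

    Each clinical stage's volumes are multiplied per region by
    ``(1 + effect_{stage,r})``; the HC members get zero effect.  Returns the
    cohort plus the ground-truth manifest of what was injected.
    """
    spec = spec.resolved()
    stages = [g for g in spec.group_sizes if g != HC_LABEL]
    if not stages:
        raise ValueError("clinical cohort spec must declare at least one stage")
    for s in stages:
        if s not in spec.effect_maps:
            raise ValueError(f"stage {s!r} has no effect map")
    rng = np.random.default_rng(spec.seed)
    zero = np.zeros(N_REGIONS)
    records: list[SubjectRecord] = []
    for group, n in spec.group_sizes.items():
        effects = zero if group == HC_LABEL else spec.effect_maps[group].effects
        records.extend(_generate_group(spec, group, n, effects, rng, spec.name))
    truth = GroundTruth(
        effect_maps={s: spec.effect_maps[s] for s in stages},
        affected_indices={s: spec.effect_maps[s].affected_indices for s in stages},
        seed=spec.seed,
    )
    return Cohort(records=records, atlas=spec.atlas, name=spec.name), truth


def graded_ad_spec(n_per_group: int = 150, seed: int = 0,
                   severities: Mapping[str, float] | None = None,
                   atlas: RegionAtlas | None = None,
                   name: str = "clinical") -> SimulationSpec:
    """Convenience spec: HC plus EMCI/LMCI/AD analogues with graded severity.

    Default severities 0.3 / 0.6 / 1.0 scale the AD-analogue effect map,
    emulating the clinical gradient from early MCI to dementia.
    """
    severities = dict(severities or {"EMCI": 0.3, "LMCI": 0.6, "AD": 1.0})
    atlas = atlas or default_atlas()
    sizes = {HC_LABEL: n_per_group}
    maps = {}
    for stage, sev in severities.items():
        sizes[stage] = n_per_group
        maps[stage] = default_ad_effect_map(sev, atlas=atlas, stage=stage)
    return SimulationSpec(group_sizes=sizes, effect_maps=maps, atlas=atlas,
                          seed=seed, name=name)
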