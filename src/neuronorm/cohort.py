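"""Cohort data model: region atlas, subject records, table I/O, balance tests.

The analysis operates on tabular morphometry: one row per subject carrying
demographics, estimated total intracranial volume (TIV) and 101 regional
volumes (68 Desikan-Killiany cortical subregions, 34 per hemisphere, plus 33
whole-brain volumetric structures from an Aseg-style segmentation).  All
cohorts in one analysis share a single fixed, ordered region atlas.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

N_CORTICAL = 68
N_STRUCTURES = 33
N_REGIONS = N_CORTICAL + N_STRUCTURES  # 101

AGE_MIN = 47
AGE_MAX = 73
N_AGES = AGE_MAX - AGE_MIN + 1  # 27 one-hot positions

SEXES = ("male", "female")

ID_COLUMNS = ("subject_id", "age", "sex", "group", "tiv")


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the subject-record contract.

    The message lists every offending row/column, not just the first.
    """


# 34 Desikan-Killiany cortical parcels per hemisphere.
_DK_PARCELS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
)

# 33 volumetric structures: 13 bilateral pairs + 7 midline/global entries.
_ASEG_PAIRED = (
    "Lateral-Ventricle", "Inf-Lat-Vent", "Cerebellum-White-Matter",
    "Cerebellum-Cortex", "Thalamus-Proper", "Caudate", "Putamen", "Pallidum",
    "Hippocampus", "Amygdala", "Accumbens-area", "VentralDC", "choroid-plexus",
)
_ASEG_MIDLINE = (
    "3rd-Ventricle", "4th-Ventricle", "Brain-Stem", "CSF", "Optic-Chiasm",
    "WM-hypointensities", "Corpus-Callosum",
)


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered list of the 101 region names shared by every cohort.

    ``kinds`` tags each entry as ``"cortical"`` or ``"structure"``; the
    order of ``names`` is significant and defines the column order of every
    volume vector in the analysis.
    """

    names: tuple[str, ...]
    kinds: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != N_REGIONS:
            raise ValueError(
                f"atlas must have exactly {N_REGIONS} regions, got {len(self.names)}"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("atlas region names must be unique")
        if len(self.kinds) != len(self.names):
            raise ValueError("kinds must align with names")
        if any(k not in ("cortical", "structure") for k in self.kinds):
            raise ValueError("region kind must be 'cortical' or 'structure'")
        if self.kinds.count("cortical") != N_CORTICAL:
            raise ValueError(f"atlas must tag {N_CORTICAL} cortical regions")

    def index(self, name: str) -> int:
        return self.names.index(name)

    def indices(self, names: Iterable[str]) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=int)

    @property
    def cortical_names(self) -> tuple[str, ...]:
        return tuple(n for n, k in zip(self.names, self.kinds) if k == "cortical")

    @property
    def structure_names(self) -> tuple[str, ...]:
        return tuple(n for n, k in zip(self.names, self.kinds) if k == "structure")

    @classmethod
    def from_file(cls, path: str | Path) -> "RegionAtlas":
        """Load an atlas from plain text, one region name per line.

        Lines starting with ``#`` are comments.  Cortical entries are
        recognised by an ``lh-``/``rh-`` prefix; everything else is tagged
        as a volumetric structure.
        """
        names = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                names.append(line)
        kinds = tuple(
            "cortical" if n.startswith(("lh-", "rh-")) else "structure" for n in names
        )
        return cls(names=tuple(names), kinds=kinds)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.names) + "\n")


def default_atlas() -> RegionAtlas:
    """The canonical 101-region atlas used when none is supplied.

    68 Desikan-Killiany cortical labels (``lh-``/``rh-`` prefixed) followed
    by 33 Aseg-style structures (13 bilateral pairs with ``Left-``/``Right-``
    prefixes, then 7 midline/global entries).
    """
    names = [f"{hemi}-{p}" for hemi in ("lh", "rh") for p in _DK_PARCELS]
    kinds = ["cortical"] * N_CORTICAL
    for side in ("Left", "Right"):
        names.extend(f"{side}-{s}" for s in _ASEG_PAIRED)
    names.extend(_ASEG_MIDLINE)
    kinds.extend(["structure"] * N_STRUCTURES)
    return RegionAtlas(names=tuple(names), kinds=tuple(kinds))


@dataclass
class SubjectRecord:
    """One subject: demographics, TIV and the atlas-aligned volume vector."""

    subject_id: str
    age: int
    sex: str
    group: str
    tiv: float
    volumes: np.ndarray

    def validation_errors(self) -> list[str]:
        errs = []
        if not (isinstance(self.age, (int, np.integer)) and not isinstance(self.age, bool)):
            errs.append(f"age must be an integer, got {self.age!r}")
        elif not AGE_MIN <= self.age <= AGE_MAX:
            errs.append(f"age {self.age} outside [{AGE_MIN}, {AGE_MAX}]")
        if self.sex not in SEXES:
            errs.append(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not np.isfinite(self.tiv) or self.tiv <= 0:
            errs.append(f"tiv must be > 0, got {self.tiv!r}")
        v = np.asarray(self.volumes, dtype=float)
        if v.shape != (N_REGIONS,):
            errs.append(f"volumes must have length {N_REGIONS}, got {v.shape}")
        else:
            bad = ~np.isfinite(v) | (v < 0)
            if bad.any():
                errs.append(f"volumes at indices {np.flatnonzero(bad).tolist()} "
                            "are negative or missing")
        return errs

    def validate(self) -> None:
        errs = self.validation_errors()
        if errs:
            raise CohortValidationError(
                f"subject {self.subject_id!r}: " + "; ".join(errs)
            )


@dataclass
class Cohort:
    """A named collection of subject records sharing one atlas."""

    records: list[SubjectRecord]
    atlas: RegionAtlas
    name: str = "cohort"

    def __len__(self) -> int:
        return len(self.records)

    @property
    def groups(self) -> list[str]:
        """Unique group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.group, None)
        return list(seen)

    def group_labels(self) -> np.ndarray:
        return np.array([r.group for r in self.records])

    def ages(self) -> np.ndarray:
        return np.array([r.age for r in self.records], dtype=int)

    def sexes(self) -> np.ndarray:
        return np.array([r.sex for r in self.records])

    def tivs(self) -> np.ndarray:
        return np.array([r.tiv for r in self.records], dtype=float)

    def volumes_matrix(self) -> np.ndarray:
        """(n_subjects, 101) raw volume matrix in atlas order."""
        return np.array([r.volumes for r in self.records], dtype=float)

    def subset(self, group: str, name: str | None = None) -> "Cohort":
        recs = [r for r in self.records if r.group == group]
        return Cohort(records=recs, atlas=self.atlas,
                      name=name or f"{self.name}:{group}")

    def select(self, mask: Sequence[int] | np.ndarray, name: str | None = None) -> "Cohort":
        recs = [self.records[i] for i in np.asarray(mask, dtype=int)]
        return Cohort(records=recs, atlas=self.atlas, name=name or self.name)

    def to_frame(self) -> pd.DataFrame:
        vol = self.volumes_matrix()
        data = {
            "subject_id": [r.subject_id for r in self.records],
            "age": self.ages() if self.records else pd.Series(dtype=int),
            "sex": self.sexes() if self.records else pd.Series(dtype=str),
            "group": self.group_labels() if self.records else pd.Series(dtype=str),
            "tiv": self.tivs() if self.records else pd.Series(dtype=float),
        }
        meta = pd.DataFrame(data)
        if self.records:
            regions = pd.DataFrame(vol, columns=list(self.atlas.names))
        else:
            regions = pd.DataFrame({r: pd.Series(dtype=float)
                                    for r in self.atlas.names})
        return pd.concat([meta, regions], axis=1)

    def validate(self) -> None:
        problems = []
        for i, r in enumerate(self.records):
            for e in r.validation_errors():
                problems.append(f"row {i} (subject {r.subject_id!r}): {e}")
        if problems:
            raise CohortValidationError("\n".join(problems))


def read_cohort_table(path: str | Path, atlas: RegionAtlas,
                      name: str | None = None) -> Cohort:
    """Read a cohort CSV and validate it against the atlas.

    The file must be comma-separated UTF-8 with a header naming
    ``subject_id, age, sex, group, tiv`` and all 101 atlas regions (in any
    column order; columns are re-ordered to atlas order).  Every violation
    of the subject-record contract is reported, naming the row and column.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in (*ID_COLUMNS, *atlas.names) if c not in df.columns]
    if missing:
        raise CohortValidationError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )

    problems: list[str] = []
    # ages must be integer years; fractional values are rejected, not rounded
    ages_raw = pd.to_numeric(df["age"], errors="coerce")
    for i, a in enumerate(ages_raw):
        if pd.isna(a) or float(a) != int(a):
            problems.append(f"row {i}, column 'age': non-integer value {df['age'].iloc[i]!r}")
    for region in atlas.names:
        col = pd.to_numeric(df[region], errors="coerce")
        for i in np.flatnonzero(col.isna().to_numpy()):
            problems.append(f"row {i}, column {region!r}: non-numeric volume "
                            f"{df[region].iloc[i]!r}")
    if problems:
        raise CohortValidationError("\n".join(problems))

    records = []
    for i, row in df.iterrows():
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]),
            age=int(row["age"]),
            sex=str(row["sex"]),
            group=str(row["group"]),
            tiv=float(row["tiv"]),
            volumes=np.array([float(row[r]) for r in atlas.names]),
        ))
    cohort = Cohort(records=records, atlas=atlas, name=name or path.stem)
    cohort.validate()
    return cohort


def write_cohort_table(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as CSV; ``read_cohort_table`` round-trips it exactly.

    Floats are written with ``repr`` precision so volumes and TIV survive
    the round trip bit-exactly.
    """
    cohort.to_frame().to_csv(path, index=False)


@dataclass
class BalanceReport:
    """Demographic balance across diagnostic groups within one cohort."""

    age_anova_p: float
    sex_chisq_p: float
    group_summary: pd.DataFrame  # per group: n, age mean, age sd, sex counts

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"age ANOVA p={self.age_anova_p:.3g}, "
                f"sex chi-square p={self.sex_chisq_p:.3g}\n"
                f"{self.group_summary}")


def demographic_balance_tests(cohort: Cohort) -> BalanceReport:
    """One-way ANOVA on age and chi-square homogeneity on sex across groups.

    Mirrors the demographic sanity checks run on each clinical dataset:
    groups entering a deviation comparison should not differ significantly
    in age or sex ratio.  Requires at least two groups of size >= 2.
    """
    groups = cohort.groups
    if len(groups) < 2:
        raise ValueError("balance tests need at least two groups")
    labels = cohort.group_labels()
    ages = cohort.ages()
    sexes = cohort.sexes()

    age_lists = []
    for g in groups:
        a = ages[labels == g]
        if len(a) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
        age_lists.append(a.astype(float))

    grand = np.concatenate(age_lists)
    means = np.array([a.mean() for a in age_lists])
    # degenerate case: zero between-group variance -> F = 0, p = 1
    if np.allclose(means, grand.mean()):
        age_p = 1.0
    else:
        _, age_p = stats.f_oneway(*age_lists)
        if np.isnan(age_p):
            age_p = 1.0

    table = np.array([[np.sum((labels == g) & (sexes == s)) for s in SEXES]
                      for g in groups], dtype=float)
    table = table[:, table.sum(axis=0) > 0]  # drop a sex absent everywhere
    if table.shape[1] < 2:
        sex_p = 1.0
    else:
        chi2, sex_p, _, _ = stats.chi2_contingency(table, correction=False)
        if np.isnan(sex_p):
            sex_p = 1.0

    rows = []
    for g in groups:
        sel = labels == g
        rows.append({
            "group": g,
            "n": int(sel.sum()),
            "age_mean": float(ages[sel].mean()),
            "age_sd": float(ages[sel].std(ddof=1)),
            "n_male": int(np.sum(sel & (sexes == "male"))),
            "n_female": int(np.sum(sel & (sexes == "female"))),
        })
    summary = pd.DataFrame(rows).set_index("group")
    return BalanceReport(age_anova_p=float(age_p), sex_chisq_p=float(sex_p),
                         group_summary=summary)
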