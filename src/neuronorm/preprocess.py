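"""Feature pipeline: TIV-relative volumes, robust scaling, one-hot conditioning.

Regional volumes are divided by total intracranial volume, then each region
is centred on the training-set median and scaled by its training-set
interquartile range (outlier-robust, fitted independently per region).  The
same training-set statistics are re-used, unchanged, to normalise clinical
data.  Age (integer years 47-73) and sex are one-hot encoded for the
decoder's conditioning input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import AGE_MAX, AGE_MIN, N_AGES, N_REGIONS, SEXES, Cohort, SubjectRecord

N_SEX = 2
N_CONDITION = N_AGES + N_SEX  # 29


@dataclass
class ScalerParams:
    """Per-region median and IQR fitted on a training set of relative volumes."""

    median: np.ndarray
    iqr: np.ndarray

    def __post_init__(self) -> None:
        self.median = np.asarray(self.median, dtype=float)
        self.iqr = np.asarray(self.iqr, dtype=float)
        if self.median.shape != (N_REGIONS,) or self.iqr.shape != (N_REGIONS,):
            raise ValueError(f"scaler params must have length {N_REGIONS}")
        if not np.all(self.iqr > 0):
            raise ValueError("all region IQRs must be positive")


def relative_volumes(record_or_volumes, tiv: float | None = None) -> np.ndarray:
    """Regional volumes divided by total intracranial volume.

    Accepts either a :class:`SubjectRecord` or an explicit
    ``(volumes, tiv)`` pair; ``volumes`` may be a matrix with subjects in
    rows, in which case ``tiv`` is broadcast per row.
    """
    if isinstance(record_or_volumes, SubjectRecord):
        volumes = np.asarray(record_or_volumes.volumes, dtype=float)
        tiv = record_or_volumes.tiv
    else:
        volumes = np.asarray(record_or_volumes, dtype=float)
    tiv_arr = np.asarray(tiv, dtype=float)
    if np.any(tiv_arr <= 0):
        raise ValueError("tiv must be positive")
    if volumes.ndim == 2:
        return volumes / tiv_arr[:, None]
    return volumes / tiv_arr


def cohort_relative_volumes(cohort: Cohort) -> np.ndarray:
    """(n, 101) matrix of TIV-relative volumes for a whole cohort."""
    return relative_volumes(cohort.volumes_matrix(), cohort.tivs())


def fit_scaler(train: np.ndarray, region_names=None) -> ScalerParams:
    """Fit per-region median and interquartile range on training data.

    ``train`` is an (n, 101) matrix of relative volumes with n >= 4.
    Quantiles use linear interpolation between order statistics (Q1 at the
    25th, Q3 at the 75th percentile).  A region with zero IQR makes robust
    scaling undefined and raises, naming the region.
    """
    X = np.asarray(train, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_REGIONS:
        raise ValueError(f"training matrix must be (n, {N_REGIONS})")
    if X.shape[0] < 4:
        raise ValueError("need at least 4 training subjects to fit the scaler")
    q1, med, q3 = np.percentile(X, [25, 50, 75], axis=0)
    iqr = q3 - q1
    zero = np.flatnonzero(iqr <= 0)
    if zero.size:
        names = ([str(i) for i in zero] if region_names is None
                 else [region_names[i] for i in zero])
        raise ValueError("zero interquartile range for region(s): " + ", ".join(names))
    return ScalerParams(median=med, iqr=iqr)


def apply_scaler(x: np.ndarray, params: ScalerParams) -> np.ndarray:
    """Normalise relative volumes: ``z = (x - median) / IQR`` per region."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != N_REGIONS:
        raise ValueError(f"expected {N_REGIONS} regions, got {x.shape[-1]}")
    return (x - params.median) / params.iqr


def invert_scaler(z: np.ndarray, params: ScalerParams) -> np.ndarray:
    """Inverse of :func:`apply_scaler` (for round-trip checks and reporting)."""
    return np.asarray(z, dtype=float) * params.iqr + params.median


def one_hot_age(age: int) -> np.ndarray:
    """27-length one-hot vector; position ``age - 47`` is set."""
    if not float(age) == int(age):
        raise ValueError(f"age must be an integer year, got {age!r}")
    age = int(age)
    if not AGE_MIN <= age <= AGE_MAX:
        raise ValueError(f"age {age} outside [{AGE_MIN}, {AGE_MAX}]")
    v = np.zeros(N_AGES)
    v[age - AGE_MIN] = 1.0
    return v


def one_hot_sex(sex: str) -> np.ndarray:
    """2-length one-hot vector, ordered (male, female)."""
    if sex not in SEXES:
        raise ValueError(f"unknown sex label {sex!r}; expected one of {SEXES}")
    v = np.zeros(N_SEX)
    v[SEXES.index(sex)] = 1.0
    return v


def condition_vector(age: int, sex: str) -> np.ndarray:
    """Concatenated (age one-hot, sex one-hot): 29 entries, exactly two 1s."""
    return np.concatenate([one_hot_age(age), one_hot_sex(sex)])


def cohort_condition_matrix(cohort: Cohort) -> np.ndarray:
    """(n, 29) conditioning matrix for a whole cohort."""
    return np.array([condition_vector(r.age, r.sex) for r in cohort.records])
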