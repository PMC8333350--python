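"""Traditional-classifier baseline: 0.632+ bootstrap AUC and generalization.

Within each clinical cohort, an RVM is trained on bootstrap resamples of the
pooled HC + patient subjects and evaluated both on the sample it was fitted
on ("resubstitution") and on the subjects never drawn ("out-of-bag").  The
0.632+ estimator blends the two per iteration,

    AUC_bootstrap = (1/b) * sum_i [ w_i * AUC_oob,i + (1 - w_i) * AUC_resub,i ]

with the weight derived from the relative overfitting rate
``R = (AUC_resub - AUC_oob) / (AUC_resub - 0.5)`` (0.5 = no-information AUC,
R clipped to [0, 1]) as ``w = 0.632 / (1 - 0.368 R)``, capped at 1.  Cross-
cohort generalization re-uses the per-iteration models to score external
cohorts, normalised with the *training* cohort's scaler, yielding the
train-by-test AUC matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .deviation import PercentileCI, auc_from_scores, derive_seed, percentile_ci
from .preprocess import ScalerParams, apply_scaler, cohort_relative_volumes, fit_scaler
from .rvm import RVMModel, fit_rvm, predict_proba
from .simulate import HC_LABEL


def omega_weight(auc_resub: float, auc_oob: float) -> float:
    """0.632+ blending weight from the relative overfitting rate.

    ``omega = 0.632`` when there is no overfitting (oob >= resub) and grows
    towards 1 as the out-of-bag performance collapses to chance while the
    resubstitution performance stays high.
    """
    for name, v in (("auc_resub", auc_resub), ("auc_oob", auc_oob)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    denom = auc_resub - 0.5
    if denom <= 0.0:
        r = 0.0 if auc_oob >= auc_resub else 1.0
    else:
        r = (auc_resub - auc_oob) / denom
    r = float(np.clip(r, 0.0, 1.0))
    omega = 0.632 / (1.0 - 0.368 * r)
    return float(min(omega, 1.0))


@dataclass
class Bootstrap632Result:
    """Per-iteration components and the blended 0.632+ aggregate."""

    cohort: str
    contrast: tuple[str, str]               # (HC label, patient group)
    pool_size: int
    auc_resub: np.ndarray                   # (b,)
    auc_oob: np.ndarray                     # (b,)
    omega: np.ndarray                       # (b,)
    blended: np.ndarray                     # (b,) omega*oob + (1-omega)*resub
    auc_bootstrap: float                    # mean of blended
    ci: PercentileCI
    n_redraws: int = 0
    models: list[RVMModel] = field(default_factory=list)

    def recompute_aggregate(self) -> float:
        """Re-derive the aggregate from the stored per-iteration parts."""
        return float(np.mean(self.omega * self.auc_oob
                             + (1.0 - self.omega) * self.auc_resub))


def _classification_arrays(cohort: Cohort, contrast: tuple[str, str]):
    hc_label, patient = contrast
    labels = cohort.group_labels()
    mask = (labels == hc_label) | (labels == patient)
    if not np.any(labels == hc_label) or not np.any(labels == patient):
        raise ValueError(f"cohort {cohort.name!r} lacks one of {contrast}")
    rel = cohort_relative_volumes(cohort)[mask]
    y = (labels[mask] == patient).astype(float)
    return rel, y


def bootstrap_632plus_auc(
    cohort: Cohort,
    contrast: tuple[str, str] = (HC_LABEL, "AD"),
    n_iterations: int = 50,
    seed: int = 0,
    level: float = 0.95,
    keep_models: bool = False,
    max_redraws: int = 100,
) -> Bootstrap632Result:
    """0.632+ bootstrap AUC of an RVM on one binary contrast.

    Per iteration the pooled HC + patient subjects are resampled with
    replacement to the pool's size; the robust scaler and the RVM are fitted
    on the bootstrap sample, and AUCs are computed on the sample
    (resubstitution) and on the never-drawn subjects (out-of-bag).  A draw
    whose bootstrap sample or out-of-bag set lacks a class is redrawn so the
    iteration count stays fixed.
    """
    if n_iterations < 1:
        raise ValueError("need at least 1 iteration")
    rel, y = _classification_arrays(cohort, contrast)
    n_pool = rel.shape[0]
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ValueError("each class needs at least 2 subjects")

    auc_resub = np.empty(n_iterations)
    auc_oob = np.empty(n_iterations)
    omegas = np.empty(n_iterations)
    models: list[RVMModel] = []
    n_redraws = 0

    for it in range(n_iterations):
        rng = np.random.default_rng(derive_seed(seed, it))
        for _ in range(max_redraws):
            idx = rng.integers(0, n_pool, size=n_pool)
            oob_mask = np.ones(n_pool, dtype=bool)
            oob_mask[np.unique(idx)] = False
            y_boot, y_oob = y[idx], y[oob_mask]
            if (len(np.unique(y_boot)) == 2 and oob_mask.sum() > 0
                    and len(np.unique(y_oob)) == 2):
                break
            n_redraws += 1
        else:
            raise RuntimeError("could not draw a two-class bootstrap split")

        X_boot = rel[idx]
        scaler = fit_scaler(X_boot, region_names=cohort.atlas.names)
        model = fit_rvm(apply_scaler(X_boot, scaler), y_boot)
        model.scaler = scaler

        p_boot = predict_proba(model, apply_scaler(X_boot, scaler))
        p_oob = predict_proba(model, apply_scaler(rel[oob_mask], scaler))
        auc_resub[it] = auc_from_scores(p_boot[y_boot == 1], p_boot[y_boot == 0])
        auc_oob[it] = auc_from_scores(p_oob[y_oob == 1], p_oob[y_oob == 0])
        omegas[it] = omega_weight(auc_resub[it], auc_oob[it])
        if keep_models:
            models.append(model)

    blended = omegas * auc_oob + (1.0 - omegas) * auc_resub
    return Bootstrap632Result(
        cohort=cohort.name,
        contrast=contrast,
        pool_size=n_pool,
        auc_resub=auc_resub,
        auc_oob=auc_oob,
        omega=omegas,
        blended=blended,
        auc_bootstrap=float(np.mean(blended)),
        ci=percentile_ci(blended, level),
        n_redraws=n_redraws,
        models=models,
    )


def generalization_aucs(models: list[RVMModel], test_cohort: Cohort,
                        contrast: tuple[str, str]) -> np.ndarray:
    """Per-iteration AUCs of trained models on an external cohort.

    Each model's own training scaler normalises the external data, matching
    how the model would be deployed.
    """
    rel, y = _classification_arrays(test_cohort, contrast)
    out = np.empty(len(models))
    for i, model in enumerate(models):
        if model.scaler is None:
            raise ValueError("model lacks its training scaler")
        p = predict_proba(model, apply_scaler(rel, model.scaler))
        out[i] = auc_from_scores(p[y == 1], p[y == 0])
    return out


@dataclass
class GeneralizationMatrix:
    """Train-cohort x test-cohort AUC grid with CIs (diagonal absent)."""

    contrast_group: str
    aucs: dict[tuple[str, str], np.ndarray]   # (train, test) -> (b,) AUCs
    level: float = 0.95

    def cell_ci(self, train: str, test: str) -> PercentileCI:
        return percentile_ci(self.aucs[(train, test)], self.level)

    def to_frame(self) -> pd.DataFrame:
        trains = sorted({t for t, _ in self.aucs})
        tests = sorted({t for _, t in self.aucs})
        table = pd.DataFrame(index=trains, columns=tests, dtype=object)
        for (tr, te), _ in self.aucs.items():
            ci = self.cell_ci(tr, te)
            table.loc[tr, te] = f"{ci.point:.2f} [{ci.lower:.2f}, {ci.upper:.2f}]"
        table.index.name = "train"
        table.columns.name = "test"
        return table


def cross_cohort_generalization(
    trained: dict[str, Bootstrap632Result],
    cohorts: dict[str, Cohort],
    contrast_group: str,
    hc_label: str = HC_LABEL,
    level: float = 0.95,
) -> GeneralizationMatrix:
    """Score every train-cohort's per-iteration models on every other cohort.

    ``trained`` maps cohort name to a :class:`Bootstrap632Result` produced
    with ``keep_models=True``; cohorts must share the atlas.
    """
    atlases = {id(c.atlas) for c in cohorts.values()}
    names = {tuple(c.atlas.names) for c in cohorts.values()}
    if len(atlases) > 1 and len(names) > 1:
        raise ValueError("all cohorts must share one region atlas")
    aucs: dict[tuple[str, str], np.ndarray] = {}
    for train_name, result in trained.items():
        if not result.models:
            raise ValueError(
                f"result for {train_name!r} kept no models; rerun with keep_models=True")
        for test_name, test_cohort in cohorts.items():
            if test_name == train_name:
                continue
            aucs[(train_name, test_name)] = generalization_aucs(
                result.models, test_cohort, (hc_label, contrast_group))
    return GeneralizationMatrix(contrast_group=contrast_group, aucs=aucs,
                                level=level)


def auc_difference_ci(auc_samples_a: np.ndarray, auc_samples_b: np.ndarray,
                      level: float = 0.95) -> tuple[PercentileCI, bool]:
    """Percentile CI of per-iteration paired AUC differences (a - b).

    The two bootstrap schemes are paired by iteration index; the difference
    is significant when the CI excludes zero.
    """
    a = np.asarray(auc_samples_a, dtype=float)
    b = np.asarray(auc_samples_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("AUC sample arrays must have equal length (paired)")
    ci = percentile_ci(a - b, level)
    return ci, ci.excludes_zero
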