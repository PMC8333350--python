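"""Deviation scoring and bootstrap inference for the normative model.

A subject's *observed deviation* is the mean squared error between the
normalised 101-region input vector and its autoencoder reconstruction; the
per-region squared errors localise the deviation.  Group inference repeats
the whole train-and-score procedure over bootstrap resamples of the healthy
reference cohort: each iteration retrains the model, scores every clinical
subject, and records group means, pairwise mean differences, discrimination
AUCs and per-region Cliff's delta effect sizes.  Percentile confidence
intervals across iterations give the uncertainty bands; an effect is flagged
significant when its 95% interval excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aae import MLP, Adam, AAEConfig, AAEParams, reconstruct_cohort, train
from .cohort import Cohort, N_REGIONS
from .simulate import HC_LABEL


def observed_deviation(x: np.ndarray, xhat: np.ndarray) -> float:
    """Mean squared reconstruction error over the 101 regions."""
    x = np.asarray(x, dtype=float)
    xhat = np.asarray(xhat, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xhat.shape}")
    return float(np.mean((x - xhat) ** 2))


def region_deviations(x: np.ndarray, xhat: np.ndarray,
                      signed: bool = False) -> np.ndarray:
    """Per-region deviation; squared by default so its mean is the score.

    ``signed=True`` returns the raw residual ``x - xhat`` instead (useful
    for inspecting the direction of each region's deviation).
    """
    x = np.asarray(x, dtype=float)
    xhat = np.asarray(xhat, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xhat.shape}")
    d = x - xhat
    return d if signed else d ** 2


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(#a>b, #a<b, n*m) over all cross pairs, via sorted search."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    bs = np.sort(b)
    greater = int(np.searchsorted(bs, a, side="left").sum())
    less = int((b.size - np.searchsorted(bs, a, side="right")).sum())
    return greater, less, a.size * b.size


def cliffs_delta(a: np.ndarray, b: np.ndarray) -> float:
    """Cliff's delta: P(a > b) - P(a < b) over all cross pairs; ties count 0."""
    greater, less, nm = _pair_counts(a, b)
    return (greater - less) / nm


def auc_from_scores(pos: np.ndarray, neg: np.ndarray) -> float:
    """Probability a random positive outscores a random negative (ties = 1/2).

    Equals the Mann-Whitney U statistic divided by n*m, i.e. the trapezoidal
    area under the ROC curve, and satisfies ``auc = (cliffs_delta + 1) / 2``.
    """
    greater, less, nm = _pair_counts(pos, neg)
    ties = nm - greater - less
    return (greater + 0.5 * ties) / nm


@dataclass
class PercentileCI:
    """Bootstrap percentile interval with the across-iteration mean as point."""

    lower: float
    upper: float
    point: float

    @property
    def excludes_zero(self) -> bool:
        return self.lower > 0.0 or self.upper < 0.0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.point:.3f} [{self.lower:.3f}, {self.upper:.3f}]"


def percentile_ci(samples: np.ndarray, level: float = 0.95) -> PercentileCI:
    """Percentile-method CI (linear-interpolation quantiles); point = mean."""
    s = np.asarray(samples, dtype=float).ravel()
    if s.size < 2:
        raise ValueError("need at least 2 bootstrap samples")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(s, [alpha, 100.0 - alpha])
    return PercentileCI(lower=float(lo), upper=float(hi), point=float(s.mean()))


@dataclass
class EffectSizeResult:
    """Mean Cliff's delta for one region under one HC-vs-group contrast."""

    region: str
    contrast: str
    delta: float
    ci: PercentileCI
    significant: bool


def derive_seed(master_seed: int, *indices: int) -> int:
    """Deterministic per-stage/per-iteration seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, indices)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class BootstrapDeviationResults:
    """Raw per-iteration arrays plus aggregation helpers.

    ``group_means[cohort][group]`` is the (B,) array of that group's mean
    deviation per iteration; ``aucs[cohort][group]`` the per-iteration AUC
    of group vs HC; ``region_deltas[cohort][group]`` a (B, 101) array of
    per-region Cliff's deltas for the same contrast.
    """

    n_iterations: int
    level: float
    region_names: tuple[str, ...]
    group_means: dict[str, dict[str, np.ndarray]]
    mean_differences: dict[str, dict[tuple[str, str], np.ndarray]]
    aucs: dict[str, dict[str, np.ndarray]]
    region_deltas: dict[str, dict[str, np.ndarray]]
    iteration_seeds: list[int] = field(default_factory=list)

    def group_mean_ci(self, cohort: str, group: str) -> PercentileCI:
        return percentile_ci(self.group_means[cohort][group], self.level)

    def difference_ci(self, cohort: str, group_a: str, group_b: str) -> PercentileCI:
        key = (group_a, group_b)
        diffs = self.mean_differences[cohort].get(key)
        if diffs is None:
            diffs = -self.mean_differences[cohort][(group_b, group_a)]
        return percentile_ci(diffs, self.level)

    def auc_ci(self, cohort: str, group: str) -> PercentileCI:
        return percentile_ci(self.aucs[cohort][group], self.level)

    def effect_sizes(self, cohort: str, group: str) -> list[EffectSizeResult]:
        deltas = self.region_deltas[cohort][group]
        out = []
        for j, region in enumerate(self.region_names):
            ci = percentile_ci(deltas[:, j], self.level)
            out.append(EffectSizeResult(
                region=region, contrast=f"{HC_LABEL} vs {group}",
                delta=ci.point, ci=ci, significant=ci.excludes_zero))
        return out

    def deviation_summary(self) -> pd.DataFrame:
        """One row per (cohort, group): mean deviation with CI."""
        rows = []
        for cohort, groups in self.group_means.items():
            for group in groups:
                ci = self.group_mean_ci(cohort, group)
                rows.append({"cohort": cohort, "group": group,
                             "mean_deviation": ci.point,
                             "ci_lower": ci.lower, "ci_upper": ci.upper})
        return pd.DataFrame(rows)

    def auc_summary(self) -> pd.DataFrame:
        rows = []
        for cohort, groups in self.aucs.items():
            for group in groups:
                ci = self.auc_ci(cohort, group)
                rows.append({"cohort": cohort,
                             "contrast": f"{group} vs {HC_LABEL}",
                             "auc": ci.point,
                             "ci_lower": ci.lower, "ci_upper": ci.upper})
        return pd.DataFrame(rows)

    def effect_size_summary(self) -> pd.DataFrame:
        rows = []
        for cohort, groups in self.region_deltas.items():
            for group in groups:
                for es in self.effect_sizes(cohort, group):
                    rows.append({"cohort": cohort, "contrast": es.contrast,
                                 "region": es.region, "delta": es.delta,
                                 "ci_lower": es.ci.lower,
                                 "ci_upper": es.ci.upper,
                                 "significant": es.significant})
        return pd.DataFrame(rows)

    def iteration_table(self) -> pd.DataFrame:
        """Long-format per-iteration record of scalar metrics."""
        rows = []
        for cohort, groups in self.group_means.items():
            for group, vals in groups.items():
                for it, v in enumerate(vals):
                    rows.append({"iteration": it, "cohort": cohort,
                                 "group": group, "metric": "mean_deviation",
                                 "value": float(v)})
        for cohort, groups in self.aucs.items():
            for group, vals in groups.items():
                for it, v in enumerate(vals):
                    rows.append({"iteration": it, "cohort": cohort,
                                 "group": group, "metric": "auc_vs_hc",
                                 "value": float(v)})
        return pd.DataFrame(rows)


def prior_separation_probe(latents: np.ndarray, seed: int = 0,
                           hidden: tuple[int, int] = (100, 100),
                           epochs: int = 40, batch_size: int = 256,
                           lr: float = 1e-3) -> float:
    """Held-out AUC of a fresh discriminator-style probe.

    Trains a new leaky-ReLU MLP classifier to separate the supplied latent
    codes from an equal number of standard-normal prior draws, on half the
    data, and reports its AUC on the other half.  A well-matched latent
    distribution leaves the probe near chance (AUC ~ 0.5); values well
    above it indicate the encoder failed to match the prior.
    """
    H = np.asarray(latents, dtype=float)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal(H.shape)
    X = np.vstack([Z, H])
    y = np.concatenate([np.ones(len(Z)), np.zeros(len(H))])
    perm = rng.permutation(len(X))
    X, y = X[perm], y[perm]
    half = len(X) // 2
    Xtr, ytr, Xte, yte = X[:half], y[:half], X[half:], y[half:]

    probe = MLP((H.shape[1], *hidden, 1), slope=0.01, rng=rng)
    opt = Adam(probe.params())
    for _ in range(epochs):
        order = rng.permutation(half)
        for start in range(0, half, batch_size):
            idx = order[start:start + batch_size]
            a, cache = probe.forward(Xtr[idx], keep_cache=True)
            p = 0.5 * (1.0 + np.tanh(0.5 * a))
            d_a = (p - ytr[idx][:, None]) / a.size
            _, grads = probe.backward(d_a, cache)
            opt.step(probe.flat_grads(grads), lr)
    scores = probe.forward(Xte)[:, 0]
    return auc_from_scores(scores[yte == 1], scores[yte == 0])


def score_cohort(cohort: Cohort, params: AAEParams) -> pd.DataFrame:
    """Per-subject deviation table for one cohort under one trained model."""
    X, Xhat = reconstruct_cohort(cohort, params)
    sq = (X - Xhat) ** 2
    meta = pd.DataFrame({
        "subject_id": [r.subject_id for r in cohort.records],
        "group": cohort.group_labels(),
        "observed_deviation": sq.mean(axis=1),
    })
    regions = pd.DataFrame(sq, columns=[f"dev:{r}" for r in cohort.atlas.names])
    return pd.concat([meta, regions], axis=1)


def bootstrap_normative_evaluation(
    reference: Cohort,
    clinical: list[Cohort],
    config: AAEConfig,
    n_iterations: int = 20,
    seed: int = 0,
    level: float = 0.95,
    train_deficit: int = 0,
    hc_label: str = HC_LABEL,
    progress=None,
) -> BootstrapDeviationResults:
    """Bootstrap the full train-and-score procedure.

    Per iteration: draw a training set of size ``len(reference) -
    train_deficit`` with replacement from the healthy reference, refit the
    robust scaler on it, train a fresh AAE (seeded deterministically from
    ``seed`` and the iteration index), then score every subject of every
    clinical cohort and record group-level metrics.  Each clinical cohort
    must contain an HC group to anchor the contrasts.
    """
    if n_iterations < 1:
        raise ValueError("need at least 1 bootstrap iteration")
    if set(reference.group_labels().tolist()) - {hc_label}:
        raise ValueError("reference cohort must contain HC subjects only")
    for c in clinical:
        if hc_label not in c.groups:
            raise ValueError(f"clinical cohort {c.name!r} lacks an {hc_label} group")

    n_ref = len(reference)
    n_train = n_ref - train_deficit
    if n_train < 4:
        raise ValueError("training-set size after deficit is too small")

    patient_groups = {c.name: [g for g in c.groups if g != hc_label]
                      for c in clinical}
    all_groups = {c.name: c.groups for c in clinical}

    group_means: dict[str, dict[str, list[float]]] = {
        c.name: {g: [] for g in all_groups[c.name]} for c in clinical}
    aucs: dict[str, dict[str, list[float]]] = {
        c.name: {g: [] for g in patient_groups[c.name]} for c in clinical}
    deltas: dict[str, dict[str, list[np.ndarray]]] = {
        c.name: {g: [] for g in patient_groups[c.name]} for c in clinical}
    diffs: dict[str, dict[tuple[str, str], list[float]]] = {
        c.name: {} for c in clinical}
    iteration_seeds = []

    group_masks = {c.name: {g: c.group_labels() == g for g in all_groups[c.name]}
                   for c in clinical}

    for it in range(n_iterations):
        it_seed = derive_seed(seed, it)
        iteration_seeds.append(it_seed)
        rng = np.random.default_rng(it_seed)
        idx = rng.integers(0, n_ref, size=n_train)
        boot = reference.select(idx, name=f"{reference.name}#boot{it}")
        model_config = AAEConfig(**{**config.__dict__, "seed": derive_seed(seed, it, 1)})
        params = train(boot, model_config, hc_label=hc_label)

        for c in clinical:
            X, Xhat = reconstruct_cohort(c, params)
            sq = (X - Xhat) ** 2
            dev = sq.mean(axis=1)
            masks = group_masks[c.name]
            means = {g: float(dev[masks[g]].mean()) for g in all_groups[c.name]}
            for g, m in means.items():
                group_means[c.name][g].append(m)
            glist = all_groups[c.name]
            for i, ga in enumerate(glist):
                for gb in glist[i + 1:]:
                    diffs[c.name].setdefault((ga, gb), []).append(
                        means[ga] - means[gb])
            hc_dev = dev[masks[hc_label]]
            hc_sq = sq[masks[hc_label]]
            for g in patient_groups[c.name]:
                g_dev = dev[masks[g]]
                aucs[c.name][g].append(auc_from_scores(g_dev, hc_dev))
                g_sq = sq[masks[g]]
                d = np.array([cliffs_delta(g_sq[:, j], hc_sq[:, j])
                              for j in range(N_REGIONS)])
                deltas[c.name][g].append(d)
        if progress is not None:
            progress(it)

    return BootstrapDeviationResults(
        n_iterations=n_iterations,
        level=level,
        region_names=reference.atlas.names,
        group_means={c: {g: np.array(v) for g, v in d.items()}
                     for c, d in group_means.items()},
        mean_differences={c: {k: np.array(v) for k, v in d.items()}
                          for c, d in diffs.items()},
        aucs={c: {g: np.array(v) for g, v in d.items()} for c, d in aucs.items()},
        region_deltas={c: {g: np.vstack(v) for g, v in d.items()}
                       for c, d in deltas.items()},
        iteration_seeds=iteration_seeds,
    )
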