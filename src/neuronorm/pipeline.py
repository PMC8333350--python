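"""Pipeline orchestration: configuration, staged commands, run manifest.

The four stages mirror the end-to-end experiment: ``simulate`` writes
synthetic reference/clinical cohort tables, ``train`` fits the normative
AAE on the reference cohort, ``score`` produces a per-subject deviation
table from a saved model, and ``evaluate`` runs the full bootstrap analysis
(normative deviations, effect sizes, AUCs, the RVM 0.632+ baseline,
cross-cohort generalization and the paired AUC-difference CIs).

All randomness flows from one master seed through named stage derivations,
so every stage is replayable in isolation; a JSON manifest records the
config snapshot, per-stage seeds and sha256 checksums of every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aae import AAEConfig, load_model, save_model, train
from .baseline import (
    auc_difference_ci,
    bootstrap_632plus_auc,
    cross_cohort_generalization,
)
from .cohort import RegionAtlas, default_atlas, read_cohort_table, write_cohort_table
from .deviation import bootstrap_normative_evaluation, derive_seed, score_cohort
from .simulate import HC_LABEL, SimulationSpec, default_ad_effect_map, graded_ad_spec

_STAGE_IDS = {"simulate": 1, "train": 2, "score": 3, "evaluate": 4}


@dataclass
class PipelineConfig:
    """Structured configuration with full desk-scale defaults."""

    outdir: str = "neuronorm-run"
    seed: int = 0
    atlas_path: str | None = None
    # simulation
    n_reference: int = 2000
    n_per_group: int = 150
    severities: dict = field(default_factory=lambda: {"EMCI": 0.3, "LMCI": 0.6, "AD": 1.0})
    noise_sd: float = 0.10
    clinical_cohorts: tuple[str, ...] = ("cohortA", "cohortB")
    # model
    aae: AAEConfig = field(default_factory=AAEConfig)
    # evaluation
    n_normative_iterations: int = 20
    n_classifier_iterations: int = 50
    confidence: float = 0.95
    contrasts: tuple[str, ...] = ("EMCI", "LMCI", "AD")

    def __post_init__(self) -> None:
        if self.n_normative_iterations < 1 or self.n_classifier_iterations < 1:
            raise ValueError("iteration counts must be >= 1")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        aae_raw = raw.pop("aae", {})
        cfg = cls(**raw)
        if aae_raw:
            for key in ("encoder_hidden", "decoder_hidden", "discriminator_hidden"):
                if key in aae_raw:
                    aae_raw[key] = tuple(aae_raw[key])
            cfg.aae = AAEConfig(**{**dataclasses.asdict(cfg.aae), **aae_raw})
        return cfg

    def atlas(self) -> RegionAtlas:
        if self.atlas_path:
            return RegionAtlas.from_file(self.atlas_path)
        return default_atlas()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class RunManifest:
    """JSON record of what a run did: config, seeds, stages, outputs."""

    def __init__(self, outdir: Path, config: PipelineConfig):
        self.path = outdir / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {"version": __version__, "config": config.to_dict(),
                         "stages": {}, "outputs": {}}

    def record_stage(self, name: str, seed: int, status: str,
                     outputs: list[Path]) -> None:
        self.data["stages"][name] = {
            "seed": seed, "status": status,
            "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        for p in outputs:
            self.data["outputs"][p.name] = _sha256(p)
        self.path.write_text(json.dumps(self.data, indent=2))


def _stage_seed(config: PipelineConfig, stage: str, *extra: int) -> int:
    return derive_seed(config.seed, _STAGE_IDS[stage], *extra)


def _cohort_paths(config: PipelineConfig, outdir: Path) -> dict[str, Path]:
    paths = {"reference": outdir / "reference.csv"}
    for name in config.clinical_cohorts:
        paths[name] = outdir / f"clinical_{name}.csv"
    return paths


def cmd_simulate(config: PipelineConfig) -> dict[str, Path]:
    """Write the reference cohort, clinical cohorts and ground-truth sidecar."""
    from .simulate import generate_clinical_cohort, generate_reference_cohort

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    atlas = config.atlas()
    paths = _cohort_paths(config, outdir)
    seed = _stage_seed(config, "simulate")

    ref_spec = SimulationSpec(group_sizes={HC_LABEL: config.n_reference},
                              atlas=atlas, noise_sd=config.noise_sd,
                              seed=derive_seed(seed, 0), name="reference")
    write_cohort_table(generate_reference_cohort(ref_spec), paths["reference"])

    truths = {}
    for k, name in enumerate(config.clinical_cohorts):
        spec = graded_ad_spec(n_per_group=config.n_per_group,
                              severities=config.severities, atlas=atlas,
                              seed=derive_seed(seed, 1 + k), name=name)
        spec.noise_sd = config.noise_sd
        cohort, truth = generate_clinical_cohort(spec)
        write_cohort_table(cohort, paths[name])
        truths[name] = truth.to_dict()
    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(json.dumps(truths, indent=2))

    RunManifest(outdir, config).record_stage(
        "simulate", seed, "ok", [*paths.values(), truth_path])
    return paths


def cmd_train(config: PipelineConfig) -> Path:
    """Train the normative AAE on the reference cohort; save the artefact."""
    outdir = Path(config.outdir)
    atlas = config.atlas()
    ref = read_cohort_table(_cohort_paths(config, outdir)["reference"], atlas)
    seed = _stage_seed(config, "train")
    aae_config = dataclasses.replace(config.aae, seed=seed)
    params = train(ref, aae_config)
    model_path = outdir / "model.npz"
    save_model(params, model_path)
    log_path = outdir / "training_log.csv"
    pd.DataFrame(params.training_log).to_csv(log_path, index=False)
    RunManifest(outdir, config).record_stage(
        "train", seed, "ok", [model_path, log_path])
    return model_path


def cmd_score(config: PipelineConfig, model_path: str | Path,
              cohort_path: str | Path, out_path: str | Path | None = None) -> Path:
    """Score a cohort with a saved model; write the deviation table."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    atlas = config.atlas()
    params = load_model(model_path)  # checksum verified here
    cohort = read_cohort_table(cohort_path, atlas)
    table = score_cohort(cohort, params)
    out = Path(out_path) if out_path else outdir / f"deviations_{Path(cohort_path).stem}.csv"
    table.to_csv(out, index=False)
    RunManifest(outdir, config).record_stage(
        "score", _stage_seed(config, "score"), "ok", [out])
    return out


def cmd_evaluate(config: PipelineConfig) -> dict[str, Path]:
    """Run the full bootstrap evaluation; write summary tables."""
    outdir = Path(config.outdir)
    atlas = config.atlas()
    paths = _cohort_paths(config, outdir)
    reference = read_cohort_table(paths["reference"], atlas)
    clinical = {name: read_cohort_table(paths[name], atlas, name=name)
                for name in config.clinical_cohorts}
    seed = _stage_seed(config, "evaluate")

    norm = bootstrap_normative_evaluation(
        reference, list(clinical.values()), config.aae,
        n_iterations=config.n_normative_iterations,
        seed=derive_seed(seed, 0), level=config.confidence)

    outputs: dict[str, Path] = {}
    outputs["deviation_summary"] = outdir / "deviation_summary.csv"
    norm.deviation_summary().to_csv(outputs["deviation_summary"], index=False)
    outputs["auc_summary"] = outdir / "auc_summary.csv"
    norm.auc_summary().to_csv(outputs["auc_summary"], index=False)
    outputs["effect_sizes"] = outdir / "effect_sizes.csv"
    norm.effect_size_summary().to_csv(outputs["effect_sizes"], index=False)
    outputs["iterations"] = outdir / "iteration_metrics.csv"
    norm.iteration_table().to_csv(outputs["iterations"], index=False)

    # classifier arm: 0.632+ per cohort and contrast, keeping models for
    # the cross-cohort generalization matrix on the most severe contrast
    clf_rows = []
    diff_rows = []
    kept: dict[str, object] = {}
    severe = config.contrasts[-1]
    for k, (name, cohort) in enumerate(clinical.items()):
        for j, group in enumerate(config.contrasts):
            if group not in cohort.groups:
                continue
            res = bootstrap_632plus_auc(
                cohort, (HC_LABEL, group),
                n_iterations=config.n_classifier_iterations,
                seed=derive_seed(seed, 1, k, j), level=config.confidence,
                keep_models=(group == severe))
            if group == severe:
                kept[name] = res
            clf_rows.append({
                "cohort": name, "contrast": f"{group} vs {HC_LABEL}",
                "auc_632plus": res.auc_bootstrap,
                "ci_lower": res.ci.lower, "ci_upper": res.ci.upper,
                "mean_omega": float(res.omega.mean()),
                "pool_size": res.pool_size,
            })
            # paired difference vs the normative AUC (truncated to the
            # common iteration count)
            n_pair = min(len(res.blended), norm.n_iterations)
            ci, sig = auc_difference_ci(
                res.blended[:n_pair], norm.aucs[name][group][:n_pair],
                level=config.confidence)
            diff_rows.append({
                "cohort": name, "contrast": f"{group} vs {HC_LABEL}",
                "auc_diff_classifier_minus_normative": ci.point,
                "ci_lower": ci.lower, "ci_upper": ci.upper,
                "significant": sig,
            })

    outputs["classifier_auc"] = outdir / "classifier_auc.csv"
    pd.DataFrame(clf_rows).to_csv(outputs["classifier_auc"], index=False)
    outputs["auc_differences"] = outdir / "auc_differences.csv"
    pd.DataFrame(diff_rows).to_csv(outputs["auc_differences"], index=False)

    if len(kept) >= 2:
        matrix = cross_cohort_generalization(kept, clinical, severe,
                                             level=config.confidence)
        outputs["generalization"] = outdir / f"generalization_{severe}.csv"
        matrix.to_frame().to_csv(outputs["generalization"])

    RunManifest(outdir, config).record_stage(
        "evaluate", seed, "ok", list(outputs.values()))
    return outputs
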