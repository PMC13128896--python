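"""End-to-end orchestration: simulate/load -> select -> train -> predict ->
explain -> phases -> evaluate, with a run manifest for reproducibility.

Every stage writes its artifacts under the output directory and can be
re-entered from those artifacts via the CLI; a failed stage raises
``StageError`` naming the stage while earlier artifacts are retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attribution import AgeBinProfile, bin_profiles, explain, sample_background, select_extreme_cpgs
from .config import PipelineConfig
from .evaluation import calibration_metrics
from .io import (
    BetaMatrix,
    SampleMeta,
    SEX_FEMALE,
    SEX_MALE,
    impute_missing,
    read_beta_matrix,
    read_sample_meta,
    write_beta_matrix,
    write_sample_meta,
)
from .model import LocoEnsemble, loco_train, make_design, predict_age
from .phases import SupportedDendrogram, compare_sex_phases, cut_phases, multiscale_bootstrap
from .selection import select_features, stratum_correlations
from .simulate import simulate_cohort

__all__ = ["run_pipeline", "StageError"]

logger = logging.getLogger(__name__)

SEX_GROUPS = {"male": SEX_MALE, "female": SEX_FEMALE}


class StageError(RuntimeError):
    """A pipeline stage failed; partial artifacts are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _log_stage(log_path: Path, record: dict) -> None:
    with open(log_path, "a") as fh:
        fh.write(json.dumps(record) + "\n")


def _subset_profile_matrix(profile: AgeBinProfile, bins: list[str]) -> pd.DataFrame:
    return profile.signed_frame().loc[bins]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the artifact directory.

    Re-running with the same config and seed reproduces all numeric
    artifacts bit-for-bit.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "stages.jsonl"
    manifest: dict = {
        "package_version": __version__,
        "global_seed": config.seed,
        "stage_seeds": {},
        "artifacts": {},
    }
    (out / "config.yaml").write_text(config.to_yaml())

    def finish(stage: str, *paths: Path) -> None:
        for p in paths:
            manifest["artifacts"][str(p.relative_to(out))] = _sha256(p)
        _log_stage(log_path, {"stage": stage, "status": "ok",
                              "artifacts": [str(p.relative_to(out)) for p in paths]})

    # ---- stage: simulate / load ----------------------------------------
    stage = "simulate"
    manifest["stage_seeds"][stage] = config.stage_seed(stage)
    try:
        if config.synthetic is not None:
            from dataclasses import replace

            sim = replace(config.synthetic, seed=config.stage_seed(stage))
            beta, meta, truth = simulate_cohort(sim)
            beta_path, meta_path = out / "beta.tsv", out / "meta.csv"
            write_beta_matrix(beta, beta_path)
            write_sample_meta(meta, meta_path)
            truth.to_json(out / "truth.json")
            finish(stage, beta_path, meta_path, out / "truth.json")
        else:
            beta = read_beta_matrix(config.inputs["beta"])
            meta = read_sample_meta(config.inputs["meta"])
            manifest["artifacts"]["input_beta"] = _sha256(Path(config.inputs["beta"]))
            manifest["artifacts"]["input_meta"] = _sha256(Path(config.inputs["meta"]))
            _log_stage(log_path, {"stage": stage, "status": "ok", "loaded": True})
        if np.isnan(beta.values).any():
            beta = impute_missing(beta, "probe_mean")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: feature selection --------------------------------------
    stage = "select_features"
    manifest["stage_seeds"][stage] = config.stage_seed(stage)
    try:
        table = stratum_correlations(beta, meta, config.stratum_scheme)
        table.write(out / "correlations.tsv")
        features = select_features(table, config.selection_fraction)
        features.write(out / "features.txt", out / "feature_provenance.tsv")
        finish(stage, out / "correlations.tsv", out / "features.txt", out / "feature_provenance.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: LOCO training ------------------------------------------
    stage = "train"
    manifest["stage_seeds"][stage] = config.stage_seed(stage)
    try:
        X, ages = make_design(beta, meta, features)
        from dataclasses import replace

        model_config = replace(config.model, seed=config.stage_seed(stage))
        ensemble = loco_train(X, ages, meta.cohort, model_config, always_train=config.always_train)
        ensemble.save(out / "model")
        mae = pd.DataFrame(
            {
                "held_out_cohort": list(ensemble.held_out_mae),
                "held_out_mae": list(ensemble.held_out_mae.values()),
                "internal_test_mae": [ensemble.internal_test_mae.get(c) for c in ensemble.held_out_mae],
            }
        )
        mae.to_csv(out / "loco_mae.csv", index=False)
        finish(stage, out / "loco_mae.csv", out / "model" / "ensemble.json")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: prediction + evaluation --------------------------------
    stage = "predict"
    manifest["stage_seeds"][stage] = config.stage_seed(stage)
    try:
        predicted = predict_age(ensemble, X)
        pred_frame = pd.DataFrame({"sample_id": meta.sample_id, "predicted_age": predicted})
        pred_frame.to_csv(out / "predictions.csv", index=False)
        finish(stage, out / "predictions.csv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "evaluate"
    manifest["stage_seeds"][stage] = config.stage_seed(stage)
    try:
        report = calibration_metrics(predicted, meta.age)
        (out / "calibration.json").write_text(json.dumps(report.to_dict(), indent=2))
        finish(stage, out / "calibration.json")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: attribution --------------------------------------------
    stage = "explain"
    seed = config.stage_seed(stage)
    manifest["stage_seeds"][stage] = seed
    try:
        background = sample_background(X, config.background_size, seed)
        attr = explain(ensemble, X, background, n_steps=config.attribution_steps, seed=seed)
        attr.write(out / "attributions.tsv", out / "attributions.json")
        profile = bin_profiles(attr, meta, config.bin_scheme)
        profile.write(out / "bin_profiles.tsv")
        k = min(config.extreme_k, len(features))
        mean_mag = profile.mean_magnitude(drop=["sex"])
        top, bottom = select_extreme_cpgs(mean_mag, k)
        (out / "top_cpgs.txt").write_text("\n".join(top) + "\n")
        (out / "bottom_cpgs.txt").write_text("\n".join(bottom) + "\n")
        finish(stage, out / "attributions.tsv", out / "bin_profiles.tsv",
               out / "top_cpgs.txt", out / "bottom_cpgs.txt")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: phases --------------------------------------------------
    stage = "phases"
    seed = config.stage_seed(stage)
    manifest["stage_seeds"][stage] = seed
    try:
        tree = multiscale_bootstrap(
            profile, scales=config.bootstrap_scales, n_bootstrap=config.bootstrap_n, seed=seed
        )
        tree.to_json(out / "dendrogram.json")
        (out / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
        assignment = cut_phases(tree, height=config.cut_height, k=config.cut_k)
        assignment.write(out / "phases.csv")
        artifacts = [out / "dendrogram.json", out / "dendrogram.nwk", out / "phases.csv"]
        summary = {
            "cut_height": assignment.cut_height,
            "n_phases": assignment.n_phases,
            "supported_phases": assignment.supported_count(),
        }
        if config.by_sex_phases:
            group_profiles: dict[str, AgeBinProfile] = {}
            for group, code in SEX_GROUPS.items():
                sub = meta.subset(meta.sex == code)
                if len(sub) == 0:
                    continue
                keep = set(sub.sample_id)
                rows = [i for i, s in enumerate(attr.sample_ids) if s in keep]
                from dataclasses import replace as dc_replace

                sub_attr = dc_replace(
                    attr,
                    values=attr.values[rows],
                    sample_ids=[attr.sample_ids[i] for i in rows],
                )
                group_profiles[group] = bin_profiles(sub_attr, sub, config.bin_scheme)
            common = [
                b for b in profile.bin_labels
                if all(b in p.bin_labels for p in group_profiles.values())
            ]
            if len(common) >= 2 and len(group_profiles) == 2:
                trees = {
                    g: multiscale_bootstrap(
                        _subset_profile_matrix(p, common),
                        scales=config.bootstrap_scales,
                        n_bootstrap=config.bootstrap_n,
                        seed=seed,
                    )
                    for g, p in group_profiles.items()
                }
                comparison = compare_sex_phases(trees, assignment.cut_height)
                for group, (assign_g, supported) in comparison.items():
                    assign_g.write(out / f"phases_{group}.csv")
                    trees[group].to_json(out / f"dendrogram_{group}.json")
                    artifacts += [out / f"phases_{group}.csv", out / f"dendrogram_{group}.json"]
                    summary[f"supported_phases_{group}"] = supported
        (out / "phase_summary.json").write_text(json.dumps(summary, indent=2))
        artifacts.append(out / "phase_summary.json")
        finish(stage, *artifacts)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
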