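"""End-to-end pipeline: data → split → baseline → prune → SMOTE →
augmentation balancing → optional Avg-TopK pooling surgery → final train →
evaluation.

Stage order is fixed (pruning first — it fixes the architecture; SMOTE on
the training split only; augmentation last), matching the ablation
sequence Pruning → SMOTE → Augmentation.  Every stochastic stage derives
its seed deterministically from the global seed plus the stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import engine
from .augment import AugmentConfig, balance_with_augmentation
from .graph import XceptionConfig, build_xception, parameter_count
from .pooling import replace_max_pooling
from .pruning import SparsityConfig, attach_classifier_head, profile_model, select_profiled_cut, truncate
from .resampling import ImbalanceStrategy, SmoteConfig, resample
from .synthetic import SyntheticSpec, generate_dataset, manifest
from .training import TrainConfig, compute_metrics, predict_labels, split_train_test, train

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    data_dir: str | None = None
    model: XceptionConfig = field(default_factory=XceptionConfig)
    sparsity: SparsityConfig = field(default_factory=SparsityConfig)
    strategy: ImbalanceStrategy = field(default_factory=lambda: ImbalanceStrategy("multiplier", 2))
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    pooling_k: int | None = 3
    train_fraction: float = 0.8
    seed: int = 0
    output_dir: str = "runs/run"
    skip_stages: tuple = ()  # any of {"prune", "resample", "augment", "pooling"}

    def resolved(self) -> dict:
        def enc(v):
            if dataclasses.is_dataclass(v):
                return {f.name: enc(getattr(v, f.name)) for f in dataclasses.fields(v)}
            if isinstance(v, (tuple, list)):
                return [enc(x) for x in v]
            return v

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        sections = {
            "synthetic": SyntheticSpec, "model": XceptionConfig, "sparsity": SparsityConfig,
            "smote": SmoteConfig, "augment": AugmentConfig, "training": TrainConfig,
        }
        for key, val in raw.items():
            if key in sections:
                if isinstance(val, dict):
                    for tup in ("class_counts", "class_names", "candidate_kinds"):
                        if tup in val:
                            val[tup] = tuple(val[tup])
                    kw[key] = sections[key](**val)
                else:
                    kw[key] = val
            elif key == "strategy":
                kw[key] = ImbalanceStrategy.parse(val) if isinstance(val, str) else ImbalanceStrategy(**val)
            elif key == "skip_stages":
                kw[key] = tuple(val)
            else:
                kw[key] = val
        return cls(**kw)


def _save_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage, writing one artifact per stage into the run dir.

    Artifacts: resolved config, dataset manifests, backbone graph JSON,
    sparsity profile CSV, pruned graph + prune-result JSON, training
    histories CSV, final metrics JSON.  Any stage failure re-raises with
    the stage name; artifacts written so far are left in place.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    _save_json(out / "config.json", config.resolved())
    stage = "setup"
    try:
        # ------------------------------------------------------------ data
        stage = "data"
        if config.data_dir:
            from .io import read_image_directory

            dataset = read_image_directory(config.data_dir)
        else:
            spec = dataclasses.replace(config.synthetic, seed=stage_seed(config.seed, "data"))
            dataset = generate_dataset(spec)
        manifest(dataset).to_csv(out / "dataset_manifest.csv", index=False)

        stage = "split"
        train_set, test_set = split_train_test(dataset, config.train_fraction,
                                               stage_seed(config.seed, "split"))

        # ------------------------------------------------ baseline training
        stage = "baseline_train"
        graph = build_xception(config.model)
        (out / "graph.json").write_text(graph.to_json())
        tcfg = dataclasses.replace(config.training, seed=stage_seed(config.seed, "baseline"))
        weights = engine.init_weights(graph, seed=tcfg.seed)
        weights, base_history = train(graph, weights, train_set, tcfg)
        pd.DataFrame({k: v for k, v in base_history.items() if isinstance(v, list)}).to_csv(
            out / "baseline_history.csv", index=False)

        # ------------------------------------------------------------ prune
        current_graph, current_weights = graph, weights
        if "prune" not in config.skip_stages:
            stage = "profile"
            rng = np.random.default_rng(stage_seed(config.seed, "profile"))
            idx = rng.choice(len(train_set), size=min(config.sparsity.batch_size, len(train_set)),
                             replace=False)
            batch = train_set.features[idx].astype(float) / 255.0
            profile = profile_model(graph, weights, batch, config.sparsity)
            pd.DataFrame(profile.entries, columns=["layer_id", "sparsity"]).to_csv(
                out / "sparsity_profile.csv", index=False)

            stage = "prune"
            cut = select_profiled_cut(graph, profile)
            backbone = truncate(graph, cut)
            pruned = attach_classifier_head(backbone, dataset.n_classes)
            (out / "pruned_graph.json").write_text(pruned.to_json())
            _save_json(out / "prune_result.json", {
                "cut_layer_id": cut,
                "parameters_before": parameter_count(graph),
                "parameters_after": parameter_count(pruned),
            })
            stage = "retrain"
            rcfg = dataclasses.replace(config.training, seed=stage_seed(config.seed, "retrain"))
            pruned_weights = engine.init_weights(pruned, seed=rcfg.seed)
            pruned_weights, retrain_history = train(pruned, pruned_weights, train_set, rcfg)
            pd.DataFrame({k: v for k, v in retrain_history.items() if isinstance(v, list)}).to_csv(
                out / "retrain_history.csv", index=False)
            current_graph, current_weights = pruned, pruned_weights

        # --------------------------------------------------------- resample
        final_train = train_set
        if "resample" not in config.skip_stages:
            stage = "resample"
            scfg = dataclasses.replace(config.smote, seed=stage_seed(config.seed, "resample"))
            final_train = resample(final_train, config.strategy, scfg)
            manifest(final_train).to_csv(out / "resampled_manifest.csv", index=False)

        # ---------------------------------------------------------- augment
        if "augment" not in config.skip_stages:
            stage = "augment"
            counts = final_train.class_counts()
            final_train = balance_with_augmentation(
                final_train, np.full_like(counts, counts.max()), config.augment,
                seed=stage_seed(config.seed, "augment"))
            manifest(final_train).to_csv(out / "augmented_manifest.csv", index=False)

        # ---------------------------------------------------------- pooling
        if config.pooling_k and "pooling" not in config.skip_stages:
            stage = "pooling"
            current_graph = replace_max_pooling(current_graph, config.pooling_k)
            (out / "pooled_graph.json").write_text(current_graph.to_json())

        # ------------------------------------------------------ final train
        stage = "final_train"
        fcfg = dataclasses.replace(config.training, seed=stage_seed(config.seed, "final"))
        final_weights = engine.init_weights(current_graph, seed=fcfg.seed)
        final_weights, final_history = train(current_graph, final_weights, final_train, fcfg)
        pd.DataFrame({k: v for k, v in final_history.items() if isinstance(v, list)}).to_csv(
            out / "final_history.csv", index=False)

        # --------------------------------------------------------- evaluate
        stage = "evaluate"
        preds = predict_labels(current_graph, final_weights, test_set.features)
        report = compute_metrics(test_set.labels, preds, dataset.n_classes,
                                 epochs_run=len(final_history["epoch"]),
                                 stopped_epoch=final_history["stopped_epoch"])
        _save_json(out / "metrics.json", report.as_dict())
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
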