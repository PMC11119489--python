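"""End-to-end orchestration: generate -> extract -> stats -> classify -> interpret.

A run is driven by a single JSON/YAML config and a root seed; every stage's
randomness is derived from that seed, outputs are CSV/JSON files in the run
directory, and a manifest records config, seeds, per-stage status and output
hashes.  Stages whose outputs already exist with matching hashes are skipped
on re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import LeavePairOutEvaluator
from .extraction import LAC_STAT_COLUMNS, UNION_WINDOW, VesicleExtractor
from .interpret import clustered_importance, embed_cells, embed_vesicles
from .stats import compare_feature_table
from .synthetic import GeneratorConfig, default_config, generate_vesicle_features, iter_cohort_phantoms

log = logging.getLogger("sxt_celltyper")


@dataclass
class PipelineConfig:
    """Run-level options (generator overrides live under ``generator``)."""

    out_dir: str = "run"
    seed: int = 20240518
    voxel_phantoms: bool = False  # feature-table mode by default (desk-scale)
    n_alpha: int | None = None  # cohort overrides for quick runs
    n_beta: int | None = None
    vesicles_per_cell: float | None = None
    voxel_size: float | None = None
    lac_window: tuple[float, float] = UNION_WINDOW
    max_vesicles_per_cell: int | None = 50  # classifier-stage tuning subsample
    families: tuple[str, ...] = ("logistic_regression", "random_forest", "xgboost")
    embed_max_rows: int = 3000
    importance_repeats: int = 10

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "lac_window" in data:
            data["lac_window"] = tuple(data["lac_window"])
        if "families" in data:
            data["families"] = tuple(data["families"])
        return cls(**data)

    def generator_config(self) -> GeneratorConfig:
        cfg = default_config(seed=self.seed)
        if self.voxel_size is not None:
            cfg.voxel_size = self.voxel_size
        if self.n_alpha is not None:
            cfg.alpha = dataclasses.replace(cfg.alpha, n_cells=self.n_alpha)
        if self.n_beta is not None:
            cfg.beta = dataclasses.replace(cfg.beta, n_cells=self.n_beta)
        if self.vesicles_per_cell is not None:
            cfg.alpha = dataclasses.replace(
                cfg.alpha, vesicle_count=(self.vesicles_per_cell, self.vesicles_per_cell * 0.2)
            )
            cfg.beta = dataclasses.replace(
                cfg.beta, vesicle_count=(self.vesicles_per_cell, self.vesicles_per_cell * 0.2)
            )
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    stages: dict = field(default_factory=dict)  # stage -> {status, outputs: {file: hash}}

    def record(self, stage: str, status: str, outputs: dict[str, str]):
        self.stages[stage] = {"status": status, "outputs": outputs}

    def save(self, path: Path):
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        data = json.loads(path.read_text())
        return cls(**data)


def _stage_fresh(manifest: RunManifest | None, stage: str, out_dir: Path) -> bool:
    """True when a previous run left this stage's outputs intact."""
    if manifest is None or stage not in manifest.stages:
        return False
    rec = manifest.stages[stage]
    if rec.get("status") != "ok":
        return False
    for rel, digest in rec["outputs"].items():
        p = out_dir / rel
        if not p.exists() or _sha256(p) != digest:
            return False
    return True


def run_pipeline(config: PipelineConfig | str | Path, resume: bool = True) -> RunManifest:
    """Execute all stages in order; any stage error aborts with a partial manifest."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    previous = RunManifest.load(manifest_path) if (resume and manifest_path.exists()) else None

    manifest = RunManifest(
        config=dataclasses.asdict(config), seed=config.seed, version=__version__
    )
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(name)s: %(message)s")
    gen_cfg = config.generator_config()
    seeds = np.random.SeedSequence(config.seed).spawn(8)
    stage_seed = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ["generate", "extract", "classify", "importance", "embed"], seeds
        )
    }

    def finish(stage, outputs):
        manifest.record(
            stage, "ok", {rel: _sha256(out_dir / rel) for rel in outputs}
        )
        manifest.save(manifest_path)
        log.info("stage %s: ok (%d outputs)", stage, len(outputs))

    try:
        # -- generate -----------------------------------------------------
        stage = "generate"
        outputs = ["vesicle_features.csv", "cells.csv"]
        if _stage_fresh(previous, stage, out_dir):
            manifest.stages[stage] = previous.stages[stage]
            log.info("stage %s: skipped (outputs fresh)", stage)
        else:
            features, cells = generate_vesicle_features(gen_cfg, stage_seed["generate"])
            features.to_csv(out_dir / "vesicle_features.csv", index=False)
            cells.to_csv(out_dir / "cells.csv", index=False)
            if config.voxel_phantoms:
                vol_dir = out_dir / "volumes"
                for vol, _truth in iter_cohort_phantoms(gen_cfg, stage_seed["generate"]):
                    vol.save(vol_dir)
                outputs = outputs  # volumes are bulky; hashed outputs stay CSV-only
            finish(stage, outputs)
        features = pd.read_csv(out_dir / "vesicle_features.csv")
        cells = pd.read_csv(out_dir / "cells.csv")

        # -- extract (only when voxel phantoms were produced) --------------
        if config.voxel_phantoms:
            stage = "extract"
            outputs = ["extracted_features.csv", "cell_metrics.csv"]
            if _stage_fresh(previous, stage, out_dir):
                manifest.stages[stage] = previous.stages[stage]
            else:
                extractor = VesicleExtractor(lac_window=config.lac_window)
                feats, mets = extractor.transform_with_metrics(
                    vol
                    for vol, _ in iter_cohort_phantoms(gen_cfg, stage_seed["generate"])
                )
                feats.to_csv(out_dir / "extracted_features.csv", index=False)
                mets.to_csv(out_dir / "cell_metrics.csv", index=False)
                finish(stage, outputs)
            features = pd.read_csv(out_dir / "extracted_features.csv")

        # -- stats ----------------------------------------------------------
        stage = "stats"
        if _stage_fresh(previous, stage, out_dir):
            manifest.stages[stage] = previous.stages[stage]
        else:
            comparison = compare_feature_table(
                features, LAC_STAT_COLUMNS + ["diameter"], with_eta=True
            )
            comparison.to_csv(out_dir / "vesicle_comparisons.csv", index=False)
            finish(stage, ["vesicle_comparisons.csv"])

        # -- classify -------------------------------------------------------
        stage = "classify"
        outputs = ["classification_combinations.csv", "classification_aggregate.csv", "cell_calls.csv"]
        if _stage_fresh(previous, stage, out_dir):
            manifest.stages[stage] = previous.stages[stage]
        else:
            evaluator = LeavePairOutEvaluator(
                families=config.families,
                max_vesicles_per_cell=config.max_vesicles_per_cell,
                seed=stage_seed["classify"],
            )
            report = evaluator.evaluate(features)
            report.per_combination.to_csv(out_dir / "classification_combinations.csv", index=False)
            report.aggregate.to_csv(out_dir / "classification_aggregate.csv", index=False)
            report.cell_calls.to_csv(out_dir / "cell_calls.csv", index=False)
            finish(stage, outputs)

        # -- interpret ------------------------------------------------------
        stage = "interpret"
        outputs = ["importance.csv", "feature_clusters.json", "vesicle_embedding.csv", "cell_embedding.csv"]
        if _stage_fresh(previous, stage, out_dir):
            manifest.stages[stage] = previous.stages[stage]
        else:
            imp = clustered_importance(
                features,
                seed=stage_seed["importance"],
                n_repeats=config.importance_repeats,
                max_vesicles_per_cell=config.max_vesicles_per_cell,
                tune=False,
            )
            imp.averaged.to_csv(out_dir / "importance.csv", index=False)
            (out_dir / "feature_clusters.json").write_text(
                json.dumps(
                    {
                        "clusters": imp.clusters,
                        "representatives": list(imp.representatives),
                        "accuracy_threshold": imp.accuracy_threshold,
                        "n_qualifying": imp.n_qualifying,
                    },
                    indent=2,
                )
            )
            rows = features
            if len(rows) > config.embed_max_rows:
                rows = rows.sample(
                    n=config.embed_max_rows, random_state=stage_seed["embed"] % (2**31)
                )
            emb = embed_vesicles(rows.reset_index(drop=True), seed=stage_seed["embed"])
            emb.frame()[["x", "y", "vesicle_id", "cell_id", "cell_class"]].to_csv(
                out_dir / "vesicle_embedding.csv", index=False
            )
            cell_features = cells.rename(columns={"n_vesicles": "vesicle_count"})
            n_cells = len(cell_features)
            cell_emb = embed_cells(
                cell_features, seed=stage_seed["embed"], n_neighbors=min(4, n_cells - 1)
            )
            cell_emb.frame().to_csv(out_dir / "cell_embedding.csv", index=False)
            finish(stage, outputs)
    except Exception as exc:
        manifest.record(stage, f"error: {exc}", {})
        manifest.save(manifest_path)
        raise RuntimeError(f"pipeline aborted in stage {stage!r}: {exc}") from exc

    return manifest
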