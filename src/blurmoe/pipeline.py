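"""End-to-end orchestration: synthesise → QC → calibrate → train →
sweep → gate → benchmark, with every artifact written to disk.

Artifacts embed the package version, a config hash and the seed, and all
stages derive their randomness from the single top-level seed, so a rerun
with the same config produces bit-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .benchmark import (
    DEFAULT_EXPERT_SIGMAS,
    DEFAULT_VALIDATION_GRID,
    blur_sensitivity_sweep,
    scenario_benchmark,
)
from .calibration import (
    DEFAULT_SIGMA_GRID,
    calibrate_sigma_to_lv,
    derive_lv_thresholds,
    select_expert_ranges,
)
from .experts import TrainConfig, train_attention_expert, train_tile_expert
from .manifest import read_manifest, write_manifest
from .sharpness import compute_bag_sharpness, qc_filter
from .synthetic import SyntheticConfig, generate_cohort, make_cv_splits

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("blurmoe")


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full pipeline run.

    ``manifest`` may point at an existing cohort; otherwise a synthetic
    cohort is generated from ``synthetic``.  ``expert_sigmas`` defaults to
    the baseline-plus-ten-blur-levels ensemble; ``validation_grid`` to the
    15-level evaluation grid.
    """

    out_dir: str = "blurmoe_run"
    manifest: str | None = None
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    lv_qc_threshold: float = 500.0
    calibration_grid: tuple[float, ...] = DEFAULT_SIGMA_GRID
    calibration_sample: int = 500
    expert_sigmas: tuple[float, ...] = DEFAULT_EXPERT_SIGMAS
    validation_grid: tuple[float, ...] = DEFAULT_VALIDATION_GRID
    scenario_ids: tuple[int, ...] = tuple(range(1, 13))
    track: str = "simple"
    k_folds: int = 5
    train: TrainConfig = field(default_factory=TrainConfig)

    def config_hash(self) -> str:
        # out_dir is an environment detail, not scientific configuration:
        # reruns into different directories must hash (and replay) the same
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    return {
        "tool_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a dict of artifact paths.

    Stage failures raise with the stage name prefixed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.track not in ("simple", "attention"):
        raise ValueError(f"unknown track {config.track!r}")
    artifacts: dict[str, Path] = {}
    stage = "load"
    try:
        # ---------------- cohort ----------------
        if config.manifest is not None:
            stage = "read-manifest"
            cohort = read_manifest(config.manifest)
        else:
            stage = "make-synthetic"
            syn = dataclasses.replace(config.synthetic, seed=config.seed)
            cohort = generate_cohort(syn)
        log.info("stage=%s slides=%d", stage, len(cohort))

        stage = "qc"
        qc_reports = []
        for bag in cohort.bags:
            compute_bag_sharpness(bag)
            filtered, rep = qc_filter(bag, config.lv_qc_threshold)
            qc_reports.append(rep)
            bag.tiles = filtered.tiles
        qc_path = out / "qc_report.json"
        _write_json(qc_path, {
            **_provenance(config),
            "lv_threshold": config.lv_qc_threshold,
            "slides": [
                {"slide_id": r.slide_id, "n_kept": r.n_kept,
                 "n_rejected": len(r.rejected),
                 "rejected": [[s.tile_id, s.theta] for s in r.rejected],
                 "empty_after_filter": r.empty_after_filter}
                for r in qc_reports
            ],
        })
        artifacts["qc_report"] = qc_path
        log.info("stage=qc rejected=%d", sum(len(r.rejected) for r in qc_reports))

        stage = "cv-split"
        splits = make_cv_splits(cohort.patient_ids, cohort.labels,
                                k=config.k_folds, seed=config.seed)

        stage = "calibrate"
        all_tiles = [t.image for b in cohort.bags for t in b.tiles]
        calib = calibrate_sigma_to_lv(
            all_tiles, config.calibration_grid,
            n_sample=min(config.calibration_sample, len(all_tiles)),
            seed=config.seed,
        )
        calib_path = out / "calibration.json"
        _write_json(calib_path, {**_provenance(config),
                                 **json.loads(calib.to_json())})
        artifacts["calibration"] = calib_path
        log.info("stage=calibrate n_tiles=%d", calib.n_tiles_sampled)

        stage = "train-experts"
        trainer = (train_tile_expert if config.track == "simple"
                   else train_attention_expert)
        fold_experts = []
        for f, (tr_ids, _) in enumerate(splits):
            train_bags = cohort.subset(tr_ids).bags
            experts = {}
            for s in config.expert_sigmas:
                eid = f"E{s:g}"
                experts[eid] = trainer(
                    train_bags, sigma=s, config=config.train,
                    seed=int(np.random.default_rng([config.seed, f]).integers(2**31)),
                    expert_id=eid,
                )
            fold_experts.append(experts)
        experts_path = out / "experts.json"
        _write_json(experts_path, {
            **_provenance(config),
            "folds": [
                {eid: json.loads(ex.to_json()) for eid, ex in experts.items()}
                for experts in fold_experts
            ],
        })
        artifacts["experts"] = experts_path
        log.info("stage=train-experts n=%d folds=%d",
                 len(config.expert_sigmas), len(splits))

        stage = "sweep"
        fold_val_bags = [cohort.subset(va_ids).bags for _, va_ids in splits]
        matrix = blur_sensitivity_sweep(fold_experts, fold_val_bags,
                                        config.validation_grid)
        sweep_path = out / "sensitivity.csv"
        matrix.table.to_csv(sweep_path, float_format="%.17g")
        artifacts["sensitivity"] = sweep_path
        log.info("stage=sweep cells=%d", matrix.table.size)

        stage = "derive-gates"
        train_sigmas = {f"E{s:g}": float(s) for s in config.expert_sigmas}
        ranges = select_expert_ranges(matrix.table, train_sigmas)
        gating = derive_lv_thresholds(calib, ranges)
        gates_path = out / "gates.json"
        _write_json(gates_path, {
            **_provenance(config),
            "ranges": ranges.entries,
            **json.loads(gating.to_json()),
        })
        artifacts["gates"] = gates_path
        log.info("stage=derive-gates m=%d", len(gating.expert_ids))

        stage = "benchmark"
        baselines = [experts["E0"] for experts in fold_experts]
        report = scenario_benchmark(
            baselines, fold_experts, [gating] * len(splits), fold_val_bags,
            scenario_ids=config.scenario_ids, seed=config.seed,
            track=config.track,
        )
        scen_path = out / "scenarios.csv"
        report.per_fold.to_csv(scen_path, index=False, float_format="%.17g")
        artifacts["scenarios"] = scen_path
        log.info("stage=benchmark scenarios=%d", len(config.scenario_ids))

        stage = "write-config"
        cfg_path = out / "run_config.json"
        cfg_payload = dataclasses.asdict(config)
        cfg_payload.pop("out_dir", None)
        _write_json(cfg_path, {**_provenance(config), "config": cfg_payload})
        artifacts["run_config"] = cfg_path
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return {k: str(v) for k, v in artifacts.items()}
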