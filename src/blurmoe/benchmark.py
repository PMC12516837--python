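"""Evaluation harness: AUC, cross-blur sensitivity sweeps, the 12-scenario
MoE-vs-baseline comparison, and the blurriest-slides subset selection.

The sensitivity sweep reproduces the crossing pattern that motivates the
mixture of experts: a baseline trained on sharp tiles degrades
monotonically with validation blur while blur-trained experts peak near
their training sigma.  The scenario benchmark then quantifies what the
LV-gated mixture buys over the baseline when slides mix blur levels:
both systems see the *identical* blurred validation tiles (shared
scenario draw), so per-scenario deltas isolate the modelling strategy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blur import SCENARIOS, BlurScenario, assign_scenario_blur
from .calibration import GatingTable
from .experts import (
    TrainedExpert,
    extract_bag_features,
    predict_bag_attention,
    predict_tiles_from_features,
)
from .moe import aggregate_75th, run_moe_attention, run_moe_simple
from .sharpness import compute_bag_sharpness
from .types import SlideBag

__all__ = [
    "auc",
    "SensitivityMatrix",
    "blur_sensitivity_sweep",
    "ScenarioReport",
    "scenario_benchmark",
    "blurriest_subset",
    "baseline_slide_score",
]

#: Validation sigma grid used for cross-blur sensitivity evaluation.
DEFAULT_VALIDATION_GRID: tuple[float, ...] = (
    0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0
)

#: Expert training sigmas: baseline plus ten blur levels.
DEFAULT_EXPERT_SIGMAS: tuple[float, ...] = (
    0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0
)


def auc(labels, scores) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count 1/2."""
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, scores))


def baseline_slide_score(expert: TrainedExpert, features: np.ndarray) -> float:
    """Slide score from one expert applied to every tile of a bag."""
    if expert.spec.kind == "tile_classifier":
        return aggregate_75th(predict_tiles_from_features(expert, features))
    return predict_bag_attention(expert, features)


@dataclass
class SensitivityMatrix:
    """Mean CV AUC per (expert, validation sigma)."""

    table: pd.DataFrame  # rows: expert ids; columns: sigma
    per_fold: pd.DataFrame | None = None

    def row(self, expert_id: str) -> np.ndarray:
        return self.table.loc[expert_id].to_numpy()


def blur_sensitivity_sweep(
    fold_experts: list[dict[str, TrainedExpert]],
    fold_validation_bags: list[list[SlideBag]],
    sigma_grid=DEFAULT_VALIDATION_GRID,
) -> SensitivityMatrix:
    """Evaluate every expert on uniformly blurred validation sets.

    ``fold_experts[f]`` holds the experts trained on fold ``f``'s training
    split; ``fold_validation_bags[f]`` that fold's pristine validation
    bags.  Each cell is the mean over folds of the slide-level AUC of the
    expert on validation bags blurred at the column sigma.  Features are
    extracted once per (fold, sigma) and shared across experts.
    """
    if len(fold_experts) != len(fold_validation_bags):
        raise ValueError("one expert set per fold required")
    expert_ids = list(fold_experts[0].keys())
    rows = []
    for f, (experts, bags) in enumerate(zip(fold_experts, fold_validation_bags)):
        if set(experts.keys()) != set(expert_ids):
            raise ValueError("expert ids differ across folds")
        labels = [b.label for b in bags]
        for sigma in sigma_grid:
            feats = [extract_bag_features(b, sigma) for b in bags]
            for eid in expert_ids:
                ex = experts[eid]
                if not ex.params:
                    raise ValueError(f"expert {eid!r} is untrained")
                scores = [baseline_slide_score(ex, F) for F in feats]
                rows.append(
                    {"fold": f, "expert_id": eid, "sigma": float(sigma),
                     "auc": auc(labels, scores)}
                )
    per_fold = pd.DataFrame(rows)
    table = (
        per_fold.pivot_table(index="expert_id", columns="sigma", values="auc",
                             aggfunc="mean")
        .reindex(expert_ids)
    )
    return SensitivityMatrix(table=table, per_fold=per_fold)


@dataclass
class ScenarioReport:
    """Per-(scenario, fold) baseline and MoE AUCs with deltas."""

    per_fold: pd.DataFrame  # scenario_id, fold, auc_baseline, auc_moe, delta
    seed: int

    def summary(self) -> pd.DataFrame:
        g = self.per_fold.groupby("scenario_id")[["auc_baseline", "auc_moe"]].mean()
        g["delta"] = g["auc_moe"] - g["auc_baseline"]
        return g


def scenario_benchmark(
    fold_baselines: list[TrainedExpert],
    fold_experts: list[dict[str, TrainedExpert]],
    fold_gatings: list[GatingTable],
    fold_validation_bags: list[list[SlideBag]],
    scenario_ids=tuple(range(1, 13)),
    seed: int = 0,
    track: str = "simple",
) -> ScenarioReport:
    """Benchmark MoE vs baseline over mixed-blur scenarios.

    Per (scenario, fold): scenario blur is drawn once and applied to the
    fold's validation bags; sharpness and features of the blurred tiles
    are computed once and shared, so baseline and MoE predictions see
    bit-identical inputs and deltas isolate the modelling strategy.
    """
    if track not in ("simple", "attention"):
        raise ValueError(f"unknown track {track!r}")
    run_moe = run_moe_simple if track == "simple" else run_moe_attention
    rows = []
    for sid in scenario_ids:
        if sid not in SCENARIOS:
            raise ValueError(f"scenario id must be 1..12, got {sid}")
        scenario = SCENARIOS[sid]
        for f, bags in enumerate(fold_validation_bags):
            rng = np.random.default_rng([seed, sid, f])
            labels = [b.label for b in bags]
            base_scores, moe_scores = [], []
            for bag in bags:
                blurred, _ = assign_scenario_blur(bag, scenario, rng)
                compute_bag_sharpness(blurred)
                F = extract_bag_features(blurred)
                base_scores.append(
                    baseline_slide_score(fold_baselines[f], F))
                pred = run_moe(blurred, fold_experts[f], fold_gatings[f],
                               features=F)
                moe_scores.append(pred.final)
            a_base = auc(labels, base_scores)
            a_moe = auc(labels, moe_scores)
            rows.append(
                {"scenario_id": sid, "fold": f, "auc_baseline": a_base,
                 "auc_moe": a_moe, "delta": a_moe - a_base}
            )
    return ScenarioReport(pd.DataFrame(rows), seed)


def blurriest_subset(slide_ids, q1_values, n: int) -> list[str]:
    """The n slides with the smallest Q1-of-LV (ties broken by slide id).

    Selection is invariant to input order.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    ids = list(slide_ids)
    q1 = list(q1_values)
    if n > len(ids):
        raise ValueError(f"asked for {n} slides but only {len(ids)} available")
    order = sorted(zip(q1, ids))
    return [sid for _, sid in order[:n]]
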