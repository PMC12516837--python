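"""Mixture-of-experts inference: LV routing, aggregation, combination.

Routing is a hard, deterministic rule over the gating table's LV
thresholds.  Two slide-level combination modes mirror the two expert
kinds:

* tile-classifier track: every tile is predicted by its routed expert and
  the slide probability is the 75th percentile of the pooled tile
  probabilities;
* attention track: each expert with at least one routed tile produces a
  bag-level probability from *its* tiles only, and the slide probability
  is the tile-fraction-weighted average

      p_final = sum_i w_i * p_i,   w_i = n_i / n_tot,  sum_i w_i = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import GatingTable
from .experts import (
    TrainedExpert,
    extract_bag_features,
    predict_bag_attention,
    predict_tiles_from_features,
)
from .sharpness import compute_bag_sharpness
from .types import SlideBag

__all__ = [
    "RoutingResult",
    "SlidePrediction",
    "route_tiles",
    "aggregate_75th",
    "moe_weights",
    "moe_combine",
    "run_moe_simple",
    "run_moe_attention",
]


@dataclass
class RoutingResult:
    """Tile-to-expert assignment plus per-expert tile counts."""

    assignments: dict[str, str]
    counts: dict[str, int]
    n_tot: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_tot:
            raise ValueError("per-expert counts do not sum to n_tot")


def route_tiles(thetas, gating: GatingTable) -> RoutingResult:
    """Assign each tile to an expert by its LV value.

    ``thetas`` maps tile_id -> theta (dict or iterable of pairs).  With
    thresholds tau_1 > ... > tau_{m-1}: theta > tau_1 -> expert 1;
    tau_{k+1} < theta <= tau_k -> expert k+1; theta <= tau_{m-1} ->
    expert m.  A boundary value theta == tau_k therefore routes to the
    blurrier expert k+1.
    """
    if not isinstance(thetas, dict):
        thetas = dict(thetas)
    taus = gating.thresholds
    experts = gating.expert_ids
    assignments: dict[str, str] = {}
    counts = {e: 0 for e in experts}
    for tile_id, theta in thetas.items():
        # negate so the descending taus become ascending; side="right"
        # places theta == tau_k with the blurrier expert k+1
        k = int(np.searchsorted(-taus, -float(theta), side="right"))
        expert = experts[k]
        assignments[tile_id] = expert
        counts[expert] += 1
    return RoutingResult(assignments, counts, len(assignments))


def aggregate_75th(tile_probs) -> float:
    """Slide score: 75th percentile of tile probabilities (linear interp)."""
    probs = np.asarray(list(tile_probs), dtype=float)
    if probs.size == 0:
        raise ValueError("cannot aggregate an empty probability collection")
    return float(np.percentile(probs, 75))


def moe_weights(routing: RoutingResult) -> dict[str, float]:
    """Per-expert weight w_i = n_i / n_tot; zero-tile experts get 0."""
    if routing.n_tot == 0:
        raise ValueError("routing covers no tiles")
    return {e: n / routing.n_tot for e, n in routing.counts.items()}


def moe_combine(weights: dict[str, float], per_expert_probs: dict[str, float]) -> float:
    """Weighted-average combination over experts with positive weight.

    Zero-weight experts may omit their probability; an active expert
    without one raises.
    """
    total_w = sum(weights.values())
    if abs(total_w - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {total_w}, expected 1")
    final = 0.0
    for e, w in weights.items():
        if w > 0:
            if e not in per_expert_probs:
                raise ValueError(f"expert {e!r} has weight {w} but no probability")
            final += w * per_expert_probs[e]
    return final


@dataclass
class SlidePrediction:
    """Slide-level MoE output with its audit trail."""

    slide_id: str
    final: float
    mode: str  # "percentile75" | "weighted_average"
    counts: dict[str, int] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)
    per_expert_probs: dict[str, float] = field(default_factory=dict)


def _bag_thetas_features(bag: SlideBag, need_features: bool):
    if any(t.theta is None for t in bag.tiles):
        compute_bag_sharpness(bag)
    thetas = {t.tile_id: float(t.theta) for t in bag.tiles}
    feats = extract_bag_features(bag) if need_features else None
    return thetas, feats


def run_moe_simple(
    bag: SlideBag,
    experts: dict[str, TrainedExpert],
    gating: GatingTable,
    features: np.ndarray | None = None,
) -> SlidePrediction:
    """Tile-classifier MoE: route, predict per tile, pool, 75th percentile.

    All tile probabilities (from whichever expert produced them) are
    pooled before the percentile — the slide score reflects every tile.
    ``features`` may carry precomputed raw per-tile features (bag order).
    """
    if not bag.tiles:
        raise ValueError(f"slide {bag.slide_id!r} has no tiles")
    thetas, F = _bag_thetas_features(bag, need_features=features is None)
    if features is not None:
        F = np.atleast_2d(features)
    routing = route_tiles(thetas, gating)
    tile_ids = [t.tile_id for t in bag.tiles]
    probs = np.empty(len(tile_ids))
    per_expert: dict[str, float] = {}
    for eid in gating.expert_ids:
        idx = [i for i, tid in enumerate(tile_ids) if routing.assignments[tid] == eid]
        if not idx:
            continue
        p = predict_tiles_from_features(experts[eid], F[idx])
        probs[idx] = p
        per_expert[eid] = aggregate_75th(p)
    return SlidePrediction(
        slide_id=bag.slide_id,
        final=aggregate_75th(probs),
        mode="percentile75",
        counts=routing.counts,
        weights=moe_weights(routing),
        per_expert_probs=per_expert,
    )


def run_moe_attention(
    bag: SlideBag,
    experts: dict[str, TrainedExpert],
    gating: GatingTable,
    features: np.ndarray | None = None,
) -> SlidePrediction:
    """Attention MoE: per-expert bag predictions, tile-fraction weighting.

    Each expert with at least one routed tile pools *its own* tiles into a
    bag probability; the final slide probability is the weighted average
    with weights n_i / n_tot.  Zero-tile experts are skipped (weight 0).
    """
    if not bag.tiles:
        raise ValueError(f"slide {bag.slide_id!r} has no tiles")
    thetas, F = _bag_thetas_features(bag, need_features=features is None)
    if features is not None:
        F = np.atleast_2d(features)
    routing = route_tiles(thetas, gating)
    tile_ids = [t.tile_id for t in bag.tiles]
    weights = moe_weights(routing)
    per_expert: dict[str, float] = {}
    for eid in gating.expert_ids:
        idx = [i for i, tid in enumerate(tile_ids) if routing.assignments[tid] == eid]
        if not idx:
            continue
        per_expert[eid] = predict_bag_attention(experts[eid], F[idx])
    final = moe_combine(weights, per_expert)
    return SlidePrediction(
        slide_id=bag.slide_id,
        final=final,
        mode="weighted_average",
        counts=routing.counts,
        weights=weights,
        per_expert_probs=per_expert,
    )
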