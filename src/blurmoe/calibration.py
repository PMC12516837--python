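"""Sigma-to-LV calibration and gating-threshold derivation.

Simulated blur is parameterised by sigma, but at inference time only the
measured sharpness (LV) of a tile is available.  The bridge is built in
three steps:

1. ``calibrate_sigma_to_lv`` — blur a tile sample at every sigma on a grid
   and record the median LV per sigma (the sigma→LV map).
2. ``select_expert_ranges`` — from a cross-blur AUC matrix (expert rows,
   validation-sigma columns), assign each validation sigma to its
   best-performing expert and merge adjacent winners into sigma intervals.
3. ``derive_lv_thresholds`` — convert each interval boundary into an LV
   threshold by averaging the median LV of the boundary sigma and the next
   consecutive grid sigma.

The resulting gating table (tau_1 > tau_2 > ... > tau_{m-1}) routes a tile
with sharpness theta to expert 1 if theta > tau_1, expert k+1 if
tau_{k+1} < theta <= tau_k, and expert m if theta <= tau_{m-1}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .blur import apply_blur
from .sharpness import laplacian_variance

__all__ = [
    "DEFAULT_SIGMA_GRID",
    "LVCalibrationTable",
    "ExpertRangeMap",
    "GatingTable",
    "calibrate_sigma_to_lv",
    "select_expert_ranges",
    "derive_lv_thresholds",
]

#: Half-unit sigma grid used for the sigma->LV map.
DEFAULT_SIGMA_GRID: tuple[float, ...] = tuple(np.arange(0.0, 10.5, 0.5))


@dataclass
class LVCalibrationTable:
    """Ordered (sigma, median LV) pairs over a sigma grid."""

    sigmas: np.ndarray
    median_lv: np.ndarray
    n_tiles_sampled: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.median_lv = np.asarray(self.median_lv, dtype=float)
        if self.sigmas.shape != self.median_lv.shape:
            raise ValueError("sigma grid and median LV lengths differ")
        if not np.all(np.diff(self.sigmas) > 0):
            raise ValueError("sigma grid must be strictly increasing")

    def median_for(self, sigma: float) -> float:
        idx = np.nonzero(np.isclose(self.sigmas, sigma))[0]
        if idx.size == 0:
            raise KeyError(f"sigma {sigma} not on the calibration grid")
        return float(self.median_lv[idx[0]])

    def to_json(self) -> str:
        return json.dumps(
            {
                "sigmas": self.sigmas.tolist(),
                "median_lv": self.median_lv.tolist(),
                "n_tiles_sampled": self.n_tiles_sampled,
                "seed": self.seed,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "LVCalibrationTable":
        d = json.loads(text)
        return cls(np.asarray(d["sigmas"]), np.asarray(d["median_lv"]),
                   d["n_tiles_sampled"], d.get("seed"))


def calibrate_sigma_to_lv(
    tiles,
    sigma_grid=DEFAULT_SIGMA_GRID,
    rng: np.random.Generator | None = None,
    n_sample: int | None = None,
    seed: int | None = None,
) -> LVCalibrationTable:
    """Blur a tile sample at every grid sigma and record the median LV.

    ``tiles`` is a sequence of tile images (at least 100 for a stable
    median).  If ``n_sample`` is given, that many tiles are drawn without
    replacement using ``rng``.
    """
    tiles = list(tiles)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if not np.all(np.diff(sigma_grid) > 0):
        raise ValueError("sigma grid must be sorted strictly ascending")
    if n_sample is not None:
        if rng is None:
            rng = np.random.default_rng(seed)
        idx = rng.choice(len(tiles), size=min(n_sample, len(tiles)),
                         replace=False)
        tiles = [tiles[i] for i in idx]
    if len(tiles) < 100:
        raise ValueError(
            f"need at least 100 tiles for calibration, got {len(tiles)}"
        )
    medians = []
    for s in sigma_grid:
        lvs = [laplacian_variance(apply_blur(t, s)) for t in tiles]
        medians.append(np.median(lvs))
    medians = np.asarray(medians)
    if np.all(medians == 0):
        raise ValueError("degenerate tile sample: all LV medians are zero")
    return LVCalibrationTable(sigma_grid, medians, len(tiles), seed)


@dataclass
class ExpertRangeMap:
    """Contiguous sigma intervals and the expert that wins each.

    ``entries`` is an ordered list of (expert_id, grid_sigmas) pairs where
    ``grid_sigmas`` are the validation-grid sigmas the expert wins;
    consecutive entries cover the grid without gaps.
    """

    entries: list[tuple[str, list[float]]]

    def __post_init__(self) -> None:
        flat = [s for _, sig in self.entries for s in sig]
        if flat != sorted(flat) or len(set(flat)) != len(flat):
            raise ValueError("range map sigmas must be increasing and disjoint")

    @property
    def expert_ids(self) -> list[str]:
        return [e for e, _ in self.entries]

    def boundaries(self) -> list[tuple[float, float]]:
        """(last sigma of range k, first sigma of range k+1) per boundary."""
        out = []
        for (_, lo_sigmas), (_, hi_sigmas) in zip(self.entries, self.entries[1:]):
            out.append((lo_sigmas[-1], hi_sigmas[0]))
        return out


def _majority_smooth(winners: list[str], window: int = 3) -> list[str]:
    """3-cell majority vote; ties keep the original winner."""
    if len(winners) < 3:
        return list(winners)
    out = list(winners)
    half = window // 2
    for i in range(len(winners)):
        lo, hi = max(0, i - half), min(len(winners), i + half + 1)
        votes: dict[str, int] = {}
        for w in winners[lo:hi]:
            votes[w] = votes.get(w, 0) + 1
        best = max(votes.values())
        leaders = [w for w, v in votes.items() if v == best]
        if len(leaders) == 1:
            out[i] = leaders[0]
    return out


def select_expert_ranges(
    auc_matrix,
    train_sigmas: dict[str, float],
    smooth: bool = True,
    tie_margin: float = 0.01,
) -> ExpertRangeMap:
    """Assign each validation sigma to the best expert; merge into ranges.

    ``auc_matrix`` is a pandas DataFrame indexed by expert id with one
    column per validation sigma.  Per column the argmax-AUC expert wins,
    with ties — and near-ties within ``tie_margin`` AUC — resolved toward
    the expert with the lower training sigma: the sharper, more general
    model keeps a blur band unless a specialist is meaningfully better.
    A 3-cell majority vote smooths isolated winners before adjacent
    columns with the same winner are merged.  Missing cells raise, naming
    the offender.
    """
    import pandas as pd

    mat = pd.DataFrame(auc_matrix)
    for eid in mat.index:
        if eid not in train_sigmas:
            raise KeyError(f"no training sigma recorded for expert {eid!r}")
        for col in mat.columns:
            if pd.isna(mat.loc[eid, col]):
                raise ValueError(f"missing AUC for expert {eid!r} at sigma {col}")
    cols = sorted(mat.columns, key=float)
    winners = []
    for col in cols:
        series = mat[col]
        best = series.max()
        tied = [e for e in mat.index if series[e] >= best - tie_margin]
        tied.sort(key=lambda e: train_sigmas[e])
        winners.append(tied[0])
    if smooth:
        winners = _majority_smooth(winners)
    entries: list[tuple[str, list[float]]] = []
    for sigma, w in zip(cols, winners):
        if entries and entries[-1][0] == w:
            entries[-1][1].append(float(sigma))
        else:
            entries.append((w, [float(sigma)]))
    return ExpertRangeMap(entries)


@dataclass
class GatingTable:
    """LV thresholds tau_1 > ... > tau_{m-1} and the m experts they gate.

    ``expert_ids`` is ordered sharpest-first (expert 1 takes theta >
    tau_1).
    """

    thresholds: np.ndarray
    expert_ids: list[str]

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if len(self.expert_ids) != len(self.thresholds) + 1:
            raise ValueError(
                f"{len(self.expert_ids)} experts require "
                f"{len(self.expert_ids) - 1} thresholds, got {len(self.thresholds)}"
            )
        if self.thresholds.size:
            if not np.all(np.diff(self.thresholds) < 0):
                raise ValueError("thresholds must be strictly decreasing")
            if self.thresholds[-1] <= 0:
                raise ValueError("thresholds must be positive")

    def to_json(self) -> str:
        return json.dumps(
            {"thresholds": self.thresholds.tolist(),
             "expert_ids": list(self.expert_ids)},
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GatingTable":
        d = json.loads(text)
        return cls(np.asarray(d["thresholds"]), list(d["expert_ids"]))


def derive_lv_thresholds(
    calib: LVCalibrationTable, ranges: ExpertRangeMap
) -> GatingTable:
    """LV thresholds from expert sigma ranges via consecutive-median averaging.

    For each boundary between expert range k (ending at grid sigma s) and
    range k+1 (starting at s'), the threshold is
    (median_LV(s) + median_LV(s')) / 2.  Boundary sigmas must lie on the
    calibration grid.  A single-expert map yields an empty threshold list.
    """
    taus = []
    for s, s_next in ranges.boundaries():
        taus.append((calib.median_for(s) + calib.median_for(s_next)) / 2.0)
    return GatingTable(np.asarray(taus), ranges.expert_ids)
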