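"""Variance-of-Laplacian (LV) sharpness estimation and quality control.

LV is the population variance of the response of the four-neighbour
Laplacian [[0,1,0],[1,-4,1],[0,1,0]] applied to the 0-255 luminance image
with reflect-101 borders.  Sharp tissue tiles have high LV; defocused or
blurred tiles have low LV, which motivates both the classical LV < 500
quality-control filter and the LV-threshold gating used by the mixture of
experts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import SlideBag

__all__ = [
    "SharpnessRecord",
    "QCReport",
    "to_luminance",
    "laplacian_variance",
    "compute_bag_sharpness",
    "qc_filter",
    "slide_blur_q1",
]

LAPLACIAN_KERNEL = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)

#: Classical tile QC cut-off on the 0-255 scale for full-size H&E tiles.
DEFAULT_LV_THRESHOLD = 500.0


@dataclass(frozen=True)
class SharpnessRecord:
    tile_id: str
    theta: float


def to_luminance(tile: np.ndarray) -> np.ndarray:
    """Collapse a tile to a float 2-D luminance grid on the 0-255 scale.

    Grayscale passes through; RGB uses the Rec. 601 weights
    0.299 R + 0.587 G + 0.114 B.
    """
    tile = np.asarray(tile)
    if tile.ndim == 2:
        return tile.astype(float)
    if tile.ndim == 3 and tile.shape[2] == 1:
        return tile[:, :, 0].astype(float)
    if tile.ndim == 3 and tile.shape[2] == 3:
        w = np.array([0.299, 0.587, 0.114])
        return tile.astype(float) @ w
    raise ValueError(
        f"expected a grayscale or 3-channel tile, got shape {tile.shape}"
    )


def laplacian_variance(tile: np.ndarray) -> float:
    """Sharpness theta: variance of the Laplacian-filtered luminance."""
    lum = to_luminance(tile)
    if lum.shape[0] < 3 or lum.shape[1] < 3:
        raise ValueError(f"tile too small for a 3x3 Laplacian: {lum.shape}")
    resp = ndimage.convolve(lum, LAPLACIAN_KERNEL, mode="mirror")
    return float(resp.var())


def compute_bag_sharpness(bag: SlideBag) -> list[SharpnessRecord]:
    """Compute and store theta for every tile in a bag (in place)."""
    records = []
    for tile in bag.tiles:
        tile.theta = laplacian_variance(tile.image)
        records.append(SharpnessRecord(tile.tile_id, tile.theta))
    return records


@dataclass
class QCReport:
    slide_id: str
    rejected: list[SharpnessRecord] = field(default_factory=list)
    n_kept: int = 0
    empty_after_filter: bool = False


def qc_filter(
    bag: SlideBag, lv_threshold: float = DEFAULT_LV_THRESHOLD
) -> tuple[SlideBag, QCReport]:
    """Drop tiles with theta strictly below the threshold.

    The rule is strictly "less than": a tile at exactly the threshold is
    retained.  Kept-tile order is preserved.  A bag emptied by the filter
    is flagged in the report rather than raising.
    """
    report = QCReport(bag.slide_id)
    kept = []
    for tile in bag.tiles:
        if tile.theta is None:
            raise ValueError(f"tile {tile.tile_id!r} has no sharpness value")
        if tile.theta < lv_threshold:
            report.rejected.append(SharpnessRecord(tile.tile_id, tile.theta))
        else:
            kept.append(tile)
    report.n_kept = len(kept)
    report.empty_after_filter = not kept
    filtered = SlideBag(bag.slide_id, bag.patient_id, bag.label, kept)
    return filtered, report


def slide_blur_q1(bag: SlideBag) -> float:
    """Slide-level blur summary: lower quartile (Q1) of tile LV values.

    Uses linear interpolation between order statistics.  Lower Q1 means a
    blurrier slide.
    """
    if not bag.tiles:
        raise ValueError(f"slide {bag.slide_id!r} has no tiles")
    return float(np.percentile(bag.thetas(), 25))
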