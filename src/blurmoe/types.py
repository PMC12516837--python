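"""Core in-memory containers shared across the pipeline.

A *tile* is a small square crop of a whole-slide image (WSI), stored as an
8-bit grayscale or RGB array.  A *slide bag* is one patient's slide: its
binary label plus an ordered collection of tiles with per-tile metadata
(the base blur sigma ``g`` the tile carries and, once measured, its
variance-of-Laplacian sharpness ``theta``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TileRecord", "SlideBag", "LabeledCohort"]


@dataclass
class TileRecord:
    """One tile: pixels plus routing metadata.

    Parameters
    ----------
    tile_id
        Unique identifier within the cohort.
    image
        ``(H, W)`` or ``(H, W, 3)`` uint8 array on the 0-255 scale.
    base_sigma
        Gaussian blur sigma the stored pixels already carry (``g``); 0 for
        pristine synthetic tiles.
    theta
        Variance-of-Laplacian sharpness, filled in by the sharpness stage.
    """

    tile_id: str
    image: np.ndarray
    base_sigma: float = 0.0
    theta: float | None = None


@dataclass
class SlideBag:
    """One patient's slide as a bag of tiles with a binary label."""

    slide_id: str
    patient_id: str
    label: int
    tiles: list[TileRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.tiles)

    def thetas(self) -> np.ndarray:
        """Per-tile sharpness values; raises if any tile lacks one."""
        vals = []
        for t in self.tiles:
            if t.theta is None:
                raise ValueError(
                    f"tile {t.tile_id!r} has no sharpness value; run the "
                    "sharpness stage first"
                )
            vals.append(t.theta)
        return np.asarray(vals, dtype=float)


@dataclass
class LabeledCohort:
    """A collection of slide bags, one per patient."""

    bags: list[SlideBag]

    def __post_init__(self) -> None:
        ids = [b.patient_id for b in self.bags]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient_id in cohort")

    def __len__(self) -> int:
        return len(self.bags)

    @property
    def patient_ids(self) -> list[str]:
        return [b.patient_id for b in self.bags]

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([b.label for b in self.bags], dtype=int)

    def subset(self, patient_ids) -> "LabeledCohort":
        wanted = set(patient_ids)
        return LabeledCohort([b for b in self.bags if b.patient_id in wanted])
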