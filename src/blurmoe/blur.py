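"""Gaussian blur simulation and mixed-blur scenario sampling.

Blur severity is parameterised by the standard deviation sigma of an
isotropic Gaussian kernel

    G(x, y) = 1 / (2 pi sigma^2) * exp(-(x^2 + y^2) / (2 sigma^2)),

and a blurred tile is the convolution I' = I * G.  The kernel is truncated
at radius ceil(4 sigma), which leaves less than 1e-4 of the Gaussian mass
outside the support, and renormalised to sum exactly 1 so constants are
preserved.  All convolutions use reflect-101 ("mirror") borders to avoid
edge darkening that would corrupt downstream sharpness estimates.

The scenario sampler emulates a slide whose tiles fall into three blur
severity groups (low / moderate / high); each tile is independently
assigned a group with the scenario's proportions and receives a sigma drawn
uniformly from that group's range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import SlideBag, TileRecord

__all__ = [
    "GaussianKernel",
    "BlurScenario",
    "BlurredTileRecord",
    "SCENARIOS",
    "DEFAULT_GROUP_RANGES",
    "make_kernel",
    "apply_blur",
    "assign_scenario_blur",
]


@dataclass(frozen=True)
class GaussianKernel:
    """A truncated, normalised 2-D Gaussian kernel.

    ``raw_weights`` holds the analytic kernel values
    ``exp(-(x^2+y^2)/(2 sigma^2)) / (2 pi sigma^2)`` on the truncated
    support; ``weights`` is the same grid renormalised to sum 1.
    """

    sigma: float
    radius: int
    weights: np.ndarray
    raw_weights: np.ndarray

    def __post_init__(self) -> None:
        s = float(self.weights.sum())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"kernel weights sum to {s}, expected 1")


def make_kernel(sigma: float) -> GaussianKernel:
    """Build the truncated Gaussian kernel for blur level ``sigma``.

    ``sigma = 0`` yields the identity kernel (radius 0, single weight 1).
    """
    sigma = float(sigma)
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    if sigma == 0.0:
        one = np.ones((1, 1))
        return GaussianKernel(0.0, 0, one.copy(), one.copy())
    radius = math.ceil(4.0 * sigma)
    coords = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(coords, coords)
    raw = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2)) / (2.0 * math.pi * sigma**2)
    return GaussianKernel(sigma, radius, raw / raw.sum(), raw)


def _gauss_1d(sigma: float) -> np.ndarray:
    radius = math.ceil(4.0 * sigma)
    x = np.arange(-radius, radius + 1, dtype=float)
    w = np.exp(-(x**2) / (2.0 * sigma**2))
    return w / w.sum()


def apply_blur(tile: np.ndarray, sigma: float) -> np.ndarray:
    """Convolve a tile with the Gaussian kernel at ``sigma``.

    The separable form is used (the truncated 2-D kernel is the outer
    product of its 1-D factors, so this is exact).  Integer input is
    processed in floating point and rounded back to the 0-255 scale;
    float input stays float.  ``sigma = 0`` returns an unchanged copy.
    """
    tile = np.asarray(tile)
    if tile.size == 0:
        raise ValueError("empty tile")
    sigma = float(sigma)
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    if sigma == 0.0:
        return tile.copy()
    integer_in = np.issubdtype(tile.dtype, np.integer)
    out = tile.astype(float)
    w = _gauss_1d(sigma)
    for axis in (0, 1):
        out = ndimage.correlate1d(out, w, axis=axis, mode="mirror")
    if integer_in:
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out


DEFAULT_GROUP_RANGES: tuple[tuple[float, float], ...] = (
    (0.0, 1.5),
    (1.5, 5.0),
    (5.0, 10.0),
)

GROUP_NAMES = ("low", "moderate", "high")


@dataclass(frozen=True)
class BlurScenario:
    """Percentages of tiles assigned to the low/moderate/high blur groups."""

    scenario_id: int
    p_low: float
    p_moderate: float
    p_high: float
    group_ranges: tuple[tuple[float, float], ...] = DEFAULT_GROUP_RANGES

    def __post_init__(self) -> None:
        total = self.p_low + self.p_moderate + self.p_high
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"group percentages must sum to 100, got {total}")
        if min(self.p_low, self.p_moderate, self.p_high) < 0:
            raise ValueError("group percentages must be non-negative")
        lo, mid, hi = self.group_ranges
        if not (lo[0] <= lo[1] <= mid[0] <= mid[1] <= hi[0] <= hi[1]):
            raise ValueError("group ranges must be ordered and non-overlapping")

    @property
    def probs(self) -> np.ndarray:
        return np.array([self.p_low, self.p_moderate, self.p_high]) / 100.0


#: The 12 mixed-blur evaluation scenarios (percent low / moderate / high).
SCENARIOS: dict[int, BlurScenario] = {
    sid: BlurScenario(sid, *p)
    for sid, p in {
        1: (100, 0, 0),
        2: (0, 100, 0),
        3: (0, 0, 100),
        4: (50, 25, 25),
        5: (25, 50, 25),
        6: (25, 25, 50),
        7: (50, 50, 0),
        8: (0, 50, 50),
        9: (80, 10, 10),
        10: (10, 80, 10),
        11: (10, 10, 80),
        12: (80, 15, 5),
    }.items()
}


@dataclass(frozen=True)
class BlurredTileRecord:
    """Audit record for one scenario-blurred tile: sigma_hat = g + g_i."""

    tile_id: str
    g: float
    g_i: float
    sigma_hat: float
    group: str


def assign_scenario_blur(
    bag: SlideBag,
    scenario: BlurScenario,
    rng: np.random.Generator,
    *,
    mode: str = "sum",
    exact_proportions: bool = False,
) -> tuple[SlideBag, list[BlurredTileRecord]]:
    """Blur a bag's tiles according to a mixed-blur scenario.

    Each tile is assigned a blur group (independent draw with the scenario
    proportions, or an exact-proportion shuffled partition when
    ``exact_proportions`` is set), receives ``g_i ~ U(a, b)`` from its
    group's sigma range, and is blurred once.

    ``mode="sum"`` (default) applies a single convolution at
    ``sigma_hat = g + g_i`` to the stored pixels, treating the scalar sum
    as the final blur level; ``mode="sequential"`` convolves the stored
    (possibly already-blurred) pixels at ``g_i``, giving an effective sigma
    of sqrt(g^2 + g_i^2).  The two coincide for pristine tiles (g = 0).
    """
    if mode not in ("sum", "sequential"):
        raise ValueError(f"unknown blur mode {mode!r}")
    n = len(bag.tiles)
    if exact_proportions:
        counts = np.floor(scenario.probs * n).astype(int)
        frac = scenario.probs * n - counts
        for _ in range(n - counts.sum()):
            k = int(np.argmax(frac))
            counts[k] += 1
            frac[k] = -1
        groups = rng.permuted(np.repeat(np.arange(3), counts))
    else:
        groups = rng.choice(3, size=n, p=scenario.probs)

    records: list[BlurredTileRecord] = []
    new_tiles: list[TileRecord] = []
    for tile, grp in zip(bag.tiles, groups):
        a, b = scenario.group_ranges[grp]
        g_i = float(rng.uniform(a, b))
        g = float(tile.base_sigma)
        sigma_hat = g + g_i
        if mode == "sum":
            blurred = apply_blur(tile.image, sigma_hat)
        else:
            blurred = apply_blur(tile.image, g_i)
        new_tiles.append(TileRecord(tile.tile_id, blurred, base_sigma=sigma_hat))
        records.append(
            BlurredTileRecord(tile.tile_id, g, g_i, sigma_hat, GROUP_NAMES[grp])
        )
    blurred_bag = SlideBag(bag.slide_id, bag.patient_id, bag.label, new_tiles)
    return blurred_bag, records
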