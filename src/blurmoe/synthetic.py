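"""Synthetic tile, slide-bag and cohort generation plus CV splits.

The generator emulates the statistical skeleton of a tiled histopathology
cohort: each patient is a bag of tiles, and the binary class signal is
carried by high-spatial-frequency texture — Poisson-distributed dark blobs
(nucleus-like spots) planted on a smooth background, with class 1 roughly
three times denser than class 0.  Because the discriminative energy lives
at high spatial frequencies, Gaussian blur progressively destroys
separability, which is the regime the sharpness-gated mixture of experts
is designed for.

Every tile is recentred to mean 128 before pixel noise is added, so mean
intensity carries (essentially) no class information and a classifier
cannot sidestep blur through a blur-invariant brightness shortcut.

All generators are pure functions of (config, seed); per-patient RNG
substreams are keyed by patient index so partial regeneration is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .types import LabeledCohort, SlideBag, TileRecord

__all__ = [
    "SyntheticConfig",
    "generate_tile",
    "generate_cohort",
    "make_cv_splits",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-generation parameters.

    Defaults give a desk-scale cohort whose classes differ only in blob
    density (mean 40 vs 120 blobs per tile), with a class balance of 0.6
    mirroring a roughly 2:3 grade-1 : grade-3 case mix.
    """

    n_patients: int = 40
    tiles_per_slide: int = 16
    tile_size: int = 128
    class_blob_density: tuple[float, float] = (40.0, 120.0)
    blob_radius_px: tuple[float, float] = (2.0, 4.0)
    blob_contrast: float = 80.0
    background_smoothness: float = 16.0
    background_amplitude: tuple[float, float] = (4.0, 28.0)
    texture_smoothness: float = 6.0
    texture_amplitude: tuple[float, float] = (0.0, 12.0)
    pixel_noise_sd: float = 5.0
    slide_density_spread: float = 0.35
    class_balance: float = 0.6
    rgb: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.tile_size < 32:
            raise ValueError(f"tile_size must be >= 32, got {self.tile_size}")
        if self.tiles_per_slide < 1:
            raise ValueError("tiles_per_slide must be >= 1")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError(
                f"class_balance must be in (0, 1), got {self.class_balance}"
            )
        if min(self.class_blob_density) < 0 or self.blob_contrast < 0:
            raise ValueError("blob density and contrast must be non-negative")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel_noise_sd must be non-negative")
        if self.slide_density_spread < 0:
            raise ValueError("slide_density_spread must be non-negative")


def _disk_stamp(radius: float) -> np.ndarray:
    """Hard-edged unit disk of the given radius (odd-sized footprint)."""
    r = int(np.ceil(radius))
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    return (x * x + y * y <= radius * radius).astype(float)


def generate_tile(
    class_label: int,
    params: SyntheticConfig,
    rng: np.random.Generator,
    *,
    density_multiplier: float = 1.0,
    background_amp: float | None = None,
    texture_amp: float | None = None,
    return_meta: bool = False,
):
    """Generate one tile for the given class.

    The tile is: smooth random background (Gaussian-filtered white noise)
    + Poisson-count dark disks + i.i.d. pixel noise, recentred to mean 128
    and clipped to [0, 255] as uint8.  ``density_multiplier`` scales the
    class blob density (used by :func:`generate_cohort` to model per-slide
    severity spread; defaults to 1 so a bare call realises the exact class
    means).  With ``return_meta=True`` the planted blob count and radii
    are returned alongside the pixels.
    """
    if class_label not in (0, 1):
        raise ValueError(f"class label must be 0 or 1, got {class_label!r}")
    params.validate()
    t = params.tile_size

    # smooth low-frequency background around mid-gray plus a weaker
    # mid-frequency texture field; both amplitudes vary tile to tile,
    # emulating stain / tissue-density nuisance that survives blur (so the
    # blurred-regime class signal is read against realistic noise)
    from scipy import ndimage

    def _smooth_field(smoothness: float) -> np.ndarray:
        f = rng.standard_normal((t, t))
        if smoothness > 0:
            f = ndimage.gaussian_filter(f, smoothness, mode="mirror")
            sd = f.std()
            if sd > 0:
                f = f / sd
        return f

    bg = _smooth_field(params.background_smoothness)
    if background_amp is None:
        background_amp = float(rng.uniform(*params.background_amplitude))
    tex = _smooth_field(params.texture_smoothness)
    if texture_amp is None:
        texture_amp = float(rng.uniform(*params.texture_amplitude))
    canvas = 128.0 + background_amp * bg + texture_amp * tex

    # blobs attenuate multiplicatively (stain absorption): overlaps stack
    # without clipping, so mean intensity stays class-free after recentring
    density = params.class_blob_density[class_label] * density_multiplier
    n_blobs = int(rng.poisson(density))
    r_lo, r_hi = params.blob_radius_px
    margin = int(np.ceil(2 * r_hi))
    attenuation = max(0.0, 1.0 - params.blob_contrast / 128.0)
    transmission = np.ones((t, t))
    radii = []
    for _ in range(n_blobs):
        radius = float(rng.uniform(r_lo, r_hi))
        radii.append(radius)
        cy = int(rng.integers(margin, t - margin))
        cx = int(rng.integers(margin, t - margin))
        stamp = _disk_stamp(radius)
        r = stamp.shape[0] // 2
        transmission[cy - r : cy + r + 1, cx - r : cx + r + 1] *= np.where(
            stamp > 0, attenuation, 1.0
        )
    canvas = canvas * transmission

    # kill the mean-intensity shortcut: class signal stays high-frequency
    canvas += 128.0 - canvas.mean()
    if params.pixel_noise_sd > 0:
        canvas += rng.normal(0.0, params.pixel_noise_sd, size=(t, t))
    tile = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    if params.rgb:
        tile = np.repeat(tile[:, :, None], 3, axis=2)
    if return_meta:
        return tile, {"blob_count": n_blobs, "radii": radii}
    return tile


def _patient_rng(seed: int, patient_index: int) -> np.random.Generator:
    # one substream per patient, keyed by index -> stable partial reruns
    return np.random.default_rng([seed, patient_index])


def generate_cohort(config: SyntheticConfig) -> LabeledCohort:
    """Generate a labelled cohort: one bag of pristine tiles per patient.

    Class counts match ``class_balance`` to within rounding; the label
    sequence is a seeded shuffle so classes interleave across patient ids.
    Each slide carries a lognormal blob-density multiplier (unit mean,
    log-sd ``slide_density_spread``) modelling per-patient severity
    spread, and slide-level background/texture nuisance amplitudes
    (stain-intensity variation); tiles within a slide share all three.
    """
    config.validate()
    n = config.n_patients
    if n < 2:
        raise ValueError(f"need at least 2 patients, got {n}")
    n_pos = int(round(config.class_balance * n))
    if n_pos in (0, n):
        raise ValueError(
            f"class_balance {config.class_balance} with {n} patients yields a "
            "single-class cohort"
        )
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    labels = np.random.default_rng([config.seed, 2**31]).permuted(labels)

    bags = []
    for i in range(n):
        rng = _patient_rng(config.seed, i)
        pid = f"P{i:04d}"
        s = config.slide_density_spread
        mult = float(np.exp(rng.normal(-0.5 * s * s, s))) if s > 0 else 1.0
        bg_amp = float(rng.uniform(*config.background_amplitude))
        tex_amp = float(rng.uniform(*config.texture_amplitude))
        tiles = [
            TileRecord(f"{pid}_T{j:04d}",
                       generate_tile(int(labels[i]), config, rng,
                                     density_multiplier=mult,
                                     background_amp=bg_amp,
                                     texture_amp=tex_amp))
            for j in range(config.tiles_per_slide)
        ]
        bags.append(SlideBag(pid, pid, int(labels[i]), tiles))
    return LabeledCohort(bags)


def make_cv_splits(
    patient_ids,
    labels,
    k: int = 5,
    seed: int = 0,
) -> list[tuple[list[str], list[str]]]:
    """Stratified patient-level k-fold CV splits.

    Folds partition the patients with per-fold class counts within one of
    an even split and balanced fold sizes.  Splitting delegates to
    scikit-learn's StratifiedKFold; when a class has fewer than k members
    (which StratifiedKFold refuses) the patients are instead dealt
    class-by-class into the smallest folds, which preserves both
    properties.  Returns (train_ids, validation_ids) pairs.
    """
    patient_ids = list(patient_ids)
    labels = np.asarray(labels, dtype=int)
    if len(patient_ids) != len(labels):
        raise ValueError("patient_ids and labels must have equal length")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < 1:
        raise ValueError("both classes must be present")
    if len(patient_ids) < k:
        raise ValueError(
            f"cannot form k={k} folds from {len(patient_ids)} patients"
        )

    if counts.min() >= k:
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        ids = np.asarray(patient_ids, dtype=object)
        return [
            (list(ids[tr]), list(ids[va]))
            for tr, va in skf.split(ids, labels)
        ]

    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    # deal each class (larger first) into the currently smallest folds, so
    # class counts per fold stay within one of even and sizes balance
    order = np.argsort(-counts)
    for cls in order:
        members = [p for p, l in zip(patient_ids, labels) if l == cls]
        members = list(rng.permutation(np.asarray(members, dtype=object)))
        for p in members:
            sizes = [len(f) for f in folds]
            folds[int(np.argmin(sizes))].append(str(p))
    splits = []
    for i in range(k):
        val = sorted(folds[i], key=patient_ids.index)
        train = [p for p in patient_ids if p not in set(val)]
        splits.append((train, val))
    return splits
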