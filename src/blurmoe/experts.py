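"""Blur-specialised expert models over handcrafted tile features.

The mixture-of-experts framework is agnostic to what an expert is, as long
as it maps a tile (or a bag of tile features) to a class-1 probability.
Two desk-scale reference experts are provided behind that contract:

* a tile-level logistic classifier on a 12-dimensional handcrafted
  feature vector, with slide-level 75th-percentile aggregation, and
* a gated-attention multiple-instance head pooling the same features into
  a bag embedding before a linear bag classifier.

Each expert is trained on tiles blurred at one fixed sigma.  Features are
standardised to the expert's *training* statistics and hard-clipped at a
fixed number of training standard deviations, giving each expert a
calibrated dynamic range: inputs from a very different blur regime pin at
the clip rails and lose all ordering, so a mismatched expert produces
neutral rather than misleading scores.  This is what makes experts
genuinely specialised to their blur band (and what the LV gate exploits).
Both heads train by fixed-epoch full-batch gradient descent from a seeded
initialisation, so training is exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .blur import apply_blur
from .sharpness import laplacian_variance, to_luminance
from .types import SlideBag

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_DIM",
    "ExpertSpec",
    "TrainConfig",
    "TrainedExpert",
    "extract_features",
    "extract_bag_features",
    "train_tile_expert",
    "train_attention_expert",
    "predict_tile",
    "predict_tiles_from_features",
    "predict_bag_attention",
    "attention_weights",
]

FEATURE_NAMES = (
    "mean_intensity",
    "sd_intensity",
    "log_lv_s0",
    "log_lv_s1",
    "log_lv_s2",
    "log_lv_s4",
    "log_grad_energy_s1",
    "log_grad_energy_s2",
    "minima_count_s1",
    "minima_count_s2",
    "histogram_entropy",
    "dark_fraction",
)
FEATURE_DIM = len(FEATURE_NAMES)

_LV_SCALES = (0.0, 1.0, 2.0, 4.0)
_GRAD_SCALES = (1.0, 2.0)
_MINIMA_SCALES = (1.0, 2.0)
_MINIMA_DEPTHS = (55.0, 25.0)


def extract_features(tile: np.ndarray) -> np.ndarray:
    """Deterministic 12-dimensional handcrafted feature vector.

    Components: intensity mean and sd; log variance-of-Laplacian after
    Gaussian smoothing at scales {0, 1, 2, 4}; log gradient energy at
    scales {1, 2}; count of prominent local intensity minima (blob
    response) at scales {1, 2}; intensity-histogram entropy; fraction of
    pixels more than 25 units below the tile mean.  Texture components
    are zero on a constant tile and strictly shrink under added blur on
    textured tiles.
    """
    lum = to_luminance(tile)
    feats = np.empty(FEATURE_DIM)
    mean = lum.mean()
    sd = lum.std()
    feats[0] = mean
    feats[1] = sd

    # one smoothing pass per scale, reused by every scale-space feature
    smoothed = {0.0: lum}
    for s in sorted(set(_LV_SCALES) | set(_GRAD_SCALES) | set(_MINIMA_SCALES)):
        if s > 0:
            smoothed[s] = ndimage.gaussian_filter(lum, s, mode="mirror")
    i = 2
    for s in _LV_SCALES:
        feats[i] = np.log1p(laplacian_variance(smoothed[s]))
        i += 1
    for s in _GRAD_SCALES:
        gy, gx = np.gradient(smoothed[s])
        feats[i] = np.log1p(float((gx * gx + gy * gy).mean()))
        i += 1
    # blob counts: local minima that dip a fixed depth below the smooth
    # local background.  The absolute depth threshold makes the detector
    # deliberately fragile to blur — small blobs fall under it first.
    coarse = ndimage.gaussian_filter(lum, 8.0, mode="mirror")
    for s, depth in zip(_MINIMA_SCALES, _MINIMA_DEPTHS):
        sm = smoothed[s]
        local_min = sm == ndimage.minimum_filter(sm, size=5, mode="mirror")
        deep = (coarse - sm) > depth
        feats[i] = float(np.count_nonzero(local_min & deep))
        i += 1

    hist, _ = np.histogram(lum, bins=64, range=(0.0, 256.0))
    p = hist / hist.sum()
    p = p[p > 0]
    feats[10] = float(-(p * np.log2(p)).sum())
    feats[11] = float((lum < mean - 25.0).mean())
    return feats


def extract_bag_features(bag: SlideBag, sigma: float = 0.0) -> np.ndarray:
    """Feature matrix (n_tiles x 12) for a bag, optionally blurred first.

    Blur is applied before feature extraction, mirroring the evaluation
    pipeline (features always describe the pixels a model would see).
    """
    rows = [
        extract_features(apply_blur(t.image, sigma) if sigma > 0 else t.image)
        for t in bag.tiles
    ]
    return np.asarray(rows)


@dataclass(frozen=True)
class ExpertSpec:
    expert_id: str
    train_sigma: float
    kind: str  # "tile_classifier" | "attention_bag"
    feature_dim: int = FEATURE_DIM
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.train_sigma <= 10.0):
            raise ValueError(f"train_sigma must be in [0, 10]: {self.train_sigma}")
        if self.kind not in ("tile_classifier", "attention_bag"):
            raise ValueError(f"unknown expert kind {self.kind!r}")


@dataclass(frozen=True)
class TrainConfig:
    """Fixed-epoch full-batch gradient-descent settings (deterministic)."""

    epochs: int = 400
    learning_rate: float = 0.5
    l2: float = 1e-3
    attention_hidden: int = 8
    attention_epochs: int = 400
    attention_learning_rate: float = 0.2
    dropout: float = 0.0  # applied to attention activations during training only


@dataclass
class TrainedExpert:
    """A fitted expert: spec + parameter arrays + training metadata."""

    spec: ExpertSpec
    params: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "spec": asdict(self.spec),
            "params": {k: v.tolist() for k, v in self.params.items()},
            "metadata": self.metadata,
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TrainedExpert":
        payload = json.loads(text)
        return cls(
            spec=ExpertSpec(**payload["spec"]),
            params={k: np.asarray(v) for k, v in payload["params"].items()},
            metadata=payload.get("metadata", {}),
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


#: Dynamic range of the feature squash, in training-set standard
#: deviations.  Features are standardised to the expert's training
#: statistics and clipped at +/- SQUASH_RANGE sd: inputs from the wrong
#: blur band pin at the rails and carry no ordering at all, so a
#: mismatched expert returns neutral (tied) scores instead of garbage.
SQUASH_RANGE = 2.5


def _squash(X: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    # standardise to training statistics, then hard-limit the range
    z = (X - mu) / sd
    return np.clip(z, -SQUASH_RANGE, SQUASH_RANGE) / SQUASH_RANGE


def _training_matrix(train_bags, sigma):
    X, y = [], []
    for bag in train_bags:
        if not bag.tiles:
            raise ValueError(f"empty bag {bag.slide_id!r} in training set")
        F = extract_bag_features(bag, sigma)
        X.append(F)
        y.append(np.full(len(bag.tiles), bag.label))
    return np.vstack(X), np.concatenate(y)


def _check_two_classes(labels) -> None:
    if len(set(int(l) for l in labels)) < 2:
        raise ValueError("training data contains a single class")


def train_tile_expert(
    train_bags: list[SlideBag],
    labels=None,
    sigma: float = 0.0,
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
    expert_id: str | None = None,
) -> TrainedExpert:
    """Train a tile-level logistic expert at one fixed blur level.

    Every training tile is blurred at exactly ``sigma`` before feature
    extraction; tiles inherit their slide's label.  The classifier is a
    logistic-loss linear model on standardised, range-clipped features,
    fitted by full-batch gradient descent for a fixed number of epochs
    from a seeded initialisation.
    """
    if labels is None:
        labels = [b.label for b in train_bags]
    _check_two_classes(labels)
    if not (0.0 <= sigma <= 10.0):
        raise ValueError(f"sigma must be in [0, 10], got {sigma}")
    X, y = _training_matrix(train_bags, sigma)
    mu = X.mean(axis=0)
    sd = np.maximum(X.std(axis=0), 1e-8)
    Z = _squash(X, mu, sd)

    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, 0.01, size=Z.shape[1])
    b = 0.0
    n = len(y)
    lr = config.learning_rate
    loss = np.inf
    for _ in range(config.epochs):
        p = _sigmoid(Z @ w + b)
        err = p - y
        gw = Z.T @ err / n + config.l2 * w
        gb = err.mean()
        w -= lr * gw
        b -= lr * gb
    eps = 1e-12
    p = _sigmoid(Z @ w + b)
    loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))

    spec = ExpertSpec(
        expert_id=expert_id or f"tile_sigma_{sigma:g}",
        train_sigma=sigma,
        kind="tile_classifier",
        seed=seed,
    )
    params = {"mu": mu, "sd": sd, "w": w, "b": np.array([b])}
    return TrainedExpert(spec, params,
                         {"epochs": config.epochs, "final_loss": loss})


def predict_tiles_from_features(expert: TrainedExpert, F: np.ndarray) -> np.ndarray:
    """Class-1 probabilities for a feature matrix (n_tiles x feature_dim)."""
    if expert.spec.kind != "tile_classifier":
        raise ValueError(f"expert {expert.spec.expert_id!r} is not a tile classifier")
    Z = _squash(np.atleast_2d(F), expert.params["mu"], expert.params["sd"])
    return _sigmoid(Z @ expert.params["w"] + expert.params["b"][0])


def predict_tile(expert: TrainedExpert, tile: np.ndarray) -> float:
    """Class-1 probability for a single tile image."""
    return float(predict_tiles_from_features(expert, extract_features(tile))[0])


# ---------------------------------------------------------------------------
# gated-attention MIL head
# ---------------------------------------------------------------------------

def _attention_forward(params, Z):
    """Gated attention pooling over preprocessed instance features Z (n x d).

    Returns (probability, cache for backprop).
    """
    T = np.tanh(Z @ params["V"].T)          # n x h
    S = _sigmoid(Z @ params["U"].T)         # n x h
    A = T * S                               # n x h
    s = A @ params["wa"]                    # n
    s = s - s.max()
    e = np.exp(s)
    a = e / e.sum()                         # attention weights
    z = a @ Z                               # bag embedding, d
    logit = float(z @ params["wc"] + params["bc"][0])
    p = float(_sigmoid(np.array([logit]))[0])
    return p, {"T": T, "S": S, "A": A, "a": a, "z": z, "Z": Z}


def train_attention_expert(
    train_bags: list[SlideBag],
    labels=None,
    sigma: float = 0.0,
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
    expert_id: str | None = None,
    feature_bags: list[np.ndarray] | None = None,
) -> TrainedExpert:
    """Train a gated-attention MIL expert at one fixed blur level.

    Per-tile scores come from tanh and sigmoid branches of hidden width
    ``attention_hidden``, softmax-normalised over the bag; the bag
    embedding is the attention-weighted feature sum, classified by a
    linear layer.  Bag-level supervision only, cross-entropy loss,
    full-batch gradient descent.  ``feature_bags`` may supply precomputed
    raw (unsquashed) per-bag feature matrices for the requested sigma.
    """
    if labels is None:
        labels = [b.label for b in train_bags]
    labels = np.asarray(labels, dtype=float)
    _check_two_classes(labels)
    if feature_bags is None:
        feature_bags = [extract_bag_features(b, sigma) for b in train_bags]
    for bag, F in zip(train_bags, feature_bags):
        if F.shape[0] == 0:
            raise ValueError(f"empty bag {bag.slide_id!r} in training set")

    Xall = np.vstack(feature_bags)
    mu = Xall.mean(axis=0)
    sd = np.maximum(Xall.std(axis=0), 1e-8)
    Zbags = [_squash(F, mu, sd) for F in feature_bags]
    d = Xall.shape[1]
    h = config.attention_hidden

    rng = np.random.default_rng(seed)
    params = {
        "V": rng.normal(0.0, 0.1, size=(h, d)),
        "U": rng.normal(0.0, 0.1, size=(h, d)),
        "wa": rng.normal(0.0, 0.1, size=h),
        "wc": rng.normal(0.0, 0.1, size=d),
        "bc": np.zeros(1),
    }
    lr = config.attention_learning_rate
    n_bags = len(Zbags)
    loss = np.inf
    for _ in range(config.attention_epochs):
        grads = {k: np.zeros_like(v) for k, v in params.items()}
        loss = 0.0
        for Z, y in zip(Zbags, labels):
            if config.dropout > 0:
                keep = rng.random(Z.shape[0]) >= config.dropout
                if keep.any():
                    Z = Z[keep]
            p, c = _attention_forward(params, Z)
            eps = 1e-12
            loss += -(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
            dlogit = p - y
            grads["wc"] += dlogit * c["z"]
            grads["bc"][0] += dlogit
            dz = dlogit * params["wc"]                     # d
            da = c["Z"] @ dz                               # n
            ds = c["a"] * (da - float(c["a"] @ da))        # softmax backprop
            grads["wa"] += c["A"].T @ ds
            dA = np.outer(ds, params["wa"])                # n x h
            dT = dA * c["S"]
            dS = dA * c["T"]
            grads["V"] += (dT * (1 - c["T"] ** 2)).T @ c["Z"]
            grads["U"] += (dS * c["S"] * (1 - c["S"])).T @ c["Z"]
        for k in params:
            params[k] -= lr * (grads[k] / n_bags + config.l2 * params[k])
        loss /= n_bags

    spec = ExpertSpec(
        expert_id=expert_id or f"attn_sigma_{sigma:g}",
        train_sigma=sigma,
        kind="attention_bag",
        seed=seed,
    )
    params_out = dict(params)
    params_out["mu"] = mu
    params_out["sd"] = sd
    return TrainedExpert(spec, params_out,
                         {"epochs": config.attention_epochs,
                          "final_loss": float(loss)})


def predict_bag_attention(expert: TrainedExpert, features: np.ndarray) -> float:
    """Slide-level probability from a bag of raw tile feature vectors.

    Deterministic and invariant to tile order (attention weights are
    softmax-normalised over the bag before pooling).
    """
    if expert.spec.kind != "attention_bag":
        raise ValueError(f"expert {expert.spec.expert_id!r} is not an attention expert")
    F = np.atleast_2d(np.asarray(features, dtype=float))
    if F.shape[0] == 0:
        raise ValueError("cannot predict on an empty bag")
    Z = _squash(F, expert.params["mu"], expert.params["sd"])
    p, _ = _attention_forward(expert.params, Z)
    return p


def attention_weights(expert: TrainedExpert, features: np.ndarray) -> np.ndarray:
    """Softmax attention weights the expert assigns over a bag's tiles."""
    F = np.atleast_2d(np.asarray(features, dtype=float))
    Z = _squash(F, expert.params["mu"], expert.params["sd"])
    _, cache = _attention_forward(expert.params, Z)
    return cache["a"]
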