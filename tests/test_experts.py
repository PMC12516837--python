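"""Handcrafted features and the two expert heads (tile logistic, gated MIL)."""

import numpy as np
import pytest

from blurmoe.benchmark import auc
from blurmoe.blur import apply_blur
from blurmoe.experts import (
    FEATURE_DIM,
    FEATURE_NAMES,
    ExpertSpec,
    TrainConfig,
    TrainedExpert,
    attention_weights,
    extract_bag_features,
    extract_features,
    predict_bag_attention,
    predict_tile,
    predict_tiles_from_features,
    train_attention_expert,
    train_tile_expert,
)
from blurmoe.moe import aggregate_75th


class TestFeatures:
    def test_constant_tile_has_zero_texture_components(self):
        f = extract_features(np.full((32, 32), 77, dtype=np.uint8))
        named = dict(zip(FEATURE_NAMES, f))
        assert named["sd_intensity"] == 0.0
        assert named["log_lv_s0"] == 0.0
        assert named["log_grad_energy_s1"] == 0.0
        assert named["minima_count_s1"] == 0.0
        assert named["dark_fraction"] == 0.0
        assert np.isfinite(f).all()

    def test_blur_shrinks_sharpness_components(self, textured_tiles):
        j = FEATURE_NAMES.index("log_lv_s0")
        g = FEATURE_NAMES.index("log_grad_energy_s1")
        for tile in textured_tiles[:8]:
            sharp = extract_features(tile)
            blurred = extract_features(apply_blur(tile, 4.0))
            assert blurred[j] < sharp[j]
            assert blurred[g] < sharp[g]

    def test_deterministic(self, textured_tiles):
        t = textured_tiles[0]
        assert np.array_equal(extract_features(t), extract_features(t))

    def test_vector_length(self, textured_tiles):
        assert extract_features(textured_tiles[0]).shape == (FEATURE_DIM,)


@pytest.fixture(scope="module")
def split_cohort(small_cohort):
    train = small_cohort.bags[:40]
    val = small_cohort.bags[40:]
    return train, val


class TestTileExpert:
    def test_training_is_deterministic(self, split_cohort):
        train, _ = split_cohort
        a = train_tile_expert(train[:10], sigma=1.0, seed=5)
        b = train_tile_expert(train[:10], sigma=1.0, seed=5)
        assert np.array_equal(a.params["w"], b.params["w"])
        assert a.to_json() == b.to_json()

    def test_single_class_rejected(self, split_cohort):
        train, _ = split_cohort
        ones = [b for b in train if b.label == 1][:4]
        with pytest.raises(ValueError, match="single class"):
            train_tile_expert(ones, sigma=0.0)

    def test_sigma_out_of_range_rejected(self, split_cohort):
        train, _ = split_cohort
        with pytest.raises(ValueError, match=r"\[0, 10\]"):
            train_tile_expert(train, sigma=11.0)

    def test_baseline_separates_sharp_validation(self, split_cohort):
        train, val = split_cohort
        expert = train_tile_expert(train, sigma=0.0, seed=2)
        scores = [
            aggregate_75th(
                predict_tiles_from_features(expert, extract_bag_features(b)))
            for b in val
        ]
        assert auc([b.label for b in val], scores) >= 0.85

    def test_blur_matched_expert_beats_baseline_on_blurred_data(self, split_cohort):
        train, val = split_cohort
        base = train_tile_expert(train, sigma=0.0, seed=2)
        matched = train_tile_expert(train, sigma=5.0, seed=2)
        labels = [b.label for b in val]
        feats = [extract_bag_features(b, 5.0) for b in val]
        auc_base = auc(labels, [
            aggregate_75th(predict_tiles_from_features(base, F)) for F in feats])
        auc_matched = auc(labels, [
            aggregate_75th(predict_tiles_from_features(matched, F)) for F in feats])
        assert auc_matched > auc_base

    def test_zero_score_gives_half_probability(self):
        spec = ExpertSpec("z", 0.0, "tile_classifier")
        expert = TrainedExpert(spec, {
            "mu": np.zeros(FEATURE_DIM), "sd": np.ones(FEATURE_DIM),
            "w": np.zeros(FEATURE_DIM), "b": np.array([0.0])})
        tile = np.random.default_rng(0).integers(0, 255, (32, 32)).astype(np.uint8)
        assert predict_tile(expert, tile) == pytest.approx(0.5)

    def test_monotone_in_positively_weighted_feature(self):
        spec = ExpertSpec("m", 0.0, "tile_classifier")
        w = np.zeros(FEATURE_DIM)
        w[0] = 2.0
        expert = TrainedExpert(spec, {
            "mu": np.zeros(FEATURE_DIM), "sd": np.ones(FEATURE_DIM),
            "w": w, "b": np.array([0.0])})
        lo = np.zeros((1, FEATURE_DIM))
        hi = np.zeros((1, FEATURE_DIM))
        hi[0, 0] = 1.0
        assert (predict_tiles_from_features(expert, hi)
                > predict_tiles_from_features(expert, lo))

    def test_batch_matches_per_tile(self, split_cohort, textured_tiles):
        train, _ = split_cohort
        expert = train_tile_expert(train[:10], sigma=0.0, seed=1)
        F = np.stack([extract_features(t) for t in textured_tiles[:6]])
        batch = predict_tiles_from_features(expert, F)
        singles = [predict_tile(expert, t) for t in textured_tiles[:6]]
        assert np.allclose(batch, singles, atol=1e-12)

    def test_wrong_kind_rejected(self, split_cohort):
        train, _ = split_cohort
        attn = train_attention_expert(train[:10], sigma=0.0, seed=0,
                                      config=TrainConfig(attention_epochs=5))
        with pytest.raises(ValueError, match="not a tile classifier"):
            predict_tiles_from_features(attn, np.zeros((1, FEATURE_DIM)))


class TestAttentionExpert:
    @pytest.fixture(scope="class")
    def trained(self, split_cohort):
        train, _ = split_cohort
        return train_attention_expert(train[:20], sigma=0.0, seed=4,
                                      config=TrainConfig(attention_epochs=100))

    def test_attention_weights_sum_to_one(self, trained, textured_tiles):
        F = np.stack([extract_features(t) for t in textured_tiles[:7]])
        a = attention_weights(trained, F)
        assert a.sum() == pytest.approx(1.0, abs=1e-9)

    def test_identical_tiles_get_uniform_attention(self, trained, textured_tiles):
        F = np.tile(extract_features(textured_tiles[0]), (5, 1))
        a = attention_weights(trained, F)
        assert np.allclose(a, 0.2, atol=1e-12)

    def test_permutation_invariance(self, trained, textured_tiles):
        F = np.stack([extract_features(t) for t in textured_tiles[:9]])
        p1 = predict_bag_attention(trained, F)
        rng = np.random.default_rng(2)
        p2 = predict_bag_attention(trained, F[rng.permutation(9)])
        assert abs(p1 - p2) < 1e-12

    def test_duplication_invariance(self, trained, textured_tiles):
        F = np.stack([extract_features(t) for t in textured_tiles[:5]])
        p1 = predict_bag_attention(trained, F)
        p2 = predict_bag_attention(trained, np.vstack([F, F]))
        assert abs(p1 - p2) < 1e-9

    def test_single_tile_bag(self, trained, textured_tiles):
        F = extract_features(textured_tiles[0])[None, :]
        p = predict_bag_attention(trained, F)
        assert 0.0 <= p <= 1.0

    def test_empty_bag_rejected(self, trained):
        with pytest.raises(ValueError, match="empty"):
            predict_bag_attention(trained, np.zeros((0, FEATURE_DIM)))

    def test_training_deterministic(self, split_cohort):
        train, _ = split_cohort
        cfg = TrainConfig(attention_epochs=20)
        a = train_attention_expert(train[:8], sigma=0.0, seed=7, config=cfg)
        b = train_attention_expert(train[:8], sigma=0.0, seed=7, config=cfg)
        assert a.to_json() == b.to_json()

    def test_empty_training_bag_rejected(self, split_cohort):
        from blurmoe.types import SlideBag

        train, _ = split_cohort
        bad = train[:4] + [SlideBag("E", "E", 0, [])]
        with pytest.raises(ValueError, match="empty bag"):
            train_attention_expert(bad, sigma=0.0)

    def test_gradients_match_finite_differences(self):
        # analytic backprop of the gated-attention head vs central
        # differences on a tiny random problem
        from blurmoe.experts import _attention_forward

        rng = np.random.default_rng(13)
        d, h = 4, 3
        params = {
            "V": rng.normal(size=(h, d)), "U": rng.normal(size=(h, d)),
            "wa": rng.normal(size=h), "wc": rng.normal(size=d),
            "bc": np.zeros(1),
        }
        Z = rng.normal(size=(6, d))
        y = 1.0

        def loss_of(p):
            prob, _ = _attention_forward(p, Z)
            eps = 1e-12
            return -(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps))

        # analytic gradients (same code path as training)
        p, c = _attention_forward(params, Z)
        dlogit = p - y
        grads = {k: np.zeros_like(v) for k, v in params.items()}
        grads["wc"] = dlogit * c["z"]
        grads["bc"][0] = dlogit
        dz = dlogit * params["wc"]
        da = c["Z"] @ dz
        ds = c["a"] * (da - float(c["a"] @ da))
        grads["wa"] = c["A"].T @ ds
        dA = np.outer(ds, params["wa"])
        dT = dA * c["S"]
        dS = dA * c["T"]
        grads["V"] = (dT * (1 - c["T"] ** 2)).T @ c["Z"]
        grads["U"] = (dS * c["S"] * (1 - c["S"])).T @ c["Z"]

        h_eps = 1e-6
        for key in params:
            flat = params[key].reshape(-1)
            gflat = grads[key].reshape(-1)
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + h_eps
                up = loss_of(params)
                flat[i] = orig - h_eps
                dn = loss_of(params)
                flat[i] = orig
                num = (up - dn) / (2 * h_eps)
                assert num == pytest.approx(gflat[i], rel=1e-4, abs=1e-7), key
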