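"""Classifier architecture, inference contracts, training, checkpoints."""

from __future__ import annotations

import numpy as np
import pytest

from envdesign import dataset, nn
from envdesign.featurize import build_environment, featurize
from envdesign.geometry import apply_rigid_motion, random_rotation
from envdesign.model import (
    ClassifierModel,
    ModelConfig,
    TrainingConfig,
    confidence_score,
    embed_environment,
    init_model,
    load_checkpoint,
    predict_batch,
    predict_distribution,
    save_checkpoint,
    train,
)

SMALL = ModelConfig(layers=2, heads=2, head_dim=8, seed=0)


@pytest.fixture(scope="module")
def helix_features():
    st = dataset.make_ideal_backbone(12, "helix", seed=0)
    seq = st.native_sequence()
    return [featurize(build_environment(st, seq, i, 12.0)) for i in range(12)]


class TestInit:
    def test_default_width_is_256(self):
        cfg = ModelConfig()
        assert cfg.model_dim == 256
        assert cfg.layers == 3 and cfg.heads == 16 and cfg.head_dim == 16

    def test_same_seed_gives_identical_parameters(self):
        a = init_model(ModelConfig(layers=2, heads=2, head_dim=8, seed=7))
        b = init_model(ModelConfig(layers=2, heads=2, head_dim=8, seed=7))
        assert a.params.keys() == b.params.keys()
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_different_seed_changes_parameters(self):
        a = init_model(ModelConfig(layers=1, heads=2, head_dim=8, seed=1))
        b = init_model(ModelConfig(layers=1, heads=2, head_dim=8, seed=2))
        assert not np.array_equal(a.params["in.W"], b.params["in.W"])

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError):
            init_model(ModelConfig(layers=0))
        with pytest.raises(ValueError):
            init_model(ModelConfig(n_classes=21))


class TestForward:
    def test_embedding_preserves_row_count(self, helix_features):
        m = init_model(SMALL)
        for f in helix_features[:3]:
            emb = embed_environment(m, f)
            assert emb.shape == (f.k, SMALL.model_dim)

    def test_default_model_embeds_to_256(self):
        m = init_model(ModelConfig())
        st = dataset.make_ideal_backbone(5, "helix", seed=1)
        f = featurize(build_environment(st, st.native_sequence(), 2, 12.0))
        assert embed_environment(m, f).shape == (f.k, 256)

    def test_distribution_is_normalized_20_way(self, helix_features):
        m = init_model(SMALL)
        for f in helix_features:
            d = predict_distribution(m, f)
            assert d.shape == (20,)
            assert d.min() >= 0
            assert d.sum() == pytest.approx(1.0, abs=1e-6)

    def test_prediction_is_deterministic(self, helix_features):
        m = init_model(SMALL)
        a = predict_distribution(m, helix_features[0])
        b = predict_distribution(m, helix_features[0])
        assert np.array_equal(a, b)

    def test_neighbor_permutation_invariance(self, helix_features):
        m = init_model(SMALL)
        rng = np.random.default_rng(0)
        for f in helix_features[:4]:
            perm = rng.permutation(f.k)
            a = predict_distribution(m, f.matrix)
            b = predict_distribution(m, f.matrix[perm])
            assert np.allclose(a, b, atol=1e-5)
            emb_a = embed_environment(m, f.matrix)
            emb_b = embed_environment(m, f.matrix[perm])
            assert np.allclose(emb_a[perm], emb_b, atol=1e-5)

    def test_padding_never_changes_predictions(self, helix_features):
        m = init_model(SMALL)
        batch = [helix_features[0], helix_features[5]]
        joint = predict_batch(m, batch)
        for i, f in enumerate(batch):
            alone = predict_distribution(m, f)
            assert np.allclose(joint[i], alone, atol=1e-5)

    def test_rigid_motion_invariance_of_predictions(self):
        m = init_model(SMALL)
        rng = np.random.default_rng(1)
        st = dataset.make_ideal_backbone(10, "helix", seed=2)
        seq = st.native_sequence()
        moved = apply_rigid_motion(st, random_rotation(rng), rng.normal(size=3) * 10)
        for i in range(len(st)):
            a = predict_distribution(m, featurize(build_environment(st, seq, i, 12.0)))
            b = predict_distribution(m, featurize(build_environment(moved, seq, i, 12.0)))
            assert np.allclose(a, b, atol=1e-5)

    def test_wrong_feature_width_rejected(self):
        m = init_model(SMALL)
        with pytest.raises(ValueError):
            predict_distribution(m, np.zeros((3, 45)))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients agree with central differences (float32)."""
        rng = np.random.default_rng(0)
        params = nn.init_params(10, 16, 2, 5, seed=3)
        X = rng.normal(size=(4, 3, 10))
        mask = np.ones((4, 3))
        mask[2, 2] = 0
        y = rng.integers(0, 5, size=4)

        def loss_of(params):
            probs, _, _, cache = nn.forward(params, X, mask, 2, 2, want_cache=True)
            loss, dlogits = nn.cross_entropy(probs, y)
            return loss, cache, dlogits

        loss, cache, dlogits = loss_of(params)
        grads = nn.backward(params, cache, dlogits, 2, 2)
        eps = 1e-2
        for name in ("in.W", "layer0.attn.Wq", "layer1.fc.W", "head.W",
                     "layer0.ln1.g"):
            p = params[name]
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp, _, _ = loss_of(params)
                p[idx] = orig - eps
                lm, _, _ = loss_of(params)
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[name][idx]
                assert num == pytest.approx(ana, abs=2e-3, rel=5e-2)


class TestTrain:
    def test_zero_epochs_returns_identical_model(self, helix_features):
        m = init_model(SMALL)
        trained, trace = train(
            m, [f.matrix for f in helix_features],
            [0] * len(helix_features), TrainingConfig(epochs=0),
        )
        assert trace == []
        for k in m.params:
            assert np.array_equal(m.params[k], trained.params[k])

    def test_loss_decreases_on_toy_rule(self):
        samples = dataset.make_toy_rule_dataset(
            2000, dataset.ToyRuleParams(noise=0.0, seed=1)
        )
        m = init_model(ModelConfig(layers=1, heads=2, head_dim=8, seed=0))
        _, trace = train(
            m, [s.features.matrix for s in samples], [s.label for s in samples],
            TrainingConfig(epochs=30, seed=0),
        )
        assert len(trace) == 30
        assert trace[-1] < trace[0]
        assert np.isfinite(trace).all()

    def test_training_recipe_defaults(self):
        cfg = TrainingConfig()
        assert cfg.learning_rate == 1e-3
        assert (cfg.adam_beta1, cfg.adam_beta2) == (0.9, 0.999)
        assert cfg.batch_size == 1000

    def test_invalid_labels_rejected(self, helix_features):
        m = init_model(SMALL)
        with pytest.raises(ValueError):
            train(m, [helix_features[0].matrix], [20], TrainingConfig(epochs=1))

    def test_empty_dataset_rejected(self):
        m = init_model(SMALL)
        with pytest.raises(ValueError):
            train(m, [], [], TrainingConfig(epochs=1))

    def test_training_is_seeded(self, helix_features):
        feats = [f.matrix for f in helix_features]
        labels = list(range(12))[:len(feats)]
        labels = [l % 20 for l in labels]
        runs = []
        for _ in range(2):
            m = init_model(SMALL)
            trained, _ = train(m, feats, labels, TrainingConfig(epochs=3, seed=5))
            runs.append(predict_distribution(trained, helix_features[0]))
        assert np.array_equal(runs[0], runs[1])


class TestConfidence:
    def test_uniform_is_minus_ln20(self):
        assert confidence_score(np.full(20, 0.05)) == pytest.approx(-np.log(20))

    def test_point_mass_is_zero(self):
        d = np.zeros(20)
        d[4] = 1.0
        assert confidence_score(d) == 0.0

    def test_two_way_split_is_minus_ln2(self):
        d = np.zeros(20)
        d[0] = d[1] = 0.5
        assert confidence_score(d) == pytest.approx(-np.log(2))

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            confidence_score(np.full(20, 0.06))


class TestCheckpoint:
    def test_roundtrip_predictions_bitwise_identical(self, tmp_path, helix_features):
        m = init_model(SMALL)
        before = predict_batch(m, helix_features)
        path = tmp_path / "model.npz"
        save_checkpoint(m, path)
        loaded = load_checkpoint(path)
        assert loaded.config == m.config
        after = predict_batch(loaded, helix_features)
        assert np.array_equal(before, after)

    def test_bad_format_version_rejected(self, tmp_path):
        import json
        m = init_model(SMALL)
        path = tmp_path / "model.npz"
        save_checkpoint(m, path)
        data = dict(np.load(path))
        meta = json.loads(bytes(data["__meta__"]).decode())
        meta["format_version"] = 999
        data["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **data)
        with pytest.raises(ValueError, match="format"):
            load_checkpoint(path)
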