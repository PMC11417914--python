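import numpy as np
import pytest

from deamipred.chimeric_model import (
    FeatureSet,
    TrainedModel,
    build_model,
    featurize_candidates,
    featurize_labeled,
    predict,
    train,
)
from deamipred.errors import ConfigError, ShapeError, TrainingError, ValidationError
from deamipred.global_embedding import make_mock_embedder
from deamipred.io_formats import ChainSequence, RunConfig, SiteTimeCourse
from deamipred.labeling import LabeledSite
from tests.conftest import _split


def make_features(n=120, d=6, w=5, seed=0, separable=False):
    """Synthetic FeatureSet; optionally linearly separable in X_global."""
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.4).astype(int)
    X = rng.standard_normal((n, d))
    if separable:
        X[:, 0] = y * 4.0 - 2.0
    tokens = rng.integers(0, 22, (n, w))
    tokens[:, (w - 1) // 2] = 12  # N
    targets = np.clip(rng.uniform(0, 40, (n, 3)), 0, 100)
    prov = [("m", "HC", i + 1, "N") for i in range(n)]
    return FeatureSet(X, tokens, prov, "mock-d6-s0", w, y=y, targets=targets)


@pytest.fixture(scope="module")
def tiny_cfg():
    return RunConfig(window_size=5, hidden_widths=(8,), dropout=0.0, token_dim=4,
                     lstm_hidden=4, max_epochs=10, patience=3, batch_size=32)


class TestBuildModel:
    def test_chimeric_head_width_is_sum(self):
        cfg = RunConfig()  # defaults: lstm_hidden 64 -> local output 128
        m = build_model("chimeric", "classification", cfg, d=1280)
        assert m.head_input_dim == 1280 + 128

    def test_local_only_head_width(self, tiny_cfg):
        m = build_model("local_only", "classification", tiny_cfg, d=99)
        assert m.head_input_dim == 2 * tiny_cfg.lstm_hidden

    def test_regression_output_is_three(self, tiny_cfg):
        m = build_model("chimeric", "regression", tiny_cfg, d=6)
        assert m.network.head.widths[-1] == 3

    def test_bad_dimension(self, tiny_cfg):
        with pytest.raises(ConfigError):
            build_model("global_only", "classification", tiny_cfg, d=0)

    def test_bad_variant(self, tiny_cfg):
        with pytest.raises(ConfigError):
            build_model("hybrid", "classification", tiny_cfg, d=4)


class TestTraining:
    def test_seeded_determinism(self, tiny_cfg):
        feats = make_features()
        tr, va = feats.subset(range(100)), feats.subset(range(100, 120))
        runs = []
        for _ in range(2):
            m = build_model("global_only", "classification", tiny_cfg, feats.dim)
            runs.append(train(m, tr, va, tiny_cfg))
        assert runs[0].val_losses == runs[1].val_losses
        np.testing.assert_array_equal(
            runs[0].predict_proba(va), runs[1].predict_proba(va)
        )

    def test_patience_zero_stops_after_first_non_improvement(self, tiny_cfg):
        cfg = RunConfig.from_dict({**tiny_cfg.to_dict(), "patience": 0, "max_epochs": 50})
        feats = make_features(seed=2)
        tr, va = feats.subset(range(100)), feats.subset(range(100, 120))
        m = build_model("global_only", "classification", cfg, feats.dim)
        tm = train(m, tr, va, cfg)
        losses = tm.val_losses
        if tm.epochs_run < cfg.max_epochs:
            # every epoch before the last must have improved on the running best
            best = np.inf
            for v in losses[:-1]:
                assert v < best
                best = v
            assert losses[-1] >= min(losses[:-1])

    def test_single_class_split_rejected(self, tiny_cfg):
        feats = make_features()
        idx = np.where(feats.y == 0)[0]
        with pytest.raises(TrainingError, match="single class"):
            m = build_model("global_only", "classification", tiny_cfg, feats.dim)
            train(m, feats.subset(idx), feats.subset(range(5)), tiny_cfg)

    def test_separable_features_reach_perfect_training_accuracy(self, tiny_cfg):
        cfg = RunConfig.from_dict({**tiny_cfg.to_dict(), "max_epochs": 200, "patience": 200,
                                   "weight_decay": 0.0, "learning_rate": 1e-2})
        feats = make_features(separable=True)
        tr, va = feats.subset(range(100)), feats.subset(range(100, 120))
        m = build_model("global_only", "classification", cfg, feats.dim)
        tm = train(m, tr, va, cfg)
        acc = np.mean((tm.predict_proba(tr) > 0.5).astype(int) == tr.y)
        assert acc == 1.0

    def test_regression_training_runs_and_clamps(self, tiny_cfg):
        feats = make_features()
        tr, va = feats.subset(range(100)), feats.subset(range(100, 120))
        m = build_model("chimeric", "regression", tiny_cfg, feats.dim)
        tm = train(m, tr, va, tiny_cfg)
        ext = tm.predict_extents(va)
        assert ext.shape == (20, 3)
        assert np.all(ext >= 0) and np.all(ext <= 100)


class TestPredict:
    @pytest.fixture(scope="class")
    def linear_model(self):
        """Hand-built global_only model with known weights: logit = x0."""
        cfg = RunConfig(window_size=5, hidden_widths=(), dropout=0.0)
        m = build_model("global_only", "classification", cfg, d=2)
        params = {"head.W0": np.array([[1.0], [0.0]]), "head.b0": np.zeros(1)}
        return TrainedModel(variant="global_only", task="classification", config=cfg,
                            d=2, params=params, epochs_run=0, best_epoch=0, val_losses=[])

    def _feats(self, x0):
        X = np.array([[x0, 0.0]])
        return FeatureSet(X, np.zeros((1, 5), np.int64), [("m", "HC", 1, "N")],
                          "mock", 5)

    def test_above_threshold_active(self, linear_model):
        (p,) = predict(linear_model, self._feats(0.85))  # sigmoid(0.85) ~ 0.70
        assert p.predicted_label == "active"
        assert p.probability == pytest.approx(1 / (1 + np.exp(-0.85)))

    def test_boundary_is_inactive(self, linear_model):
        (p,) = predict(linear_model, self._feats(0.0))  # probability exactly 0.5
        assert p.probability == 0.5
        assert p.predicted_label == "inactive"  # strict >

    def test_global_only_ignores_windows(self, linear_model):
        f1 = self._feats(0.3)
        f2 = self._feats(0.3)
        f2.tokens = np.full_like(f2.tokens, 7)
        assert predict(linear_model, f1)[0].probability == predict(linear_model, f2)[0].probability

    def test_dimension_mismatch_names_shapes(self, linear_model):
        bad = FeatureSet(np.zeros((1, 9)), np.zeros((1, 5), np.int64),
                         [("m", "HC", 1, "N")], "mock", 5)
        with pytest.raises(ShapeError, match="expected global dim 2, got 9"):
            predict(linear_model, bad)


class TestCheckpoint:
    def test_roundtrip(self, trained_global_model, small_features, tmp_path):
        trained_global_model.save(tmp_path / "ckpt")
        loaded = TrainedModel.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(
            trained_global_model.predict_proba(small_features),
            loaded.predict_proba(small_features),
        )
        assert loaded.config == trained_global_model.config
        assert loaded.embedder_name == trained_global_model.embedder_name


class TestFeaturize:
    def test_residue_mismatch_detected(self, small_dataset, fast_config):
        chains, sites, _ = small_dataset
        bad_site = SiteTimeCourse(chains[0].molecule_id, chains[0].chain_id, 1, "N"
                                  if chains[0].sequence[0] != "N" else "Q", {})
        ls = LabeledSite(site=bad_site, label="inactive", regression_targets={})
        with pytest.raises(ValidationError, match="residue mismatch"):
            featurize_labeled([ls], chains, make_mock_embedder(8, 0), 5)

    def test_candidates_cover_all_nq_sites(self):
        chains = [ChainSequence("a", "HC", "ANGQSN"), ChainSequence("a", "LC", "QQAA")]
        feats = featurize_candidates(chains, make_mock_embedder(8, 0), 5)
        assert len(feats) == 5  # N2, Q4, N6 + Q1, Q2
        assert feats.y is None

    def test_alignment_with_matrix(self, small_dataset, fast_config):
        from deamipred.global_embedding import embed_chain

        chains, sites, _ = small_dataset
        emb = make_mock_embedder(16, 0)
        feats = featurize_candidates(chains[:1], emb, 5)
        matrix = embed_chain(emb, chains[0]).vectors
        for i, (_, _, pos, _) in enumerate(feats.provenance):
            np.testing.assert_array_equal(feats.X_global[i], matrix[pos - 1])


def test_chimeric_beats_trivial_on_small_data(small_features, fast_config):
    """Sanity: the chimeric model learns something real on synthetic data."""
    tr, va = _split(small_features)
    m = build_model("chimeric", "classification", fast_config, small_features.dim)
    tm = train(m, tr, va, fast_config)
    probs = tm.predict_proba(small_features)
    from deamipred.evaluation import roc_auc

    assert roc_auc(probs, small_features.y) > 0.8
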