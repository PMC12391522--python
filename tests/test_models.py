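import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from metaharm import (
    BaselineLR,
    EmbeddedPairs,
    FixtureProvider,
    ModelFormatError,
    SiameseFCN,
    SplitPlan,
    TrainConfig,
    TrainedScorer,
    ValidationError,
    build_pair_dataset,
    fit_baseline,
    fit_contrastive,
    fit_fcn,
    load_model,
    nce_loss,
    permute_augment,
    save_model,
    split_pairs,
)
from metaharm.models import _fcn_forward_backward, _nce_forward_backward, _init_fcn


def make_embedded(rng, n=200, d=8, separation=1.0):
    """Pairs whose cosine correlates with the label by construction."""
    anchor = rng.standard_normal(d)
    anchor /= np.linalg.norm(anchor)
    y = rng.integers(0, 2, n).astype(float)
    X1 = rng.standard_normal((n, d))
    X2 = np.where(
        y[:, None] == 1,
        X1 + separation * 0.1 * rng.standard_normal((n, d)),
        rng.standard_normal((n, d)),
    )
    return EmbeddedPairs(X1=X1, X2=X2, y=y)


def world_split_embedded(world, seed=0, ratio=3.0):
    dataset = build_pair_dataset(world.corpus, ratio=ratio, seed=seed)
    train, val, test = split_pairs(dataset, SplitPlan(seed=seed))
    prov = world.provider
    return (
        EmbeddedPairs.from_pairs(train, prov),
        EmbeddedPairs.from_pairs(val, prov),
        EmbeddedPairs.from_pairs(test, prov),
    )


class TestScorePair:
    def test_baseline_sigmoid_at_zero_cosine(self):
        model = BaselineLR(slope=1.0, intercept=0.0, dimension=2)
        scorer = TrainedScorer(
            model=model, config=TrainConfig(), history={}, provider_name="t",
            dimension=2, kind="baseline",
        )
        assert scorer.score_pair(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(0.5)

    def test_hand_computed_fcn_forward_pass(self):
        # identity projection, w=1, b=0, e1=e2=(1,1): cos=1 -> sigmoid(1)
        model = SiameseFCN(W=np.eye(2), c=np.zeros(2), w=1.0, b=0.0)
        scorer = TrainedScorer(
            model=model, config=TrainConfig(), history={}, provider_name="t",
            dimension=2, kind="fcn",
        )
        e = np.array([1.0, 1.0])
        assert scorer.score_pair(e, e) == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-9)

    @pytest.mark.parametrize("kind", ["baseline", "fcn"])
    def test_symmetry_under_argument_swap(self, kind):
        rng = np.random.default_rng(3)
        if kind == "baseline":
            model = BaselineLR(slope=2.0, intercept=-0.5, dimension=6)
        else:
            model = SiameseFCN(
                W=rng.standard_normal((4, 6)), c=rng.standard_normal(4),
                w=1.5, b=-0.2,
            )
        scorer = TrainedScorer(
            model=model, config=TrainConfig(), history={}, provider_name="t",
            dimension=6, kind=kind,
        )
        for _ in range(100):
            e1 = rng.standard_normal(6)
            e2 = rng.standard_normal(6)
            assert scorer.score_pair(e1, e2) == scorer.score_pair(e2, e1)

    def test_dimension_mismatch_rejected(self):
        model = BaselineLR(slope=1.0, intercept=0.0, dimension=4)
        scorer = TrainedScorer(
            model=model, config=TrainConfig(), history={}, provider_name="t",
            dimension=4, kind="baseline",
        )
        with pytest.raises(ValidationError, match="dimension"):
            scorer.score_pair(np.ones(3), np.ones(3))

    def test_zero_projection_scores_at_bias(self):
        # a ReLU that zeroes everything: cosine defined as 0 at the head
        model = SiameseFCN(W=-np.eye(2), c=np.zeros(2), w=5.0, b=0.3)
        scorer = TrainedScorer(
            model=model, config=TrainConfig(), history={}, provider_name="t",
            dimension=2, kind="fcn",
        )
        p = scorer.score_pair(np.array([1.0, 1.0]), np.array([2.0, 2.0]))
        assert p == pytest.approx(1 / (1 + np.exp(-0.3)))

    def test_baseline_monotone_in_cosine(self):
        model = BaselineLR(slope=3.0, intercept=0.1, dimension=2)
        angles = np.linspace(0, np.pi, 50)
        probs = [
            model.scores(
                np.array([[1.0, 0.0]]), np.array([[np.cos(a), np.sin(a)]])
            )[0]
            for a in angles
        ]
        assert all(p1 > p2 for p1, p2 in zip(probs, probs[1:]))


class TestGradients:
    """Closed-form gradients against central finite differences."""

    @pytest.mark.parametrize("loss", ["bce", "nce"])
    def test_matches_finite_differences(self, loss):
        rng = np.random.default_rng(11)
        d, h, B = 5, 4, 6
        params = _init_fcn(d, h, rng)
        E1 = rng.standard_normal((B, d))
        E2 = E1 * 0.5 + rng.standard_normal((B, d))
        y = rng.integers(0, 2, B).astype(float)

        if loss == "bce":
            f = lambda prm: _fcn_forward_backward(prm, E1, E2, y)
        else:
            f = lambda prm: _nce_forward_backward(prm, E1, E2, tau=0.2)
        _, grads = f(params)
        eps = 1e-6
        for key in params:
            flat = params[key].ravel()
            for idx in range(min(flat.size, 10)):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = f(params)
                flat[idx] = orig - eps
                lm, _ = f(params)
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert grads[key].ravel()[idx] == pytest.approx(numeric, abs=1e-5), key


class TestFitBaseline:
    def test_separable_cosines_give_positive_slope_and_auc_one(self):
        # matched pairs colinear (+), nonmatched anti-colinear (-)
        base = np.tile(np.array([1.0, 0.0]), (40, 1))
        X2 = np.vstack([np.tile([1.0, 0.0], (20, 1)), np.tile([-1.0, 0.0], (20, 1))])
        y = np.array([1.0] * 20 + [0.0] * 20)
        train = EmbeddedPairs(X1=base, X2=X2, y=y)
        scorer = fit_baseline(train, None, TrainConfig())
        assert scorer.model.slope > 0
        assert roc_auc_score(y, scorer.score_batch(train.X1, train.X2)) == 1.0

    def test_constant_feature_recovers_base_rate_intercept(self):
        # all cosines exactly 0 -> intercept-only MLE is logit of base rate
        n_pos, n_neg = 30, 70
        X1 = np.tile(np.array([1.0, 0.0]), (100, 1))
        X2 = np.tile(np.array([0.0, 1.0]), (100, 1))
        y = np.array([1.0] * n_pos + [0.0] * n_neg)
        scorer = fit_baseline(EmbeddedPairs(X1=X1, X2=X2, y=y), None, TrainConfig())
        p_hat = 1 / (1 + np.exp(-scorer.model.intercept))
        assert p_hat == pytest.approx(n_pos / 100, abs=1e-4)

    def test_permuted_labels_give_chance_auc(self):
        rng = np.random.default_rng(7)
        pairs = make_embedded(rng, n=1000, d=16)
        rng.shuffle(pairs.y)  # destroy label/cosine dependence
        scorer = fit_baseline(pairs, None, TrainConfig())
        auc = roc_auc_score(pairs.y, scorer.score_batch(pairs.X1, pairs.X2))
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        pairs = make_embedded(rng, n=50)
        pairs.y[:] = 1.0
        with pytest.raises(ValidationError, match="single class"):
            fit_baseline(pairs, None, TrainConfig())


class TestFitFCN:
    @pytest.fixture(scope="class")
    def trained(self, separable_world):
        train, val, test = world_split_embedded(separable_world, seed=5)
        config = TrainConfig(seed=17, max_epochs=60, patience=8, hidden_dim=64)
        scorer = fit_fcn(train, val, config)
        return scorer, train, val, test, config

    def test_training_improves_on_first_epoch(self, trained):
        scorer, *_ = trained
        losses = scorer.history["train_loss"]
        assert min(losses) <= losses[0]

    def test_separable_world_validation_auc(self, trained):
        scorer, _, val, *_ = trained
        auc = roc_auc_score(val.y, scorer.score_batch(val.X1, val.X2))
        assert auc >= 0.99

    def test_early_stopping_epoch_bound(self, trained):
        scorer, *_, config = trained
        n_epochs = len(scorer.history["train_loss"])
        assert n_epochs <= scorer.best_epoch + config.patience + 1

    def test_deterministic_given_seed(self, separable_world):
        train, val, _ = world_split_embedded(separable_world, seed=5)
        config = TrainConfig(seed=23, max_epochs=12, patience=5, hidden_dim=16)
        a = fit_fcn(train, val, config)
        b = fit_fcn(train, val, config)
        np.testing.assert_array_equal(a.model.W, b.model.W)
        assert a.model.w == b.model.w and a.model.b == b.model.b


class TestContrastive:
    def test_uniform_softmax_nce_is_log_two(self):
        # one positive + one negative at identical cosine -> -log(1/2)
        cos = np.array([[0.4, 0.4], [0.4, 0.4]])
        assert nce_loss(cos, tau=0.07) == pytest.approx(np.log(2))

    def test_zero_fraction_augmentation_is_identity(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((5, 12))
        np.testing.assert_array_equal(permute_augment(X, 0.0, rng), X)

    def test_augmentation_permutes_within_vector(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((4, 20))
        out = permute_augment(X, 0.5, rng)
        assert not np.array_equal(out, X)
        np.testing.assert_allclose(np.sort(out, axis=1), np.sort(X, axis=1))

    def test_separable_world_auc(self, separable_world):
        train, val, test = world_split_embedded(separable_world, seed=5)
        config = TrainConfig(seed=17, max_epochs=40, patience=6, hidden_dim=64, loss="nce")
        scorer = fit_contrastive(train, val, config)
        auc = roc_auc_score(val.y, scorer.score_batch(val.X1, val.X2))
        assert auc >= 0.95

    def test_requires_nce_loss(self, separable_world):
        train, val, _ = world_split_embedded(separable_world, seed=5)
        with pytest.raises(ValidationError, match="nce"):
            fit_contrastive(train, val, TrainConfig(loss="bce"))


class TestConfigValidation:
    def test_patience_must_be_less_than_max_epochs(self):
        with pytest.raises(ValidationError):
            TrainConfig(max_epochs=5, patience=5)

    def test_temperature_positive(self):
        with pytest.raises(ValidationError):
            TrainConfig(temperature=0.0)


class TestSerialization:
    @pytest.mark.parametrize("kind", ["baseline", "fcn"])
    def test_round_trip_preserves_scores(self, kind, tmp_path):
        rng = np.random.default_rng(4)
        if kind == "baseline":
            model = BaselineLR(slope=1.7, intercept=-0.3, dimension=8)
        else:
            model = SiameseFCN(
                W=rng.standard_normal((6, 8)), c=rng.standard_normal(6),
                w=2.0, b=0.1,
            )
        scorer = TrainedScorer(
            model=model, config=TrainConfig(), history={"train_loss": [0.5]},
            provider_name="fixture", dimension=8, kind=kind,
        )
        path = tmp_path / "model.json"
        save_model(scorer, path)
        again = load_model(path)
        for _ in range(100):
            e1 = rng.standard_normal(8)
            e2 = rng.standard_normal(8)
            assert again.score_pair(e1, e2) == scorer.score_pair(e1, e2)

    def test_corrupted_file_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(ModelFormatError):
            load_model(path)

    def test_version_mismatch_rejected(self, tmp_path):
        path = tmp_path / "old.json"
        path.write_text('{"format": "metaharm-model-0"}')
        with pytest.raises(ModelFormatError, match="format"):
            load_model(path)

    def test_loaded_model_rejects_wrong_dimension(self, tmp_path):
        model = BaselineLR(slope=1.0, intercept=0.0, dimension=8)
        scorer = TrainedScorer(
            model=model, config=TrainConfig(), history={}, provider_name="f",
            dimension=8, kind="baseline",
        )
        path = tmp_path / "m.json"
        save_model(scorer, path)
        again = load_model(path)
        with pytest.raises(ValidationError, match="dimension"):
            again.score_pair(np.ones(4), np.ones(4))
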