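import numpy as np
import pytest

from eegfuse.model import ModelConfig
from eegfuse.training import (
    TrainConfig,
    compute_metrics,
    cross_validate,
    make_folds,
    train_fold,
)

TINY_MODEL = ModelConfig(res_blocks=((8, 1), (12, 1)), gat_hidden=4, fusion_hidden=16)


def _separable_features(n=120, seed=0):
    """Linearly separable synthetic channel features: class shifts a frontal
    subset of channels on two feature columns."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    rng.shuffle(y)
    feats = rng.standard_normal((n, 32, 6)).astype(np.float32)
    feats[y == 1, :6, 1] += 3.0  # variance-like column
    feats[y == 1, :6, 5] += 3.0  # entropy-like column
    return feats, y


class TestMakeFolds:
    def test_partition_disjoint_and_complete(self):
        y = np.arange(103) % 2
        folds = make_folds(y, k=10, seed=0)
        all_val = np.concatenate([va for _, va in folds])
        assert len(folds) == 10
        assert sorted(all_val.tolist()) == list(range(103))
        sizes = [len(va) for _, va in folds]
        assert max(sizes) - min(sizes) <= 1
        for tr, va in folds:
            assert np.intersect1d(tr, va).size == 0

    def test_full_scale_fold_sizes(self):
        # 12,800 pooled segments split 10 ways -> 1,280 validation samples each
        y = np.arange(12_800) % 2
        folds = make_folds(y, k=10, seed=0)
        assert all(len(va) == 1_280 for _, va in folds)

    def test_stratification(self):
        y = np.array([0] * 80 + [1] * 20)
        for _, va in make_folds(y, k=10, seed=1):
            assert np.asarray(y)[va].sum() == 2  # 20% positives in every fold

    def test_determinism(self):
        y = np.arange(50) % 2
        f1 = make_folds(y, k=5, seed=42)
        f2 = make_folds(y, k=5, seed=42)
        for (tr1, va1), (tr2, va2) in zip(f1, f2):
            np.testing.assert_array_equal(va1, va2)

    def test_grouping_keeps_groups_together(self):
        y = np.arange(60) % 2
        groups = np.repeat(np.arange(20), 3)
        y = np.repeat(np.arange(20) % 2, 3)
        folds = make_folds(y, k=5, seed=0, groups=groups)
        for tr, va in folds:
            assert set(groups[tr]).isdisjoint(set(groups[va]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            make_folds(np.zeros(20), k=5)


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1, 1])
        probs = np.column_stack([1.0 - y, y * 1.0])
        m = compute_metrics(y, probs)
        assert (m.accuracy, m.f1, m.auc) == (1.0, 1.0, 1.0)
        assert m.confusion == (2, 0, 0, 3)

    def test_inverted_predictions_have_zero_auc(self):
        y = np.array([0, 1, 0, 1])
        scores = 1.0 - y
        m = compute_metrics(y, scores)
        assert m.auc == 0.0

    def test_accuracy_matches_confusion_counts(self, rng):
        y = rng.integers(0, 2, 200)
        probs = rng.random((200, 2))
        probs /= probs.sum(axis=1, keepdims=True)
        m = compute_metrics(y, probs)
        tn, fp, fn, tp = m.confusion
        assert m.accuracy == pytest.approx((tp + tn) / (tp + tn + fp + fn))

    def test_trapezoid_auc_equals_concordance(self, rng):
        # AUC must equal the Mann-Whitney pairwise concordance (ties = 1/2)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # coarse grid to force ties
            m = compute_metrics(y, scores)
            pos, neg = scores[y == 1], scores[y == 0]
            conc = np.mean(
                [(1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg]
            )
            assert abs(m.auc - conc) < 1e-9

    def test_roc_endpoints_and_monotonicity(self, rng):
        y = rng.integers(0, 2, 50)
        m = compute_metrics(y, rng.random(50))
        roc = m.roc_points
        assert tuple(roc[0]) == (0.0, 0.0)
        assert tuple(roc[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc[:, 0]) >= 0)
        assert np.all(np.diff(roc[:, 1]) >= 0)

    def test_single_class_auc_nan_with_warning(self):
        with pytest.warns(UserWarning, match="single-class"):
            m = compute_metrics(np.ones(5), np.linspace(0, 1, 5))
        assert np.isnan(m.auc)


@pytest.fixture(scope="module")
def separable():
    return _separable_features()


class TestTrainFold:
    def test_learns_separable_features(self, separable):
        feats, y = separable
        tr, va = make_folds(y, k=4, seed=0)[0]
        cfg = TrainConfig(learning_rate=1e-3, epochs=30, batch_size=32, folds=4, seed=0)
        _, metrics, _ = train_fold(feats, y, tr, va, TINY_MODEL, cfg)
        assert metrics.accuracy >= 0.95

    def test_shuffled_labels_give_chance_level(self, separable):
        feats, y = separable
        folds = make_folds(y, k=4, seed=0)
        preds = []
        for i, (tr, va) in enumerate(folds):
            cfg = TrainConfig(
                learning_rate=1e-3, epochs=10, batch_size=32, folds=4, seed=0,
                shuffle_labels=True,
            )
            _, metrics, _ = train_fold(feats, y, tr, va, TINY_MODEL, cfg, fold=i)
            preds.append(metrics.accuracy)
        assert 0.3 <= float(np.mean(preds)) <= 0.7  # wide band at n = 120

    def test_bitwise_reproducibility(self, separable):
        feats, y = separable
        tr, va = make_folds(y, k=4, seed=1)[0]
        cfg = TrainConfig(learning_rate=1e-3, epochs=3, batch_size=32, folds=4, seed=9)
        m1, met1, _ = train_fold(feats, y, tr, va, TINY_MODEL, cfg)
        m2, met2, _ = train_fold(feats, y, tr, va, TINY_MODEL, cfg)
        for (p1, _), (p2, _) in zip(m1.params(), m2.params()):
            np.testing.assert_array_equal(p1, p2)
        assert met1.accuracy == met2.accuracy

    def test_validation_split_cannot_leak(self, separable):
        # replacing validation features/labels must not change fitted weights
        feats, y = separable
        tr, va = make_folds(y, k=4, seed=2)[0]
        cfg = TrainConfig(learning_rate=1e-3, epochs=3, batch_size=32, folds=4, seed=5)
        model_a, _, stats_a = train_fold(feats, y, tr, va, TINY_MODEL, cfg)
        corrupted = feats.copy()
        corrupted[va] = 1e6  # absurd validation values
        y_corrupt = y.copy()
        y_corrupt[va] = 1 - y_corrupt[va]
        model_b, _, stats_b = train_fold(corrupted, y_corrupt, tr, va, TINY_MODEL, cfg)
        np.testing.assert_array_equal(stats_a.mean, stats_b.mean)
        np.testing.assert_array_equal(stats_a.sd, stats_b.sd)
        for (p1, _), (p2, _) in zip(model_a.params(), model_b.params()):
            np.testing.assert_array_equal(p1, p2)


class TestCrossValidate:
    def test_summary_is_mean_of_folds(self, tiny_cohort):
        from eegfuse.dataset import assemble_dataset

        ds = assemble_dataset(tiny_cohort)
        cfg = TrainConfig(learning_rate=1e-3, epochs=2, batch_size=16, folds=3, seed=0)
        result = cross_validate(ds, TINY_MODEL, cfg)
        assert len(result.folds) == 3
        accs = [m.accuracy for m in result.folds]
        assert result.summary["accuracy_mean"] == pytest.approx(np.mean(accs))
        frame = result.to_frame()
        assert list(frame.columns) == ["fold", "accuracy", "f1", "auc"]

    def test_outputs_written(self, tiny_cohort, tmp_path):
        from eegfuse.dataset import assemble_dataset

        ds = assemble_dataset(tiny_cohort)
        cfg = TrainConfig(learning_rate=1e-3, epochs=1, batch_size=16, folds=2, seed=0)
        cross_validate(ds, TINY_MODEL, cfg, out_dir=tmp_path)
        assert (tmp_path / "metrics.csv").exists()
        assert (tmp_path / "summary.json").exists()
        assert (tmp_path / "roc_fold0.csv").exists()
        att = np.loadtxt(tmp_path / "mean_attention.csv", delimiter=",")
        assert att.shape == (32, 32)
        np.testing.assert_allclose(att.sum(axis=1), 1.0, atol=1e-4)
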