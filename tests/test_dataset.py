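import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegfuse.dataset import (
    SchemaError,
    SegmentDataset,
    apply_normalization,
    assemble_dataset,
    build_feature_image,
    build_feature_images,
    build_graph_sample,
    fit_normalization,
    label_from_rating,
    read_cohort,
    read_dataset,
    write_cohort,
    write_dataset,
)
from eegfuse.montage import build_adjacency, build_grid_mapping, get_montage


class TestLabelFromRating:
    @pytest.mark.parametrize(
        "rating,expected",
        [(7.2, 1), (5.0, 0), (0.0, 0), (9.0, 1), (5.0000001, 1), (4.999, 0)],
    )
    def test_threshold_strictly_greater_than_five(self, rating, expected):
        assert label_from_rating(rating, "arousal") == expected
        assert label_from_rating(rating, "valence") == expected

    @pytest.mark.parametrize("rating", [-0.1, 9.5, 100.0])
    def test_out_of_scale_rejected(self, rating):
        with pytest.raises(ValueError, match="0-9"):
            label_from_rating(rating)

    def test_unknown_dimension_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            label_from_rating(3.0, "dominance")

    @given(st.integers(min_value=0, max_value=2**31))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_uniform_ratings_high_fraction(self, seed):
        # P(rating > 5) = 4/9 for uniform ratings on [0, 9]
        ratings = np.random.default_rng(seed).uniform(0, 9, size=3000)
        frac = np.mean([label_from_rating(r) for r in ratings])
        assert abs(frac - 4 / 9) < 4 * np.sqrt((4 / 9) * (5 / 9) / 3000)


class TestFeatureImage:
    @pytest.fixture
    def mapping(self):
        return build_grid_mapping(get_montage())

    @pytest.fixture
    def channels(self):
        return get_montage().channels

    def test_all_ones_slices_sum_to_32(self, mapping, channels):
        img = build_feature_image(np.ones((32, 6)), mapping, channels)
        assert img.shape == (9, 9, 6)
        np.testing.assert_array_equal(img.sum(axis=(0, 1)), np.full(6, 32.0))

    def test_single_channel_placement(self, mapping, channels):
        feats = np.zeros((32, 6))
        feats[channels.index("Cz")] = 5.0
        img = build_feature_image(feats, mapping, channels)
        assert np.all(img[4, 4] == 5.0)
        img[4, 4] = 0
        assert np.all(img == 0)

    def test_nonzero_cell_count(self, mapping, channels, rng):
        feats = rng.uniform(1.0, 2.0, size=(32, 6))
        img = build_feature_image(feats, mapping, channels)
        assert np.all((img != 0).sum(axis=(0, 1)) == 32)

    def test_batch_matches_single(self, mapping, channels, rng):
        feats = rng.standard_normal((5, 32, 6))
        batch = build_feature_images(feats, mapping, channels)
        for i in range(5):
            np.testing.assert_array_equal(batch[i], build_feature_image(feats[i], mapping, channels))

    def test_unknown_channel_rejected(self, mapping):
        with pytest.raises(KeyError, match="Xz"):
            build_feature_image(np.ones((1, 6)), mapping, ["Xz"])


class TestGraphSample:
    def test_identity_packaging(self, rng):
        feats = rng.standard_normal((32, 6))
        gs = build_graph_sample(feats, build_adjacency(32))
        np.testing.assert_array_equal(gs.node_features, feats)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="adjacency"):
            build_graph_sample(rng.standard_normal((30, 6)), build_adjacency(32))


class TestNormalization:
    def test_self_normalization_is_standard(self, rng):
        feats = rng.standard_normal((100, 32, 6)) * 10 + 3
        stats = fit_normalization(feats)
        z = apply_normalization(feats, stats).reshape(-1, 6)
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-6)
        np.testing.assert_allclose(z.std(axis=0), 1, atol=1e-6)

    def test_constant_column_falls_back_to_unit_sd(self, rng):
        feats = rng.standard_normal((50, 4, 6))
        feats[..., 2] = 9.0
        stats = fit_normalization(feats)
        assert stats.sd[2] == 1.0
        z = apply_normalization(feats, stats)
        np.testing.assert_allclose(z[..., 2], 0.0)

    def test_unmapped_cells_stay_zero_after_normalization(self, rng):
        montage = get_montage()
        mapping = build_grid_mapping(montage)
        feats = rng.standard_normal((10, 32, 6))
        stats = fit_normalization(feats)
        imgs = build_feature_images(apply_normalization(feats, stats), mapping, montage.channels)
        mapped = np.zeros((9, 9), dtype=bool)
        for cell in mapping.entries.values():
            mapped[cell] = True
        assert np.all(imgs[:, ~mapped, :] == 0)

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_normalization(np.empty((0, 32, 6)))


class TestAssembly:
    def test_tiny_cohort_counts_and_determinism(self, tiny_cohort):
        ds = assemble_dataset(tiny_cohort)
        # 2 subjects x 6 trials x 2 windows of 6 s in 12 s of post-baseline signal
        assert len(ds) == 24
        assert ds.features.shape == (24, 32, 6)
        ds2 = assemble_dataset(tiny_cohort)
        np.testing.assert_array_equal(ds.features, ds2.features)

    def test_labels_match_latent_class(self, tiny_cohort):
        ds = assemble_dataset(tiny_cohort)
        latent = tiny_cohort.latent_class[
            ds.provenance[:, 0], ds.provenance[:, 1]
        ]
        np.testing.assert_array_equal(ds.labels_arousal, latent)
        np.testing.assert_array_equal(ds.labels_valence, latent)


class TestContainers:
    @pytest.mark.parametrize("ext", ["h5", "npz"])
    def test_cohort_round_trip(self, tmp_path, tiny_cohort, ext):
        path = tmp_path / f"cohort.{ext}"
        write_cohort(path, tiny_cohort)
        back = read_cohort(path)
        np.testing.assert_array_equal(back.signals, tiny_cohort.signals)
        np.testing.assert_array_equal(back.ratings, tiny_cohort.ratings)
        np.testing.assert_array_equal(back.latent_class, tiny_cohort.latent_class)
        assert back.fs == tiny_cohort.fs
        assert back.baseline_samples == tiny_cohort.baseline_samples

    @pytest.mark.parametrize("ext", ["h5", "npz"])
    def test_dataset_round_trip(self, tmp_path, rng, ext):
        ds = SegmentDataset(
            features=rng.standard_normal((8, 32, 6)).astype(np.float32),
            labels_arousal=rng.integers(0, 2, 8),
            labels_valence=rng.integers(0, 2, 8),
            provenance=np.array([(0, t, w) for t in range(4) for w in range(2)]),
        )
        path = tmp_path / f"ds.{ext}"
        write_dataset(path, ds)
        back = read_dataset(path)
        np.testing.assert_array_equal(back.features, ds.features)
        np.testing.assert_array_equal(back.labels_arousal, ds.labels_arousal)
        np.testing.assert_array_equal(back.provenance, ds.provenance)

    def test_missing_array_schema_error(self, tmp_path, tiny_cohort):
        import h5py

        path = tmp_path / "broken.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("signals", data=tiny_cohort.signals[:1])
        with pytest.raises(SchemaError, match="ratings"):
            read_cohort(path)

    def test_duplicate_provenance_rejected(self, rng):
        with pytest.raises(ValueError, match="provenance"):
            SegmentDataset(
                features=rng.standard_normal((2, 32, 6)),
                labels_arousal=np.array([0, 1]),
                labels_valence=np.array([0, 1]),
                provenance=np.zeros((2, 3), dtype=int),
            )
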