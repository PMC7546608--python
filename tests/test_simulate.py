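import numpy as np
import pytest
from scipy import stats

from facersa import (
    GeometrySpec,
    RdmEstimatorConfig,
    SimulationConfig,
    ValidationError,
    abs_diff_rdm,
    aggregate_responses,
    generate_behavior,
    generate_dataset,
    generate_epochs,
    generate_faces,
    rdm_to_coordinates,
    split_half_pca_rdm,
    spearman_fit,
)
from facersa.datatypes import RDM
from facersa.neural import extract_bin_patterns, make_time_bins


def small_config(**overrides):
    kwargs = dict(n_participants=2, n_faces=8, n_channels=4, seed=0)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


class TestGenerateFaces:
    def test_default_count(self, rng):
        faces = generate_faces(SimulationConfig(), rng)
        assert len(faces) == 100

    def test_deterministic_given_seed(self):
        f1 = generate_faces(small_config(), np.random.default_rng(5))
        f2 = generate_faces(small_config(), np.random.default_rng(5))
        assert f1.table.equals(f2.table)

    def test_db_rating_clipped_over_many_draws(self, rng):
        faces = generate_faces(SimulationConfig(n_faces=10_000), rng)
        r = faces.attribute("db_rating")
        assert r.min() >= 1.0 and r.max() <= 7.0


class TestGenerateBehavior:
    def test_default_session_has_700_trials(self, rng):
        config = SimulationConfig()
        faces = generate_faces(config, rng)
        behavior = generate_behavior(faces, config, rng)
        assert len(behavior) == 700
        # each block shows every face exactly once
        counts = behavior.table.groupby("face_id").size()
        assert (counts == 7).all()

    def test_pure_shared_taste_is_monotone_in_db_rating(self, rng):
        config = small_config(
            n_faces=30, shared_taste_weight=1.0, rating_noise_sd=0.0
        )
        faces = generate_faces(config, rng)
        behavior = generate_behavior(faces, config, rng)
        resp = aggregate_responses(behavior).table.set_index("face_id")
        resp = resp.loc[faces.face_ids]
        mean_rating = resp["mean_rating"].to_numpy()
        db = faces.attribute("db_rating")
        # monotone non-decreasing in db_rating (rounding to the 1–7 scale
        # introduces ties, so pairwise order is the exact statement)
        order = np.argsort(db)
        assert (np.diff(mean_rating[order]) >= 0).all()
        rho = stats.spearmanr(mean_rating, db).statistic
        assert rho > 0.9

    def test_zero_shared_taste_decorrelates_from_db_rating(self):
        config = small_config(n_faces=40, shared_taste_weight=0.0)
        faces = generate_faces(config, np.random.default_rng(0))
        corrs = []
        for seed in range(50):
            behavior = generate_behavior(
                faces, config, np.random.default_rng(seed)
            )
            resp = aggregate_responses(behavior).table.set_index("face_id")
            resp = resp.loc[faces.face_ids]
            corrs.append(
                np.corrcoef(
                    resp["mean_rating"], faces.attribute("db_rating")
                )[0, 1]
            )
        assert abs(np.mean(corrs)) < 0.05

    def test_default_taste_weight_gives_moderate_rdm_correlation(self):
        """The default λ makes each participant's rating RDM only
        moderately correlated (r ≈ 0.35) with the database-rating RDM."""
        from facersa import build_predictor_suite

        config = SimulationConfig(n_faces=100)
        faces = generate_faces(config, np.random.default_rng(1))
        i, j = np.tril_indices(100, -1)
        corrs = []
        for seed in range(20):
            behavior = generate_behavior(
                faces, config, np.random.default_rng(seed)
            )
            suite = build_predictor_suite(faces, aggregate_responses(behavior))
            corrs.append(
                np.corrcoef(
                    suite["rating"].values[i, j],
                    suite["db_rating"].values[i, j],
                )[0, 1]
            )
        assert 0.2 < np.mean(corrs) < 0.5


class TestRdmToCoordinates:
    def test_recovers_planar_points(self):
        points = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 2.0], [-1.0, 1.0]])
        d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
        np.fill_diagonal(d, np.nan)
        rdm = RDM(list("abcd"), d)
        coords = rdm_to_coordinates(rdm, 2)
        recovered = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.fill_diagonal(d, 0.0)
        np.testing.assert_allclose(recovered, d, atol=1e-8)

    def test_zero_rdm_gives_identical_points(self):
        values = np.zeros((3, 3))
        np.fill_diagonal(values, np.nan)
        coords = rdm_to_coordinates(RDM(list("abc"), values), 1)
        np.testing.assert_allclose(coords, 0.0, atol=1e-12)

    def test_line_rdm_recovers_values_affinely(self):
        rdm = abs_diff_rdm(np.array([1.0, 4.0, 7.0]), list("abc"))
        coords = rdm_to_coordinates(rdm, 1)[:, 0]
        # pairwise distances on the line reproduce the absolute differences
        recovered = np.abs(coords[:, None] - coords[None, :])
        expected = np.nan_to_num(rdm.values)
        np.testing.assert_allclose(recovered, expected, atol=1e-8)

    def test_matches_reference_pcoa(self, rng):
        """Cross-check the embedding against scikit-bio's PCoA."""
        skbio = pytest.importorskip("skbio")
        points = rng.normal(size=(6, 3))
        d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
        np.fill_diagonal(d, np.nan)
        coords = rdm_to_coordinates(RDM(list("abcdef"), d), 3)
        np.fill_diagonal(d, 0.0)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d), number_of_dimensions=3
        ).samples.to_numpy()
        np.testing.assert_allclose(
            np.abs(coords), np.abs(ref), atol=1e-8
        )

    def test_q_bounds(self):
        rdm = abs_diff_rdm(np.array([1.0, 2.0, 3.0]), list("abc"))
        with pytest.raises(ValidationError):
            rdm_to_coordinates(rdm, 3)


class TestGenerateEpochs:
    def test_default_epoch_shape(self, rng):
        config = SimulationConfig(n_faces=5, n_blocks=2)
        faces = generate_faces(config, rng)
        behavior = generate_behavior(faces, config, rng)
        epochs = generate_epochs(faces, behavior, [], config, rng)
        assert epochs.data.shape == (10, 63, 425)
        assert epochs.fs == 250.0 and epochs.t0_ms == -250.0

    def test_noiseless_geometry_recovered_at_envelope_peak(self):
        """With zero sensor noise the split-half RDM at the envelope peak
        reproduces the injected geometry (Spearman > 0.9)."""
        config = small_config(
            n_faces=12, n_channels=16, n_blocks=4, noise_sd=0.0
        )
        rng = np.random.default_rng(11)
        faces = generate_faces(config, rng)
        behavior = generate_behavior(faces, config, rng)
        source = abs_diff_rdm(faces.attribute("db_rating"), faces.face_ids)
        spec = GeometrySpec(
            "g", source, onset_ms=100.0, peak_ms=400.0, offset_ms=800.0,
            amplitude=1.0, latent_dim=5,
        )
        epochs = generate_epochs(faces, behavior, [spec], config, rng)
        est = RdmEstimatorConfig(n_repetitions=2)
        grid = make_time_bins(est, config.fs)
        peak_bin = int(np.argmin(np.abs(grid.starts_ms - 400.0)))
        patterns, labels = extract_bin_patterns(epochs, grid, peak_bin)
        neural = split_half_pca_rdm(patterns, labels, est, np.random.default_rng(3))
        rho, _ = spearman_fit(neural, source)
        assert rho > 0.9

    def test_baseline_bins_carry_no_signal(self):
        config = small_config(n_faces=6, n_blocks=2, noise_sd=0.0)
        rng = np.random.default_rng(2)
        faces = generate_faces(config, rng)
        behavior = generate_behavior(faces, config, rng)
        spec = GeometrySpec("g", "db_rating", onset_ms=150.0, peak_ms=400.0,
                            offset_ms=900.0)
        epochs = generate_epochs(faces, behavior, [spec], config, rng)
        pre = epochs.data[:, :, epochs.times_ms < 100.0]
        assert np.abs(pre).max() == 0.0


class TestGenerateDataset:
    def test_default_has_23_participants(self):
        dataset = generate_dataset(SimulationConfig())
        assert len(dataset) == 23

    def test_same_seed_identical_bundles(self):
        config = small_config(n_blocks=2)
        d1 = generate_dataset(config)
        d2 = generate_dataset(config)
        assert d1.faces.table.equals(d2.faces.table)
        e1, b1 = d1.participant(1)
        e2, b2 = d2.participant(1)
        np.testing.assert_array_equal(e1.data, e2.data)
        assert b1.table.equals(b2.table)

    def test_repeated_materialisation_is_stable(self):
        dataset = generate_dataset(small_config(n_blocks=2))
        e1, _ = dataset.participant(0)
        e2, _ = dataset.participant(0)
        np.testing.assert_array_equal(e1.data, e2.data)

    def test_ground_truth_lists_geometries(self):
        spec = GeometrySpec("taste", "db_rating")
        dataset = generate_dataset(small_config(geometries=[spec]))
        names = [g["name"] for g in dataset.ground_truth["geometries"]]
        assert names == ["taste"]
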