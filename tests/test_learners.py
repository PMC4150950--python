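import numpy as np
import pytest

from peplife import (
    DecisionTableRegressor,
    EncoderSpec,
    FeatureMatrix,
    HalfLifeDataset,
    LearnerSpec,
    Peptide,
    cross_validate,
    encode_dataset,
    fit,
    fit_matrix,
    load_model,
    save_model,
)


def _dataset(seqs, y):
    return HalfLifeDataset([Peptide(s) for s in seqs], y)


@pytest.fixture
def small_ds(rng):
    from peplife import AMINO_ACIDS

    seqs = ["".join(rng.choice(list(AMINO_ACIDS), size=10)) for _ in range(20)]
    y = rng.uniform(0.1, 5.0, size=20)
    return _dataset(seqs, y)


class TestKnn:
    def test_k1_memorizes_training_points(self, small_ds):
        model = fit(LearnerSpec(technique="knn", k=1), small_ds, EncoderSpec("dpc"))
        np.testing.assert_allclose(
            model.predict(small_ds.peptides), small_ds.half_lives
        )

    def test_k_geq_n_predicts_training_mean(self, small_ds):
        model = fit(LearnerSpec(technique="knn", k=100), small_ds, EncoderSpec("aac"))
        preds = model.predict([Peptide("ACDEFGHIKL")])
        assert preds[0] == pytest.approx(small_ds.half_lives.mean())

    def test_predictions_bounded_by_training_range(self, small_ds, rng):
        from peplife import AMINO_ACIDS

        model = fit(LearnerSpec(technique="knn", k=3), small_ds, EncoderSpec("aac"))
        queries = [Peptide("".join(rng.choice(list(AMINO_ACIDS), size=10)))
                   for _ in range(30)]
        preds = model.predict(queries)
        assert np.all(preds >= small_ds.half_lives.min() - 1e-12)
        assert np.all(preds <= small_ds.half_lives.max() + 1e-12)

    def test_inverse_distance_weighting_accepted(self, small_ds):
        model = fit(
            LearnerSpec(technique="knn", k=3, weighting="inverse-distance"),
            small_ds,
            EncoderSpec("aac"),
        )
        assert model.predict(small_ds.peptides).shape == (20,)


class TestSvr:
    def test_linear_kernel_recovers_linear_target(self, rng):
        """y exactly linear in the features; a hard-margin linear SVR must
        reproduce the training targets to ~0.1% relative error."""
        X = rng.uniform(0, 1, size=(60, 5))
        w = np.array([2.0, -1.0, 0.5, 3.0, 1.5])
        y = 5.0 + X @ w
        fm = FeatureMatrix([f"f{i}" for i in range(5)], X)
        model = fit_matrix(
            LearnerSpec(technique="svr", kernel="linear", C=1e4, epsilon=1e-4),
            fm,
            y,
        )
        preds = model.predict_matrix(X)
        np.testing.assert_allclose(preds, y, rtol=1e-3)

    def test_composition_model_order_free(self, small_ds):
        model = fit(LearnerSpec(technique="svr"), small_ds, EncoderSpec("aac"))
        p = Peptide("ACDEFGHIKL")
        q = Peptide("LKIHGFEDCA")
        a, b = model.predict([p, q])
        assert a == pytest.approx(b)

    def test_deterministic_predictions(self, small_ds):
        spec = LearnerSpec(technique="svr", kernel="rbf", C=10.0, random_seed=7)
        m1 = fit(spec, small_ds, EncoderSpec("dpc"))
        m2 = fit(spec, small_ds, EncoderSpec("dpc"))
        queries = small_ds.peptides[:5]
        np.testing.assert_array_equal(m1.predict(queries), m2.predict(queries))


class TestDecisionTable:
    def test_two_separated_clusters_predict_cluster_means(self):
        """Six points, one informative feature with two well-separated
        levels: with one bin per cluster, each cluster's query must get
        its own cluster mean."""
        X = np.array([[0.01], [0.1], [0.05], [1.0], [0.9], [0.95]])
        y = np.array([1.0, 1.2, 1.1, 5.0, 5.2, 5.1])
        table = DecisionTableRegressor(n_bins=2).fit(X, y)
        low = table.predict(np.array([[0.02]]))[0]
        high = table.predict(np.array([[0.93]]))[0]
        assert low == pytest.approx(np.mean([1.0, 1.2, 1.1]))
        assert high == pytest.approx(np.mean([5.0, 5.2, 5.1]))

    def test_identical_rows_predict_global_mean(self):
        X = np.ones((5, 2))
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        table = DecisionTableRegressor().fit(X, y)
        assert table.predict(np.ones((1, 2)))[0] == pytest.approx(3.0)

    def test_empty_subset_predicts_global_mean(self, small_ds):
        model = fit(
            LearnerSpec(technique="dtable"),
            small_ds,
            EncoderSpec("aac"),
            feature_subset=[],
        )
        preds = model.predict([Peptide("ACDEFGHIKL"), Peptide("KKKKKKKKKK")])
        np.testing.assert_allclose(preds, small_ds.half_lives.mean())

    def test_unmatched_cell_falls_back_to_global_mean(self):
        """A query with a subset pattern never seen in training (here: a
        peptide without G or D when the table is keyed on the GD dipeptide)
        gets the training-mean fallback."""
        seqs = ["GDGDGDGDGD", "GDGDAAAAAA", "AAAAAAAAGD", "GDAAGDAAGD"]
        y = np.array([4.0, 2.0, 2.0, 3.0])
        ds = _dataset(seqs, y)
        model = fit(LearnerSpec(technique="dtable"), ds, EncoderSpec("dpc"),
                    feature_subset=["GD"])
        pred = model.predict([Peptide("KKKKKKKKKK")])[0]
        # GD=0 never occurs in training, so the cell is empty
        assert pred == pytest.approx(y.mean())


class TestScaleEquivariance:
    """Multiplying every half-life by c scales predictions by exactly c and
    leaves cross-validated Pearson R unchanged (the ×10/×1000 robustness
    experiment)."""

    @pytest.mark.parametrize("factor", [10.0, 1000.0])
    @pytest.mark.parametrize(
        "spec,subset",
        [
            (LearnerSpec(technique="knn", k=3), None),
            (LearnerSpec(technique="dtable"), ["EK", "EL", "GD", "GF"]),
        ],
    )
    def test_instance_learners_exact(self, hl10_like, spec, subset, factor):
        ds, _ = hl10_like
        base = cross_validate(ds, EncoderSpec("dpc"), spec, seed=3, feature_subset=subset)
        scaled = cross_validate(
            ds.scaled(factor), EncoderSpec("dpc"), spec, seed=3, feature_subset=subset
        )
        assert scaled.r == pytest.approx(base.r, abs=1e-6)
        assert scaled.mae == pytest.approx(base.mae * factor, rel=1e-12)
        np.testing.assert_allclose(scaled.predicted, base.predicted * factor, rtol=1e-12)

    @pytest.mark.parametrize("factor", [10.0, 1000.0])
    def test_svr_after_rescaling_c_and_epsilon(self, hl10_like, factor):
        ds, _ = hl10_like
        base_spec = LearnerSpec(technique="svr", kernel="rbf", C=10.0, epsilon=0.01,
                                gamma=1.0, tol=1e-8)
        scaled_spec = LearnerSpec(technique="svr", kernel="rbf", C=10.0 * factor,
                                  epsilon=0.01 * factor, gamma=1.0, tol=1e-8 * factor)
        base = cross_validate(ds, EncoderSpec("aac"), base_spec, seed=3)
        scaled = cross_validate(ds.scaled(factor), EncoderSpec("aac"), scaled_spec, seed=3)
        assert scaled.r == pytest.approx(base.r, abs=1e-6)


class TestModelContract:
    def test_requires_two_rows(self):
        ds = _dataset(["ACDEF"], [1.0])
        with pytest.raises(ValueError, match="insufficient training data"):
            fit(LearnerSpec(technique="knn"), ds, EncoderSpec("aac"))

    def test_constant_target_predicts_constant(self, rng):
        from peplife import AMINO_ACIDS

        seqs = ["".join(rng.choice(list(AMINO_ACIDS), size=8)) for _ in range(6)]
        ds = _dataset(seqs, np.full(6, 2.5))
        model = fit(LearnerSpec(technique="knn", k=6), ds, EncoderSpec("aac"))
        assert model.predict([Peptide("AAAAAAAA")])[0] == pytest.approx(2.5)

    def test_binary_model_rejects_wrong_length(self, small_ds):
        model = fit(LearnerSpec(technique="knn", k=1), small_ds, EncoderSpec("binary"))
        with pytest.raises(ValueError, match="length 10"):
            model.predict([Peptide("ACDEF")])

    def test_serialization_roundtrip(self, small_ds, tmp_path):
        model = fit(LearnerSpec(technique="svr"), small_ds, EncoderSpec("dpc"),
                    feature_subset=["EK", "GD"])
        path = tmp_path / "model.joblib"
        save_model(model, path)
        back = load_model(path)
        queries = small_ds.peptides[:4]
        np.testing.assert_array_equal(back.predict(queries), model.predict(queries))
        assert back.feature_subset == ["EK", "GD"]

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            LearnerSpec(technique="svr", C=-1.0)
        with pytest.raises(ValueError):
            LearnerSpec(technique="knn", k=0)
        with pytest.raises(ValueError):
            LearnerSpec(technique="bogus")
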