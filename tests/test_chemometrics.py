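"""Water-band selection, MSC, PCA, splitting, PLS-DA and its metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lichenmonitor import chemometrics as cm
from lichenmonitor import synthetic
from lichenmonitor.datamodel import SpectraMatrix, ValidationError


def _separable_data(n=40, p=30, seed=0, noise=0.0):
    """Two classes offset along a single spectral direction."""
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=p)
    direction /= np.linalg.norm(direction)
    labels = np.array(["lo"] * (n // 2) + ["hi"] * (n // 2))
    shift = np.where(labels == "hi", 1.0, -1.0)
    X = np.outer(shift, direction) + noise * rng.normal(size=(n, p))
    return X - X.mean(axis=0), labels


class TestWaterBand:
    def test_full_grid_retains_301(self, small_spectra):
        band = cm.select_water_band(small_spectra)
        assert band.n_wavelengths == 301
        assert band.wavelengths_nm[0] == 1300 and band.wavelengths_nm[-1] == 1600

    def test_idempotent(self, small_spectra):
        band = cm.select_water_band(small_spectra)
        again = cm.select_water_band(band)
        assert np.array_equal(band.values, again.values)

    def test_insufficient_grid_rejected(self):
        wl = np.arange(1400, 1501)
        sm = SpectraMatrix(["a", "b"], wl, np.ones((2, wl.size)))
        with pytest.raises(ValidationError):
            cm.select_water_band(sm)


class TestMSC:
    def test_reference_is_fixed_point(self, rng):
        ref = rng.uniform(0.2, 0.8, size=50)
        corrected, _ = cm.msc(np.vstack([ref, ref + 0.1]), reference=ref)
        assert np.allclose(corrected[0], ref, atol=1e-12)

    def test_exact_affine_inversion(self, rng):
        ref = rng.uniform(0.2, 0.8, size=50)
        x = 2.0 * ref + 3.0
        corrected, _ = cm.msc(x[None, :], reference=ref)
        assert np.allclose(corrected[0], ref, atol=1e-10)

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.floats(-5, 5),
        b=st.floats(0.05, 10),
        seed=st.integers(0, 10_000),
    )
    def test_affine_invariance_property(self, a, b, seed):
        rng = np.random.default_rng(seed)
        ref = rng.uniform(0.2, 0.8, size=40)
        x = rng.uniform(0.1, 0.9, size=40)
        c1, _ = cm.msc(x[None, :], reference=ref)
        c2, _ = cm.msc((b * x + a)[None, :], reference=ref)
        assert np.allclose(c1, c2, atol=1e-10)

    def test_corrects_simulated_scatter(self):
        # post-MSC, refitting the affine model against the reference gives
        # a = 0, b = 1 to numerical precision
        sm = synthetic.generate_spectra(
            synthetic.SpectraSimConfig(
                n_samples=40, scatter_sd=0.3, offset_sd=0.1, noise_sd=0.0, seed=4
            )
        )
        corrected, ref = cm.msc(sm.values)
        ref_c = ref - ref.mean()
        for row in corrected:
            b = (row - row.mean()) @ ref_c / (ref_c @ ref_c)
            a = row.mean() - b * ref.mean()
            assert abs(b - 1.0) < 1e-8 and abs(a) < 1e-8

    def test_near_zero_slope_identified(self):
        ref = np.linspace(0.2, 0.8, 30)
        flat = np.full((1, 30), 0.5)
        with pytest.raises(ValidationError, match="sample"):
            cm.msc(flat, reference=ref)


class TestMeanCenter:
    def test_training_columns_zero(self, rng):
        X = rng.normal(size=(15, 8))
        centered, means = cm.mean_center(X)
        assert np.allclose(centered.mean(axis=0), 0.0, atol=1e-10)

    def test_test_data_uses_training_means(self, rng):
        X = rng.normal(size=(15, 8))
        _, means = cm.mean_center(X)
        Xt = rng.normal(size=(4, 8))
        centered, _ = cm.mean_center(Xt, means)
        assert np.allclose(centered, Xt - means, atol=1e-12)


class TestPCA:
    def test_rank_one_explains_all(self, rng):
        X = np.outer(rng.normal(size=10), rng.normal(size=6))
        res = cm.pca(X, k=2)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-10)

    def test_scores_orthogonal_loadings_orthonormal(self, rng):
        X = rng.normal(size=(12, 7))
        X -= X.mean(axis=0)
        res = cm.pca(X, k=4)
        gram = res.scores.T @ res.scores
        assert np.allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(4), atol=1e-8)

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(10, 8))
        X -= X.mean(axis=0)
        res = cm.pca(X, k=5)
        evals, evecs = np.linalg.eigh(X.T @ X)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        assert np.allclose(
            res.explained_variance_fraction, evals[:5] / evals.sum(), atol=1e-8
        )
        for j in range(5):
            v = evecs[:, j]
            assert min(
                np.abs(res.loadings[:, j] - v).max(),
                np.abs(res.loadings[:, j] + v).max(),
            ) < 1e-8

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValidationError):
            cm.pca(rng.normal(size=(5, 3)), k=5)


class TestSplit:
    def test_sizes_disjoint_exhaustive(self):
        plan = cm.make_split(195, 58, seed=0)
        assert plan.test_indices.size == 58 and plan.train_indices.size == 137
        assert not set(plan.test_indices) & set(plan.train_indices)
        assert set(plan.test_indices) | set(plan.train_indices) == set(range(195))

    def test_deterministic_under_seed(self):
        p1 = cm.make_split(100, 30, seed=5)
        p2 = cm.make_split(100, 30, seed=5)
        assert np.array_equal(p1.test_indices, p2.test_indices)

    def test_membership_frequency_hypergeometric(self):
        # over many seeds each sample is a test member with rate 58/195
        n, n_test, n_seeds = 195, 58, 2000
        counts = np.zeros(n)
        for s in range(n_seeds):
            counts[cm.make_split(n, n_test, seed=s).test_indices] += 1
        rate = counts / n_seeds
        p = n_test / n
        se = np.sqrt(p * (1 - p) / n_seeds)
        assert np.all(np.abs(rate - p) < 4 * se)

    def test_invalid_test_size_rejected(self):
        with pytest.raises(ValidationError):
            cm.make_split(10, 10, seed=0)

    def test_stratified_split_preserves_proportions(self):
        labels = np.array(["a"] * 80 + ["b"] * 20)
        plan = cm.make_split(100, 30, seed=1, stratify_by=labels)
        test_labels = labels[plan.test_indices]
        assert np.sum(test_labels == "a") == 24 and np.sum(test_labels == "b") == 6


class TestPLSDA:
    def test_one_lv_separates_noiseless_classes(self):
        X, y = _separable_data()
        model = cm.plsda_fit(X, y, n_latent=1)
        pred, _ = cm.plsda_predict(model, X)
        assert np.array_equal(pred, y)

    def test_duplicated_columns_do_not_change_scores(self):
        X, y = _separable_data(noise=0.3, seed=2)
        m1 = cm.plsda_fit(X, y, 2)
        m2 = cm.plsda_fit(np.hstack([X, X]), y, 2)
        assert np.allclose(m1.fitted_scores, m2.fitted_scores, atol=1e-8)

    def test_coefficient_form_equals_score_form(self, rng):
        X, y = _separable_data(noise=0.5, seed=3)
        a = 3
        model = cm.plsda_fit(X, y, a)
        # score-form reconstruction: accumulate t_k c_k' over components
        classes = model.class_labels
        Y = np.array([[1.0 if yi == c else 0.0 for c in classes] for yi in y])
        Xc = X - model.x_mean
        T, W, P, C = cm._nipals(Xc, Y - Y.mean(axis=0), a)
        yhat_scores = T @ C.T + Y.mean(axis=0)
        assert np.allclose(model.fitted_scores, yhat_scores, atol=1e-8)

    def test_x_scores_orthogonal(self):
        X, y = _separable_data(noise=0.5, seed=4)
        model = cm.plsda_fit(X, y, 4)
        classes = model.class_labels
        Y = np.array([[1.0 if yi == c else 0.0 for c in classes] for yi in y])
        T, _, _, _ = cm._nipals(X - model.x_mean, Y - Y.mean(axis=0), 4)
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_full_rank_limit_equals_least_squares(self, rng):
        # with all feasible components, PLS fitted values reach the OLS fit
        n, p = 20, 5
        X = rng.normal(size=(n, p))
        y = np.array(["a"] * 10 + ["b"] * 10)
        model = cm.plsda_fit(X, y, n_latent=p)
        Y = np.array([[1.0 if yi == c else 0.0 for c in model.class_labels] for yi in y])
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        assert np.allclose(model.fitted_scores, Xc @ beta + Y.mean(axis=0), atol=1e-8)

    def test_agrees_with_sklearn_pls(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X, y = _separable_data(n=30, p=12, noise=0.4, seed=6)
        model = cm.plsda_fit(X, y, 3)
        Y = np.array([[1.0 if yi == c else 0.0 for c in model.class_labels] for yi in y])
        ref = PLSRegression(n_components=3, scale=False).fit(X, Y)
        assert np.allclose(model.fitted_scores, ref.predict(X), atol=1e-6)

    def test_centroid_classified_to_its_class(self):
        X, y = _separable_data()
        model = cm.plsda_fit(X, y, 1)
        centroid = X[y == "hi"].mean(axis=0)
        pred, _ = cm.plsda_predict(model, centroid[None, :])
        assert pred[0] == "hi"

    def test_tie_breaks_to_first_label(self):
        model = cm.plsda_fit(*_separable_data(), n_latent=1)
        # a zero centred spectrum scores exactly y_mean for each class; with
        # balanced classes that is a tie -> lexicographically first label
        pred, scores = cm.plsda_predict(model, model.x_mean[None, :])
        assert scores[0, 0] == pytest.approx(scores[0, 1])
        assert pred[0] == model.class_labels[0] == "hi"

    def test_single_class_rejected(self):
        X, _ = _separable_data()
        with pytest.raises(ValidationError):
            cm.plsda_fit(X, np.array(["a"] * X.shape[0]), 1)

    def test_grid_mismatch_rejected(self):
        X, y = _separable_data()
        model = cm.plsda_fit(X, y, 1)
        with pytest.raises(ValidationError):
            cm.plsda_predict(model, X[:, :10])


class TestChooseLV:
    def test_separable_data_chooses_one(self):
        X, y = _separable_data(n=60, noise=0.05, seed=8)
        X += 0.5  # keep MSC slopes well-defined
        n_latent, curve = cm.choose_lv(X, y, max_lv=5, k_folds=5, seed=0)
        assert n_latent == 1
        assert curve[0] == pytest.approx(0.0, abs=0.05)

    def test_tie_takes_smallest(self):
        X, y = _separable_data(n=40, noise=0.0, seed=9)
        X += 0.5
        n_latent, curve = cm.choose_lv(X, y, max_lv=4, k_folds=4, seed=0)
        assert curve[n_latent - 1] == curve.min()
        assert np.all(curve[: n_latent - 1] > curve[n_latent - 1])

    def test_fold_losing_class_rejected(self):
        X, y = _separable_data(n=20, noise=0.3, seed=10)
        y = y.copy()
        y[[0, 5]] = "rare"  # both land in the same venetian fold
        with pytest.raises(ValidationError, match="stratif"):
            cm.choose_lv(X + 0.5, y, max_lv=3, k_folds=5, seed=0, scheme="venetian")


class TestClassMetrics:
    def test_perfect_prediction(self):
        m = cm.class_metrics(["a", "a", "b"], ["a", "a", "b"], "a")
        assert (m.sensitivity, m.specificity, m.error) == (1.0, 1.0, 0.0)

    def test_confusion_counts(self):
        true = ["a"] * 10 + ["b"] * 10
        pred = ["a"] * 9 + ["b"] + ["b"] * 8 + ["a"] * 2
        m = cm.class_metrics(true, pred, "a")
        assert m.sensitivity == pytest.approx(0.9)
        assert m.specificity == pytest.approx(0.8)
        assert m.error == pytest.approx(0.15)

    def test_balanced_error_convention_matches_published_rounding(self):
        # Sn = 0.722, Sp = 0.903 -> Er = 0.1875, truncating to 0.187
        er = 1 - (0.722 + 0.903) / 2
        assert er == pytest.approx(0.1875)
        assert np.trunc(er * 1000) / 1000 == 0.187

    def test_absent_class_rejected(self):
        with pytest.raises(ValidationError):
            cm.class_metrics(["a", "a"], ["a", "b"], "b")


class TestExperiment:
    def test_structure_and_recovery(self):
        spectra = synthetic.generate_spectra(synthetic.SpectraSimConfig(seed=7))
        res = cm.run_plsda_experiment(
            spectra, "growth_form", cm.PLSDAExperimentConfig(seed=7)
        )
        # one row per class per phase, Table-1-like shape
        assert len(res.metrics) == 2 * 2
        assert set(res.metrics["phase"]) == {"cv", "prediction"}
        pred = res.metrics.query("phase == 'prediction'")
        assert (pred["error"] <= 0.1).all()

    def test_deterministic_under_seed(self):
        spectra = synthetic.generate_spectra(
            synthetic.SpectraSimConfig(n_samples=80, seed=11)
        )
        cfg = cm.PLSDAExperimentConfig(n_test=24, max_lv=6, k_folds=5, seed=11)
        r1 = cm.run_plsda_experiment(spectra, "phorophyte", cfg)
        r2 = cm.run_plsda_experiment(spectra, "phorophyte", cfg)
        assert r1.metrics.equals(r2.metrics)
        assert r1.n_latent == r2.n_latent

    def test_unknown_label_field_rejected(self, small_spectra):
        with pytest.raises(ValidationError):
            cm.run_plsda_experiment(small_spectra, "petal_width")
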