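"""The four predictors: closed-form limits, reductions, and oracle checks."""

import numpy as np
import pandas as pd
import pytest

import _oracles as oracle
from conftest import make_random_dataset
from coexpredict import (
    CollinearityError,
    DenseSubnetPredictor,
    ExpressionDataset,
    KNNPredictor,
    MutualKNNPredictor,
    TargetSet,
    TimepointRegressionPredictor,
    combined_distance_matrix,
    predict_knn,
)
from coexpredict.simulate import SimConfig, generate


def _noise_free_modular(seed=0, k_safe=5):
    cfg = SimConfig(
        n_genes=120,
        n_targets=6,
        module_size_range=(14, 18),
        background_fraction=0.1,
        noise_sd=0.0,
        loading_sd=0.0,
        gene_offset_sd=0.0,
        seed=seed,
    )
    return generate(cfg)


class TestKNN:
    def test_duplicate_neighbor_recovered_exactly_with_k1(self):
        ds, targets, truth = make_random_dataset(seed=0, n_genes=20, n_targets=1)
        tgt = targets.genes[0]
        # make a non-target an exact duplicate of the target in every strain
        ds._values[5] = ds._values[0]
        truth.loc[tgt] = ds._values[5, ds.strain_index(ds.prediction_strain)].mean(axis=1)
        pred = predict_knn(ds, targets, k=1)
        np.testing.assert_allclose(pred.values[0], truth.loc[tgt].to_numpy(), atol=1e-12)

    def test_two_neighbors_average(self):
        vals = np.zeros((4, 2, 3, 1))
        vals[1, 1] = 1.0  # neighbor values in prediction strain
        vals[2, 1] = 3.0
        vals[3] = 50.0  # far away in complete strain, excluded by k=2
        ds = ExpressionDataset(["t", "a", "b", "c"], ["s0", "s1"], "s1", [0, 10, 20], vals)
        targets = TargetSet(("t",), "s1")
        pred = predict_knn(ds.mask_targets(targets), targets, k=2)
        np.testing.assert_allclose(pred.values[0], [2.0, 2.0, 2.0])

    def test_matches_sort_and_average_oracle(self):
        ds, targets, _ = make_random_dataset(seed=4, n_genes=40, n_targets=3)
        pred = predict_knn(ds, targets, k=5)
        D = oracle.combined_distances(ds.complete_profiles())
        pv = ds.strain_matrix(ds.prediction_strain, ds.unmasked_genes)
        name_to_unmasked_row = {g: i for i, g in enumerate(ds.unmasked_genes)}
        forbidden = {ds.gene_index(g) for g in targets.genes}
        for r, g in enumerate(targets.genes):
            nbrs = oracle.knn(D, ds.gene_index(g), 5, forbidden)
            rows = [name_to_unmasked_row[ds.genes[j]] for j in nbrs]
            expected = oracle.average_profiles(pv, rows)
            np.testing.assert_allclose(pred.values[r], expected, atol=1e-12)

    def test_exact_recovery_on_noise_free_modules(self):
        ds, targets, truth = _noise_free_modular()
        pred = predict_knn(ds, targets, k=5)
        err = np.max(np.abs(pred.values - truth.gold_frame().to_numpy()))
        assert err <= 1e-9


class TestMutualKNN:
    def test_reduces_to_fallback_when_mutual_set_empty(self):
        ds, targets, _ = make_random_dataset(seed=5, n_genes=30, n_targets=1)
        tgt = targets.genes[0]
        # push the target far from everyone: it appears in nobody's top-K
        ds._values[0, :2] += 500.0
        res = MutualKNNPredictor(ds, targets, K=3, fallback=3).fit()
        knn3 = predict_knn(ds, targets, k=3)
        np.testing.assert_allclose(res.predictions.values, knn3.values, atol=1e-12)
        assert len(res.neighbor_graph.neighbors[tgt]) == 3

    def test_matches_composed_oracle(self):
        ds, targets, _ = make_random_dataset(seed=6, n_genes=60, n_targets=4)
        res = MutualKNNPredictor(ds, targets, K=20, fallback=3).fit()
        D = oracle.combined_distances(ds.complete_profiles())
        pv = ds.strain_matrix(ds.prediction_strain, ds.unmasked_genes)
        row_of = {g: i for i, g in enumerate(ds.unmasked_genes)}
        forbidden = {ds.gene_index(g) for g in targets.genes}
        for r, g in enumerate(targets.genes):
            nbrs = oracle.mutual_knn(D, ds.gene_index(g), 20, 3, forbidden)
            expected = oracle.average_profiles(pv, [row_of[ds.genes[j]] for j in nbrs])
            np.testing.assert_allclose(res.predictions.values[r], expected, atol=1e-12)

    def test_exact_recovery_on_noise_free_modules(self):
        ds, targets, truth = _noise_free_modular(seed=1)
        res = MutualKNNPredictor(ds, targets, K=10, fallback=3).fit()
        err = np.max(np.abs(res.predictions.values - truth.gold_frame().to_numpy()))
        assert err <= 1e-9


class TestDenseSubnet:
    def test_matches_composed_oracle(self):
        ds, targets, _ = make_random_dataset(seed=7, n_genes=50, n_targets=3)
        res = DenseSubnetPredictor(ds, targets, K=12, m=6).fit()
        D = oracle.combined_distances(ds.complete_profiles())
        pv = ds.strain_matrix(ds.prediction_strain, ds.unmasked_genes)
        row_of = {g: i for i, g in enumerate(ds.unmasked_genes)}
        forbidden = {ds.gene_index(g) for g in targets.genes}
        for r, g in enumerate(targets.genes):
            nbrs = oracle.dense_subnet(D, ds.gene_index(g), 12, 6, forbidden)
            expected = oracle.average_profiles(pv, [row_of[ds.genes[j]] for j in nbrs])
            np.testing.assert_allclose(res.predictions.values[r], expected, atol=1e-12)

    def test_exact_recovery_on_noise_free_modules(self):
        ds, targets, truth = _noise_free_modular(seed=2)
        res = DenseSubnetPredictor(ds, targets, K=10, m=5).fit()
        err = np.max(np.abs(res.predictions.values - truth.gold_frame().to_numpy()))
        assert err <= 1e-9


def _linear_map_dataset(seed=0, noise_sd=0.0, n_genes=200, n_tp=8):
    """Prediction strain built as a fixed linear map of the 24 predictors."""
    rng = np.random.default_rng(seed)
    strains = ["wt", "s1", "s2", "pred"]
    vals = np.empty((n_genes, 4, n_tp, 1))
    vals[:, :3, :, 0] = rng.normal(5, 2, (n_genes, 3, n_tp))
    W = rng.normal(0, 0.3, (n_tp, 3 * n_tp))
    a = rng.normal(0, 1.0, n_tp)
    X = vals[:, :3, :, 0].reshape(n_genes, 3 * n_tp)
    Y = X @ W.T + a + rng.normal(0, noise_sd, (n_genes, n_tp))
    vals[:, 3, :, 0] = Y
    ds = ExpressionDataset(
        [f"g{i:03d}" for i in range(n_genes)], strains, "pred", np.arange(n_tp) * 10.0, vals
    )
    targets = TargetSet(tuple(ds.genes[:5]), "pred")
    return ds.mask_targets(targets), targets, W, a, Y


class TestTimepointRegression:
    def test_copied_strain_recovers_unit_coefficient(self):
        ds, targets, _ = make_random_dataset(seed=8, n_genes=60, n_strains=3, n_timepoints=4)
        # prediction strain := copy of strain s0
        ds._values[:, 2] = ds._values[:, 0]
        res = TimepointRegressionPredictor(ds, targets).fit()
        for ti, fit in enumerate(res.regression_fits):
            coef = fit.coefficients
            label = f"s0.t{ds.timepoints[ti]:g}"
            assert coef[label] == pytest.approx(1.0, abs=1e-8)
            others = coef.drop(label)
            assert np.max(np.abs(others.to_numpy())) < 1e-8
            assert fit.residual_sd < 1e-8

    def test_constructed_half_half_combination_recovered(self):
        ds, targets, _ = make_random_dataset(seed=9, n_genes=80, n_strains=4, n_timepoints=3)
        # prediction strain := average of strains s1 and s2 at each timepoint
        ds._values[:, 3] = 0.5 * (ds._values[:, 1] + ds._values[:, 2])
        res = TimepointRegressionPredictor(ds, targets).fit()
        for ti, fit in enumerate(res.regression_fits):
            t = ds.timepoints[ti]
            assert fit.coefficients[f"s1.t{t:g}"] == pytest.approx(0.5, abs=1e-8)
            assert fit.coefficients[f"s2.t{t:g}"] == pytest.approx(0.5, abs=1e-8)

    def test_noisy_fit_matches_normal_equations_oracle(self):
        ds, targets, W, a, Y = _linear_map_dataset(seed=10, noise_sd=0.5)
        res = TimepointRegressionPredictor(ds, targets).fit()
        train = [g for g in ds.genes if g not in targets.genes]
        X = np.column_stack(
            [np.ones(len(train)), ds.complete_profiles()[[ds.gene_index(g) for g in train]]]
        )
        y = ds.strain_matrix("pred", train)
        for ti, fit in enumerate(res.regression_fits):
            beta = oracle.normal_equations(X, y[:, ti])
            assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
            np.testing.assert_allclose(fit.coefficients.to_numpy(), beta[1:], atol=1e-8)

    def test_coefficient_recovery_error_vanishes_with_noise(self):
        errs = []
        for noise in (0.5, 0.05, 0.0):
            ds, targets, W, a, _ = _linear_map_dataset(seed=11, noise_sd=noise)
            res = TimepointRegressionPredictor(ds, targets).fit()
            err = max(
                np.max(np.abs(fit.coefficients.to_numpy() - W[ti]))
                for ti, fit in enumerate(res.regression_fits)
            )
            errs.append(err)
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-8

    def test_collinear_design_names_columns(self):
        ds, targets, _ = make_random_dataset(seed=12, n_genes=60, n_strains=3, n_timepoints=4)
        ds._values[:, 1, 1] = ds._values[:, 1, 0]  # duplicate a predictor column
        with pytest.raises(CollinearityError, match="s1"):
            TimepointRegressionPredictor(ds, targets).fit()

    def test_too_few_training_genes_rejected(self):
        ds, targets, _ = make_random_dataset(seed=13, n_genes=20, n_targets=3)
        with pytest.raises(ValueError, match="training genes"):
            TimepointRegressionPredictor(ds, targets).fit()


class TestModelInterface:
    def test_unmasked_targets_are_rejected(self):
        ds, targets, _ = make_random_dataset(seed=14)
        unmasked = ds.copy()
        unmasked.mask[:] = False
        with pytest.raises(ValueError, match="masked"):
            KNNPredictor(unmasked, targets, k=3)

    def test_summary_mentions_model_and_sizes(self):
        ds, targets, _ = make_random_dataset(seed=15)
        res = KNNPredictor(ds, targets, k=4).fit()
        s = res.summary()
        assert "knn" in s and "Neighborhood sizes" in s

    def test_precomputed_distance_gives_identical_predictions(self):
        ds, targets, _ = make_random_dataset(seed=16)
        D = combined_distance_matrix(ds)
        a = KNNPredictor(ds, targets, k=4).fit().predictions.values
        b = KNNPredictor(ds, targets, k=4, distance=D).fit().predictions.values
        np.testing.assert_array_equal(a, b)

    def test_inverse_distance_weighting_changes_little_on_duplicates(self):
        ds, targets, _ = make_random_dataset(seed=17, n_genes=25, n_targets=1)
        uni = KNNPredictor(ds, targets, k=3).fit().predictions.values
        wtd = KNNPredictor(ds, targets, k=3, weighting="inverse-distance").fit().predictions.values
        assert uni.shape == wtd.shape
        assert np.all(np.isfinite(wtd))
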