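"""Stability selection, final OLS weights, whole-network training."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.linear_model import Lasso

from conftest import make_expression
from coordshift.datatypes import ExpressionMatrix
from coordshift.network import (
    GeneRegulatoryNetwork,
    StabilityConfig,
    _target_rng,
    fit_target_weights,
    select_stable_predictors,
    train_network,
)
from coordshift.reconstruct import reconstruct_expression
from coordshift.simulate import SimulationConfig, simulate_study


def _linear_instance(rng, n=200, n_noise=8):
    b, c = rng.normal(size=n), rng.normal(size=n)
    y = 2 * b - c
    noise = rng.normal(size=(n_noise, n))
    genes = ["y", "b", "c"] + [f"z{i}" for i in range(n_noise)]
    return make_expression(np.vstack([y, b, c, noise]), genes=genes)


class TestSelectStablePredictors:
    def test_noiseless_linear_relation_is_always_selected(self, rng):
        expr = _linear_instance(rng)
        freq = select_stable_predictors(
            "y", [g for g in expr.genes if g != "y"], expr,
            StabilityConfig(n_subsamples=50, seed=1),
        )
        assert freq["b"] == 1.0 and freq["c"] == 1.0

    def test_permuted_copy_of_target_is_rarely_selected(self, rng):
        n = 200
        y = rng.normal(size=n)
        perm = rng.permutation(y)
        others = rng.normal(size=(5, n))
        expr = make_expression(
            np.vstack([y, perm, others]),
            genes=["y", "perm"] + [f"z{i}" for i in range(5)],
        )
        freq = select_stable_predictors(
            "y", [g for g in expr.genes if g != "y"], expr,
            StabilityConfig(n_subsamples=50, seed=2),
        )
        assert freq["perm"] <= 0.2

    def test_single_subsample_gives_binary_frequencies(self, rng):
        expr = _linear_instance(rng, n=40)
        freq = select_stable_predictors(
            "y", [g for g in expr.genes if g != "y"], expr,
            StabilityConfig(n_subsamples=1, seed=3),
        )
        assert set(freq.values()) <= {0.0, 1.0}

    def test_constant_target_warns_and_returns_empty(self):
        expr = make_expression(np.vstack([np.ones(20), np.random.default_rng(0).normal(size=20)]),
                               genes=["flat", "x"])
        with pytest.warns(UserWarning, match="constant"):
            assert select_stable_predictors("flat", ["x"], expr) == {}

    def test_too_few_samples_rejected(self, rng):
        expr = _linear_instance(rng, n=8)
        with pytest.raises(ValueError, match="10 samples"):
            select_stable_predictors("y", ["b"], expr)

    def test_frequencies_match_explicit_brute_force_loop(self, rng):
        """4 genes, 12 samples: exact agreement with an independent re-run."""
        vals = rng.normal(size=(4, 12))
        vals[0] = 1.5 * vals[1] - 0.8 * vals[2] + 0.1 * rng.normal(size=12)
        expr = make_expression(vals, genes=["a", "b", "c", "d"])
        grid = (0.02, 0.05, 0.1, 0.3, 0.6)
        cfg = StabilityConfig(
            n_subsamples=20, lambda_grid=grid, max_predictors_per_fit=2, seed=9
        )
        freq = select_stable_predictors("a", ["b", "c", "d"], expr, cfg)

        # brute force: same subsample stream, explicit per-alpha Lasso fits
        y = vals[0]
        y = (y - y.mean()) / y.std()
        X = vals[1:].T
        X = (X - X.mean(0)) / X.std(0)
        rng2 = _target_rng(9, "a")
        counts = np.zeros(3)
        m = 6
        for _ in range(20):
            idx = rng2.choice(12, m, replace=False)
            Xs, ys = X[idx], y[idx]
            best, best_key = None, None
            for alpha in grid:
                coef = Lasso(alpha=alpha, fit_intercept=False, tol=1e-10).fit(
                    Xs, ys
                ).coef_
                nnz = int((coef != 0).sum())
                if nnz > 2:
                    continue
                rss = float(((ys - Xs @ coef) ** 2).sum())
                bic = m * np.log(rss / m + 1e-12) + nnz * np.log(m)
                key = (bic, nnz, -alpha)
                if best_key is None or key < best_key:
                    best, best_key = coef, key
            counts += best != 0
        np.testing.assert_array_equal(
            np.array([freq["b"], freq["c"], freq["d"]]), counts / 20
        )


class TestFitTargetWeights:
    def test_exact_weights_on_noiseless_data(self, rng):
        expr = _linear_instance(rng)
        w = fit_target_weights("y", ["b", "c"], expr)
        np.testing.assert_allclose(w.to_numpy(), [2.0, -1.0], atol=1e-10)

    def test_identity_predictor_gets_unit_weight(self, rng):
        y = rng.normal(size=30)
        expr = make_expression(np.vstack([y, y]), genes=["y", "copy"])
        w = fit_target_weights("y", ["copy"], expr)
        assert w["copy"] == pytest.approx(1.0, abs=1e-12)

    def test_ols_sampling_error_within_bounds(self, rng):
        n = 500
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = 0.7 * x1 - 0.3 * x2 + rng.normal(scale=0.1, size=n)
        expr = make_expression(np.vstack([y, x1, x2]), genes=["y", "x1", "x2"])
        w = fit_target_weights("y", ["x1", "x2"], expr)
        assert w["x1"] == pytest.approx(0.7, abs=0.05)
        assert w["x2"] == pytest.approx(-0.3, abs=0.05)

    def test_collinear_predictors_fall_back_to_ridge_with_warning(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.1, size=30)
        expr = make_expression(np.vstack([y, x, 2 * x]), genes=["y", "x", "x2"])
        with pytest.warns(UserWarning, match="ridge"):
            w = fit_target_weights("y", ["x", "x2"], expr)
        assert np.isfinite(w).all()

    def test_scaling_a_predictor_scales_its_weight_inversely(self, rng):
        expr = _linear_instance(rng)
        scaled = expr.values.copy()
        scaled.loc["b"] *= 4.0
        expr_scaled = ExpressionMatrix(scaled, "residual")
        w = fit_target_weights("y", ["b", "c"], expr)
        w2 = fit_target_weights("y", ["b", "c"], expr_scaled)
        assert w2["b"] == pytest.approx(w["b"] / 4.0)
        assert w2["c"] == pytest.approx(w["c"])
        # reconstruction output is unchanged by the rescaling
        from coordshift.datatypes import RegulatoryModel

        m1 = RegulatoryModel(pd.DataFrame(
            {"predictor": ["b", "c"], "target": ["y", "y"], "weight": w.to_numpy()}))
        m2 = RegulatoryModel(pd.DataFrame(
            {"predictor": ["b", "c"], "target": ["y", "y"], "weight": w2.to_numpy()}))
        r1 = reconstruct_expression(m1, expr).values
        r2 = reconstruct_expression(m2, expr_scaled).values
        pd.testing.assert_frame_equal(r1, r2)


class TestTrainNetwork:
    def test_independent_genes_give_empty_network(self, rng):
        expr = make_expression(rng.normal(size=(2, 60)), genes=["a", "b"])
        model = train_network(expr, StabilityConfig(n_subsamples=30, seed=1))
        assert model.n_edges == 0

    def test_deterministic_given_seed(self, rng):
        expr = make_expression(rng.normal(size=(6, 50)))
        cfg = StabilityConfig(n_subsamples=10, seed=5)
        m1 = train_network(expr, cfg)
        m2 = train_network(expr, cfg)
        pd.testing.assert_frame_equal(m1.edges, m2.edges)

    def test_noiseless_simulation_recovers_true_weights(self):
        cfg = SimulationConfig(
            n_genes=20, n_modules=1, within_module_edge_prob=0.15,
            noise_sd=0.0, n_samples_per_group=20, max_in_degree=2, seed=8,
        )
        model, _, expr, _, _ = simulate_study(cfg)
        trained = train_network(
            expr, StabilityConfig(n_subsamples=20, max_predictors_per_fit=4, seed=1)
        )
        true_preds = {
            t: dict(zip(sub["predictor"], sub["weight"]))
            for t, sub in model.edges.groupby("target")
        }
        # in a noiseless linear system the selected predictors must be a
        # subset of the true ones up to exact aliasing (a gene with a single
        # parent is perfectly collinear with it and interchangeable), and
        # when the full true set is selected the OLS weights are exact
        corr = np.corrcoef(expr.values.to_numpy())
        idx = {g: i for i, g in enumerate(expr.genes)}

        def aliases(g):
            return {
                h for h in expr.genes if abs(corr[idx[g], idx[h]]) > 1 - 1e-9
            }

        n_exact = 0
        for t, sub in trained.edges.groupby("target"):
            got = dict(zip(sub["predictor"], sub["weight"]))
            # aliases of the target itself cover roots whose deterministic
            # single-parent descendants predict them perfectly in reverse
            allowed = aliases(t) - {t}
            for p in true_preds.get(t, {}):
                allowed |= aliases(p)
            assert set(got) <= allowed, t
            if set(got) == set(true_preds.get(t, {})) and got:
                for p, w in got.items():
                    assert w == pytest.approx(true_preds[t][p], abs=1e-6)
        # the fitted model reproduces every trained target exactly
        recon = reconstruct_expression(trained, expr)
        centered = expr.values.sub(expr.values.mean(axis=1), axis=0)
        for t in recon.covered_genes:
            np.testing.assert_allclose(
                recon.values.loc[t], centered.loc[t], atol=1e-6
            )

    def test_edge_recovery_on_noisy_simulation(self):
        """Sens >= 0.8 and FDR <= 0.2 (undirected pairs) at n=300, in-degree <= 3."""
        cfg = SimulationConfig(
            n_genes=150, n_modules=4, n_samples_per_group=50,
            noise_sd=0.8, max_in_degree=3, seed=5,
        )
        model, _, expr, _, _ = simulate_study(cfg)
        trained = train_network(
            expr,
            StabilityConfig(
                n_subsamples=30, selection_threshold=0.875,
                max_predictors_per_fit=6, candidate_prefilter=30, seed=2,
            ),
        )
        true_pairs = {
            frozenset(e) for e in zip(model.edges["predictor"], model.edges["target"])
        }
        found = {
            frozenset(e) for e in zip(trained.edges["predictor"], trained.edges["target"])
        }
        sens = len(true_pairs & found) / len(true_pairs)
        fdr = len(found - true_pairs) / len(found)
        assert sens >= 0.8
        assert fdr <= 0.2


class TestEstimatorInterface:
    def test_fit_predict_roundtrip_and_sklearn_protocol(self, rng):
        X = pd.DataFrame(
            rng.normal(size=(60, 5)), columns=[f"g{i}" for i in range(5)]
        )
        X["g0"] = 1.2 * X["g1"] - 0.5 * X["g2"]
        est = GeneRegulatoryNetwork(n_subsamples=20, seed=0)
        assert clone(est).get_params() == est.get_params()
        est.set_params(n_subsamples=25)
        assert est.n_subsamples == 25
        est.fit(X)
        assert est.n_features_in_ == 5
        assert {"predictor", "target", "weight"} <= set(est.edges_.columns)
        pred = est.predict(X)
        assert "g0" in pred.columns
        obs = X["g0"] - X["g0"].mean()
        np.testing.assert_allclose(pred["g0"], obs, atol=1e-6)

    def test_predict_before_fit_raises(self):
        with pytest.raises(AttributeError, match="not fitted"):
            GeneRegulatoryNetwork().predict(pd.DataFrame(np.zeros((3, 2))))
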