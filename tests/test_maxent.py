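import numpy as np
import pytest
from scipy import optimize

from herbniche.maxent import (FeatureExpansion, MaxEntModel, build_features,
                              class_base_beta, fit_maxent, fit_sdm,
                              jackknife_gain, percent_contribution,
                              permutation_importance, predict,
                              presence_matrix, response_curve,
                              sample_background)
from herbniche.metrics import auc


def penalized_objective(lam, f_pres_mean, F_bg, beta):
    """The fitted objective, written independently for oracle checks."""
    lam = np.atleast_1d(lam)
    eta = F_bg @ lam
    mx = eta.max()
    logz = mx + np.log(np.exp(eta - mx).sum())
    return float(lam @ f_pres_mean - logz - beta @ np.abs(lam))


class TestBuildFeatures:
    def test_linear_column_count(self, rng):
        X = rng.random((40, 3))
        exp, Fp, Fb = build_features(["a", "b", "c"], X[:8], X, "L")
        assert Fb.shape[1] == 3

    def test_linear_quadratic_column_count(self, rng):
        X = rng.random((40, 3))
        exp, _, Fb = build_features(["a", "b", "c"], X[:8], X, "LQ")
        assert Fb.shape[1] == 6

    def test_constant_variable_excluded(self, rng):
        X = rng.random((40, 2))
        X[:, 1] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            exp, _, Fb = build_features(["a", "c"], X[:8], X, "L")
        assert exp.var_names == ["a"] and Fb.shape[1] == 1

    def test_hinge_and_threshold_forms(self, rng):
        X = rng.random((200, 1))
        exp, _, _ = build_features(["a"], X[:10], X, "HT",
                                   hinge_knots=3, threshold_knots=3)
        z = exp.scale(np.array([[0.4]]))[0, 0]
        F = exp.transform(np.array([[0.4]]))[0]
        for k, f in enumerate(exp.features):
            if f.fclass == "H":
                assert F[k] == pytest.approx(max(0, (z - f.knot) / (1 - f.knot)))
            elif f.fclass == "R":
                assert F[k] == pytest.approx(max(0, (f.knot - z) / f.knot))
            elif f.fclass == "T":
                assert F[k] == float(z > f.knot)

    def test_product_features_pair_distinct_variables(self, rng):
        X = rng.random((40, 3))
        exp, _, _ = build_features(["a", "b", "c"], X[:8], X, "LP")
        prods = [f for f in exp.features if f.fclass == "P"]
        assert len(prods) == 3
        assert all(f.var != f.var2 for f in prods)


class TestFitOracle:
    def _tiny_problem(self, seed=0, informative=True):
        rng = np.random.default_rng(seed)
        X_bg = rng.random((20, 1))
        if informative:
            # presences biased toward high values of the variable
            p = X_bg[:, 0] ** 3
            idx = rng.choice(20, size=8, replace=False, p=p / p.sum())
        else:
            idx = rng.choice(20, size=8, replace=False)
        X_pres = X_bg[idx]
        return X_pres, X_bg

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_one_feature_matches_brute_force(self, seed):
        X_pres, X_bg = self._tiny_problem(seed)
        exp, Fp, Fb = build_features(["x"], X_pres, X_bg, "L")
        model = fit_maxent(Fp, Fb, rm=1.0, expansion=exp, tol=1e-12,
                           max_iter=5000)
        m = Fp.shape[0]
        beta = np.array([1.0 * class_base_beta("L", m)
                         * np.sqrt(max(Fp.var(axis=0)[0], 1e-12) / m)])
        fpm = Fp.mean(axis=0)
        # independent oracle: dense grid + bounded scalar refinement
        grid = np.linspace(-50, 50, 4001)
        vals = [penalized_objective(l, fpm, Fb, beta) for l in grid]
        l0 = grid[int(np.argmax(vals))]
        res = optimize.minimize_scalar(
            lambda l: -penalized_objective(l, fpm, Fb, beta),
            bounds=(l0 - 0.5, l0 + 0.5), method="bounded",
            options={"xatol": 1e-10})
        assert model.coefficients[0] == pytest.approx(res.x, abs=1e-4)

    def test_two_features_match_brute_force(self):
        X_pres, X_bg = self._tiny_problem(3)
        exp, Fp, Fb = build_features(["x"], X_pres, X_bg, "LQ")
        model = fit_maxent(Fp, Fb, rm=1.0, expansion=exp, tol=1e-13,
                           max_iter=20000)
        m = Fp.shape[0]
        beta = np.array([class_base_beta(c, m) * np.sqrt(max(v, 1e-12) / m)
                         for c, v in zip("LQ", Fp.var(axis=0))])
        fpm = Fp.mean(axis=0)
        # coarse 2-D grid, then Nelder-Mead refinement of the same objective
        g = np.linspace(-30, 30, 121)
        best, arg = -np.inf, (0.0, 0.0)
        for a in g:
            for b in g:
                v = penalized_objective(np.array([a, b]), fpm, Fb, beta)
                if v > best:
                    best, arg = v, (a, b)
        # alternate simplex and Powell restarts; the L1 kink stalls either
        # method alone
        x = np.array(arg, float)
        for _ in range(6):
            for meth, opts in (
                    ("Nelder-Mead", {"xatol": 1e-12, "fatol": 1e-14,
                                     "maxiter": 50000}),
                    ("Powell", {"xtol": 1e-12, "ftol": 1e-14,
                                "maxiter": 50000})):
                res = optimize.minimize(
                    lambda l: -penalized_objective(l, fpm, Fb, beta),
                    x0=x, method=meth, options=opts)
                if -res.fun > penalized_objective(x, fpm, Fb, beta):
                    x = res.x
        np.testing.assert_allclose(model.coefficients, x, atol=1e-4)

    def test_raw_sums_to_one_over_background(self, seed=4):
        X_pres, X_bg = self._tiny_problem(4)
        exp, Fp, Fb = build_features(["x"], X_pres, X_bg, "LQ")
        model = fit_maxent(Fp, Fb, rm=1.0, expansion=exp)
        total = np.exp(Fb @ model.coefficients - model.log_partition).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_null_presences_give_near_uniform_model(self):
        rng = np.random.default_rng(8)
        X_bg = rng.random((1000, 2))
        X_pres = X_bg[rng.choice(1000, 200, replace=False)]
        exp, Fp, Fb = build_features(["a", "b"], X_pres, X_bg, "LQ")
        model = fit_maxent(Fp, Fb, rm=1.0, expansion=exp)
        w = np.exp(Fb @ model.coefficients - model.log_partition)
        n = len(w)
        kl_from_uniform = float(np.sum(w * np.log(np.maximum(w * n, 1e-300))))
        assert kl_from_uniform < 0.01

    def test_doubling_rm_never_increases_l1_norm(self):
        for seed in (0, 1, 2):
            X_pres, X_bg = self._tiny_problem(seed)
            exp, Fp, Fb = build_features(["x"], X_pres, X_bg, "LQ")
            norms = []
            for rm in (0.5, 1.0, 2.0, 4.0):
                m = fit_maxent(Fp, Fb, rm=rm, expansion=exp, tol=1e-10,
                               max_iter=5000)
                norms.append(np.abs(m.coefficients).sum())
            assert all(a >= b - 1e-6 for a, b in zip(norms, norms[1:]))

    def test_too_few_presences_rejected(self, rng):
        X = rng.random((20, 1))
        exp, Fp, Fb = build_features(["x"], X[:4], X, "L")
        with pytest.raises(ValueError, match="5 presences"):
            fit_maxent(Fp, Fb, expansion=exp)


def hand_model(coefs, log_partition=0.0, entropy=0.0, n_background=10,
               var_names=("a", "b")):
    """A model with a fixed linear expansion and given coefficients."""
    k = len(var_names)
    exp = FeatureExpansion(list(var_names), np.zeros(k), np.ones(k),
                           [__import__("herbniche.maxent", fromlist=["Feature"])
                            .Feature("L", v) for v in var_names])
    m = MaxEntModel(exp, np.asarray(coefs, float), rm=1.0, fc="L",
                    log_partition=log_partition, entropy_H=entropy,
                    n_background=n_background)
    m.bg_var_means = np.full(k, 0.5)
    return m


class TestPredict:
    def test_zero_coefficients_give_uniform_raw(self, rng):
        n = 10
        model = hand_model([0.0, 0.0], log_partition=np.log(n), n_background=n)
        X = rng.random((n, 2))
        np.testing.assert_allclose(model.raw(X), 1.0 / n)

    def test_transforms_preserve_ranking(self, rng):
        model = hand_model([0.7, -0.3], log_partition=1.0, entropy=2.0)
        X = rng.random((50, 2))
        c = model.suitability(X, "cloglog")
        l = model.suitability(X, "logistic")
        np.testing.assert_array_equal(np.argsort(c), np.argsort(l))
        assert np.all((c >= 0) & (c <= 1)) and np.all((l >= 0) & (l <= 1))

    def test_cloglog_matches_hand_computation(self):
        # 4 cells, 2 linear features, fixed coefficients: spreadsheet-style
        model = hand_model([0.7, -0.3], log_partition=0.2, entropy=1.5)
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        eta = 0.7 * X[:, 0] - 0.3 * X[:, 1]
        expected = 1.0 - np.exp(-np.exp(1.5) * np.exp(eta - 0.2))
        np.testing.assert_allclose(model.suitability(X, "cloglog"), expected)

    def test_missing_variable_is_schema_error(self, smooth_stack, niche_scene):
        stack, _, occ = niche_scene
        model = fit_sdm(stack, occ, fc="L", background_size=500, seed=0)
        reduced = stack.subset(["temp"])
        with pytest.raises(KeyError, match="precip"):
            predict(model, reduced)

    def test_predict_on_stack_bounded_and_masked(self, niche_scene):
        stack, _, occ = niche_scene
        model = fit_sdm(stack, occ, fc="LQ", background_size=500, seed=0)
        surf = predict(model, stack, "cloglog")
        v = surf.valid_values()
        assert np.all((v >= 0) & (v <= 1))
        assert surf.mask.sum() == stack.mask.sum()


class TestDiagnostics:
    def test_single_variable_contribution_is_100(self, niche_scene):
        stack, _, occ = niche_scene
        model = fit_sdm(stack.subset(["precip"]), occ, fc="LQ",
                        background_size=500, seed=0)
        contrib = percent_contribution(model)
        assert contrib["precip"] == pytest.approx(100.0)

    def test_duplicated_variable_splits_contribution(self, niche_scene, rng):
        from herbniche.grid import RasterLayer, RasterStack

        stack, _, occ = niche_scene
        dup = RasterStack([stack["precip"],
                           RasterLayer(stack.spec, "precip2",
                                       stack["precip"].values.copy()),
                           stack["noise"]])
        single = fit_sdm(stack.subset(["precip", "noise"]), occ, fc="LQ",
                         background_size=500, seed=0)
        double = fit_sdm(dup, occ, fc="LQ", background_size=500, seed=0)
        c1 = percent_contribution(single)
        c2 = percent_contribution(double)
        pair_total = c2["precip"] + c2["precip2"]
        assert pair_total == pytest.approx(c1["precip"], abs=5.0)

    def test_permutation_importance_extremes(self, rng):
        model = hand_model([2.0, 0.0])
        X_pres = np.column_stack([rng.random(30) * 0.3 + 0.7, rng.random(30)])
        X_bg = rng.random((300, 2))
        imp = permutation_importance(model, X_pres, X_bg, seed=1)
        assert imp["a"] == pytest.approx(100.0)
        assert imp["b"] == 0.0

    def test_jackknife_gain_bounds(self, niche_scene):
        stack, _, occ = niche_scene
        gains = jackknife_gain(stack, occ, fc="LQ", background_size=500, seed=0)
        full = next(iter(gains.values()))[2]
        assert full > 0
        # the full fit maximizes the penalized objective, so submodel gains
        # may exceed it only by the penalty slack; allow a small tolerance
        tol = 1e-3 + 1e-2 * full
        for v, (only, without, f) in gains.items():
            assert f == pytest.approx(full)
            assert only <= f + tol
            assert without <= f + tol
        # the uninformative noise variable adds nearly nothing alone
        assert gains["noise"][0] < 0.15 * full
        # withholding the sole informative variable destroys most of the gain
        assert gains["precip"][1] < 0.5 * full

    def test_response_curve_monotone_for_linear_model(self):
        model = hand_model([3.0, 0.0], log_partition=1.0, entropy=1.0)
        xs, ys, _ = response_curve(model, "a", grid=50)
        assert len(xs) == 50
        assert np.all(np.diff(ys) > 0)

    def test_response_curve_flat_for_null_model(self):
        model = hand_model([0.0, 0.0], log_partition=1.0, entropy=1.0)
        xs, ys, intervals = response_curve(model, "a", grid=50)
        assert np.allclose(ys, ys[0])
        assert intervals == [] or intervals == [(float(xs[0]), float(xs[-1]))]

    def test_symmetric_quadratic_interval_symmetric(self):
        import herbniche.maxent as mx

        exp = FeatureExpansion(["a"], np.zeros(1), np.ones(1),
                               [mx.Feature("L", "a"), mx.Feature("Q", "a")])
        model = MaxEntModel(exp, np.array([16.0, -16.0]), 1.0, "LQ",
                            log_partition=4.0, entropy_H=0.0, n_background=10)
        model.bg_var_means = np.array([0.5])
        xs, ys, intervals = response_curve(model, "a", grid=401)
        assert len(intervals) == 1
        lo, hi = intervals[0]
        assert (lo + hi) / 2 == pytest.approx(0.5, abs=0.01)


class TestRecoveryOrdering:
    def test_fitted_model_never_beats_oracle(self, niche_scene):
        stack, truth, occ = niche_scene
        model = fit_sdm(stack, occ, fc="LQ", background_size=500, seed=0)
        _, X_bg = sample_background(stack, 500, 0)
        X_pres = presence_matrix(stack, occ)
        fitted_auc = auc(model.suitability(X_pres, "cloglog"),
                         model.suitability(X_bg, "cloglog"))
        row, col = stack.spec.cell_of(occ.lons, occ.lats)
        oracle_auc = auc(truth.values[row, col], truth.valid_values())
        assert fitted_auc <= oracle_auc + 0.05
        assert fitted_auc > 0.7
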