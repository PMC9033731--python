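"""Mixed model: AR1 x AR1 operator, design assembly, REML correctness."""

import numpy as np
import pandas as pd
import pytest

from heatqtl import simdata
from heatqtl.melmm import (
    GxECov,
    MixedModel,
    REMLOptions,
    UnstructuredDelta,
    ar1_corr,
    ar1_inv,
    ar1_kron_correlation,
    build_design,
    default_delta,
    genetic_correlations,
    reml_fit,
)
from heatqtl.melmm.gxe import DiagDelta, FADelta
from heatqtl.types import (
    FAParams,
    FieldDesign,
    QTLSpec,
    SpatialParams,
    TraitObservations,
)


class TestAR1Kron:
    def test_zero_rho_is_identity(self):
        op = ar1_kron_correlation(0.0, 0.0, 3, 4)
        assert np.allclose(op.dense(), np.eye(12))

    def test_lag_product_rule(self):
        op = ar1_kron_correlation(0.5, 0.4, 4, 3)
        dense = op.dense()
        # plots ordered column-major (rows fastest): lag (1 row, 1 col)
        assert dense[0, 4 + 1] == pytest.approx(0.4 * 0.5)

    def test_matches_dense_kronecker_oracle(self):
        rr, rc = 0.55, -0.3
        op = ar1_kron_correlation(rr, rc, 4, 3)
        oracle = np.kron(ar1_corr(rc, 3), ar1_corr(rr, 4))
        assert np.allclose(op.dense(), oracle)
        rng = np.random.default_rng(50)
        X = rng.normal(size=(12, 5))
        assert np.allclose(op.matvec(X), oracle @ X)
        assert np.allclose(op.solve(X), np.linalg.solve(oracle, X))
        sign, ld = np.linalg.slogdet(oracle)
        assert op.logdet() == pytest.approx(ld)

    def test_ar1_inverse_closed_form(self):
        rho, n = 0.62, 7
        assert np.allclose(ar1_inv(rho, n), np.linalg.inv(ar1_corr(rho, n)))

    def test_incomplete_grid_submatrix(self):
        op_full = ar1_kron_correlation(0.4, 0.3, 3, 3)
        from heatqtl.melmm.ar1 import AR1KronResidual
        cols = np.array([0, 0, 1, 1, 2])
        rows = np.array([0, 1, 0, 2, 1])
        op = AR1KronResidual(cols, rows)
        op.set_params(2.0, 0.4, 0.3)
        dense_full = 2.0 * np.kron(ar1_corr(0.3, 3), ar1_corr(0.4, 3))
        idx = cols * 3 + rows
        oracle = dense_full[np.ix_(idx, idx)]
        assert np.allclose(op.dense(), oracle)
        x = np.linspace(0, 1, 5)
        assert np.allclose(op.solve(x), np.linalg.solve(oracle, x))


class TestBuildDesign:
    def test_level_counts_small_example(self):
        rows, vals = [], []
        lines = ["L1", "L2", "L3"]
        for e in ["E1", "E2"]:
            k = 0
            for g in lines + ["CHK"]:
                rows.append((e, 2015, 1, k + 1, g, g == "CHK"))
                vals.append(1.0)
                k += 1
        design = FieldDesign(pd.DataFrame(
            rows, columns=["env", "year", "column", "row", "genotype",
                           "is_check"]))
        obs = TraitObservations(design, pd.Series(vals))
        spec = build_design(obs, design)
        assert spec.X.shape[1] == 2 + 2  # 2 env means + check x env levels
        assert spec.Zg.shape[1] == 6     # 3 lines x 2 environments

    def test_unknown_genotype_names_plot(self):
        design = FieldDesign(pd.DataFrame(
            [("E1", 2015, 1, 1, "L1", False), ("E1", 2015, 1, 2, "??", False)],
            columns=["env", "year", "column", "row", "genotype", "is_check"]))
        obs = TraitObservations(design, pd.Series([1.0, 2.0]))
        with pytest.raises(ValueError, match="'\\?\\?'"):
            build_design(obs, design, dh_lines=["L1"])

    def test_column_count_matches_enumeration(self, small_trial):
        spec = small_trial["spec"]
        t = spec.n_env
        tbl = small_trial["design"].table
        checks = tbl.loc[tbl["is_check"], "genotype"].nunique()
        assert spec.X.shape[1] == t + checks * t
        assert spec.Zg.shape == (spec.n_plots, spec.n_lines * t)


def _dense_reml_loglik(spec, model, theta):
    """Direct dense evaluation of the residual log-likelihood (oracle)."""
    y, X = spec.y, spec.X
    Z = np.asarray(model.Z.todense())
    parts = model.gxe.split(theta[:model.gxe.n_params])
    Sig = np.zeros((model.q, model.q))
    blocks = []
    for th, (_, dmod, K) in zip(parts, model.gxe.terms):
        delta = dmod.delta(th)
        Kd = K if K is not None else np.eye(spec.n_lines)
        blocks.append(np.kron(delta, Kd))
    Sig[:model.qg, :model.qg] = sum(blocks)
    ng, ne = model.gxe.n_params, len(model.extra_ranges)
    for (name, lo, hi), v in zip(model.extra_ranges, theta[ng:ng + ne]):
        Sig[np.arange(lo, hi), np.arange(lo, hi)] = v
    n = len(y)
    R = np.zeros((n, n))
    for e, (s2, rr, rc) in enumerate(model._split_resid(theta)):
        rows = spec.env_rows(e)
        model.ops[e].set_params(s2, rr, rc)
        R[np.ix_(rows, rows)] = model.ops[e].dense()
    V = R + Z @ Sig @ Z.T
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    P = Vinv - Vinv @ X @ np.linalg.inv(XtVX) @ X.T @ Vinv
    return -0.5 * (np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtVX)[1]
                   + y @ P @ y)


class TestREML:
    def test_loglik_matches_dense_oracle(self, small_trial):
        spec = small_trial["spec"]
        gxe = GxECov([("g", default_delta(2), None)], spec.n_lines)
        model = MixedModel(spec, gxe, REMLOptions(max_iter=0))
        theta = model.init_theta()
        st = model._evaluate(theta)
        assert st.loglik == pytest.approx(
            _dense_reml_loglik(spec, model, theta), rel=1e-9)

    def test_loglik_matches_dense_oracle_with_grm(self, small_trial):
        spec = small_trial["spec"]
        geno = small_trial["geno"]
        Gm = geno.values() @ geno.values().T
        gxe = GxECov([("a", DiagDelta(2), Gm), ("p", DiagDelta(2), None)],
                     spec.n_lines)
        model = MixedModel(spec, gxe, REMLOptions(max_iter=0))
        theta = model.init_theta()
        st = model._evaluate(theta)
        assert st.loglik == pytest.approx(
            _dense_reml_loglik(spec, model, theta), rel=1e-9)

    @staticmethod
    def _rcb(seed=60, g=25, b=4, sg2=2.0, sb2=0.6, se2=1.0):
        rng = np.random.default_rng(seed)
        gv = rng.normal(0, np.sqrt(sg2), g)
        bv = rng.normal(0, np.sqrt(sb2), b)
        rows, vals = [], []
        for j in range(b):
            for i in range(g):
                rows.append(("E1", 2015, j + 1, i + 1, f"L{i:03d}", False))
                vals.append(10 + gv[i] + bv[j] + rng.normal(0, np.sqrt(se2)))
        design = FieldDesign(pd.DataFrame(
            rows, columns=["env", "year", "column", "row", "genotype",
                           "is_check"]))
        obs = TraitObservations(design, pd.Series(vals))
        return design, obs, np.array(vals).reshape(b, g)

    def test_balanced_rcb_equals_anova(self):
        design, obs, Y = self._rcb()
        b, g = Y.shape
        spec = build_design(obs, design, block_factor="column")
        gxe = GxECov([("g", DiagDelta(1), None)], spec.n_lines)
        model = MixedModel(spec, gxe, REMLOptions(
            tol=1e-12, estimate_spatial_corr=False, max_iter=100))
        fit = model.fit()
        gm, bm, mu = Y.mean(axis=0), Y.mean(axis=1), Y.mean()
        mse = np.sum((Y - gm[None] - bm[:, None] + mu) ** 2) / ((g - 1) * (b - 1))
        msg = b * np.sum((gm - mu) ** 2) / (g - 1)
        msb = g * np.sum((bm - mu) ** 2) / (b - 1)
        assert fit.deltas["g"][0, 0] == pytest.approx((msg - mse) / b, rel=1e-7)
        assert fit.extra_variances["column(E1)"] == pytest.approx(
            (msb - mse) / g, rel=1e-7)
        assert fit.spatial.for_env("E1")[0] == pytest.approx(mse, rel=1e-7)

    def test_zero_genetic_variance_hits_floor(self):
        design, obs, Y = self._rcb(seed=61, sg2=0.0)
        spec = build_design(obs, design, block_factor="column")
        gxe = GxECov([("g", DiagDelta(1), None)], spec.n_lines)
        model = MixedModel(spec, gxe, REMLOptions(
            tol=1e-10, estimate_spatial_corr=False))
        fit = model.fit()
        assert fit.deltas["g"][0, 0] <= 10 * model.floor

    def test_scale_equivariance(self, small_trial):
        spec = small_trial["spec"]
        opts = REMLOptions(tol=1e-9, max_iter=80)
        fit1 = reml_fit(spec, options=opts)
        from dataclasses import replace
        spec2 = replace(spec, y=2.0 * spec.y)
        fit2 = reml_fit(spec2, options=opts)
        d1, d2 = fit1.deltas["g"], fit2.deltas["g"]
        assert np.allclose(d2, 4.0 * d1, rtol=2e-3, atol=1e-4)
        for env in spec.envs:
            s1, r1, c1 = fit1.spatial.for_env(env)
            s2, r2, c2 = fit2.spatial.for_env(env)
            assert s2 == pytest.approx(4.0 * s1, rel=2e-3)
            assert r2 == pytest.approx(r1, abs=2e-3)
            assert c2 == pytest.approx(c1, abs=2e-3)

    def test_loglik_invariant_to_fixed_reparameterisation(self, small_trial):
        spec = small_trial["spec"]
        opts = REMLOptions(tol=1e-9, max_iter=80)
        fit1 = reml_fit(spec, options=opts)
        from dataclasses import replace
        C = np.array(
            [[1.0, 1.0, 0.0], [1.0, -1.0, 0.0], [0.0, 1.0, 1.0]])[:spec.X.shape[1],
                                                                  :spec.X.shape[1]]
        if C.shape[0] != spec.X.shape[1]:
            C = np.eye(spec.X.shape[1])
            C[0, 1] = 1.0
        spec2 = replace(spec, X=spec.X @ C)
        fit2 = reml_fit(spec2, options=opts)
        assert fit2.loglik == pytest.approx(fit1.loglik, abs=1e-5)

    def test_fa_attains_unstructured_likelihood(self):
        # FA(t-1) + Psi can match an unstructured Delta on data generated
        # from an unstructured covariance
        lm = simdata.simulate_linkage_map(2, 8, 80.0, seed=62)
        geno = simdata.simulate_dh_population(lm, 120, seed=63)
        envs = ["E1", "E2", "E3"]
        design = simdata.generate_prep_design(
            list(geno.lines), {2015: envs}, ["CHK1"], 1, grid_columns=8,
            seed=64)
        lam = np.array([[0.6, 0.0], [0.4, 0.3], [0.3, -0.35]])
        fa = FAParams(lam, np.array([0.05, 0.08, 0.06]))
        spatial = SpatialParams({e: (0.25, 0.2, 0.2) for e in envs})
        obs = simdata.simulate_phenotypes(
            design, geno, QTLSpec([]), {}, {e: 5.0 for e in envs}, fa,
            spatial, seed=65)
        spec = build_design(obs, design, dh_lines=geno.lines)
        opts = REMLOptions(tol=1e-9, max_iter=120)
        fit_un = reml_fit(spec, gxe=GxECov(
            [("g", UnstructuredDelta(3), None)], spec.n_lines), options=opts)
        fit_fa = reml_fit(spec, gxe=GxECov(
            [("g", FADelta(3, 2), None)], spec.n_lines), options=opts)
        assert fit_fa.loglik == pytest.approx(fit_un.loglik, abs=0.05)

    def test_sigma2_interval_coverage(self):
        # 95% AI-based intervals for the residual variance across replicates
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(700 + rep)
            g, b, se2 = 20, 3, 1.3
            gv = rng.normal(0, 0.8, g)
            rows, vals = [], []
            for j in range(b):
                for i in range(g):
                    rows.append(("E1", 2015, j + 1, i + 1, f"L{i:02d}", False))
                    vals.append(gv[i] + rng.normal(0, np.sqrt(se2)))
            design = FieldDesign(pd.DataFrame(
                rows, columns=["env", "year", "column", "row", "genotype",
                               "is_check"]))
            obs = TraitObservations(design, pd.Series(vals))
            spec = build_design(obs, design)
            gxe = GxECov([("g", DiagDelta(1), None)], spec.n_lines)
            model = MixedModel(spec, gxe, REMLOptions(
                tol=1e-9, estimate_spatial_corr=False))
            fit = model.fit()
            i = fit.param_names.index("sigma2(E1)")
            lo = fit.theta[i] - 1.96 * fit.theta_se[i]
            hi = fit.theta[i] + 1.96 * fit.theta_se[i]
            hits += lo <= se2 <= hi
        assert 0.90 <= hits / n_rep <= 0.99

    def test_fa_covariance_recovered_across_replicates(self):
        # mean of estimated Lambda Lambda' + Psi over replicate datasets
        # approaches the generating covariance
        envs = ["E1", "E2", "E3"]
        lam = np.array([[0.55], [0.5], [0.45]])
        fa = FAParams(lam, np.array([0.06, 0.08, 0.07]))
        spatial = SpatialParams({e: (0.3, 0.3, 0.2) for e in envs})
        est = []
        for rep in range(6):
            lm = simdata.simulate_linkage_map(2, 6, 60.0, seed=600 + rep)
            geno = simdata.simulate_dh_population(lm, 200, seed=620 + rep)
            design = simdata.generate_prep_design(
                list(geno.lines), {2015: envs}, ["CHK1"], 1,
                grid_columns=10, seed=640 + rep)
            obs = simdata.simulate_phenotypes(
                design, geno, QTLSpec([]), {}, {e: 4.0 for e in envs}, fa,
                spatial, seed=660 + rep)
            spec = build_design(obs, design, dh_lines=geno.lines)
            fit = reml_fit(spec, options=REMLOptions(tol=1e-8))
            est.append(fit.deltas["g"])
        mean_delta = np.mean(est, axis=0)
        truth = fa.covariance()
        # Monte-Carlo tolerance for 6 replicates at r = 200
        assert np.abs(mean_delta - truth).max() < 0.08

    def test_aliased_fixed_levels_reported(self, small_trial):
        spec = small_trial["spec"]
        from dataclasses import replace
        X = np.column_stack([spec.X, spec.X[:, 0]])
        spec2 = replace(spec, X=X, fixed_names=spec.fixed_names + ["dup"])
        with pytest.raises(ValueError, match="aliased"):
            MixedModel(spec2, GxECov([("g", default_delta(2), None)],
                                     spec.n_lines))

    def test_nondecreasing_loglik_across_iterations(self, small_trial):
        spec = small_trial["spec"]
        fit = reml_fit(spec, options=REMLOptions(tol=1e-9))
        lls = [ll for _, ll, _ in fit.iter_log]
        assert all(b >= a - 1e-8 for a, b in zip(lls, lls[1:]))


class TestGeneticCorrelations:
    def test_unit_diagonal_and_perfect_single_factor(self):
        fa = FAParams(np.array([[0.5], [-0.4]]), np.zeros(2))
        corr = fa.correlations()
        assert np.allclose(np.diag(corr), 1.0)
        assert corr[0, 1] == pytest.approx(-1.0)

    def test_fit_correlations_match_blup_correlations(self):
        # high-heritability simulation: BLUP matrix correlations approach
        # the estimated genetic correlations
        lm = simdata.simulate_linkage_map(2, 8, 80.0, seed=66)
        geno = simdata.simulate_dh_population(lm, 200, seed=67)
        envs = ["E1", "E2"]
        design = simdata.generate_prep_design(
            list(geno.lines), {2015: envs}, ["CHK1"], 1, grid_columns=10,
            seed=68)
        fa = FAParams(np.array([[0.8], [0.7]]), np.array([0.05, 0.05]))
        spatial = SpatialParams({e: (0.1, 0.1, 0.1) for e in envs})
        obs = simdata.simulate_phenotypes(
            design, geno, QTLSpec([]), {}, {e: 0.0 for e in envs}, fa,
            spatial, seed=69)
        spec = build_design(obs, design, dh_lines=geno.lines)
        fit = reml_fit(spec, options=REMLOptions(tol=1e-9))
        corr = genetic_correlations(fit)
        blups = fit.genetic_blups()
        sample = np.corrcoef(blups.to_numpy(), rowvar=False)[0, 1]
        truth = fa.correlations()[0, 1]
        assert corr.iloc[0, 1] == pytest.approx(truth, abs=0.05)
        assert corr.iloc[0, 1] == pytest.approx(sample, abs=0.05)
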