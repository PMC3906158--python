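import math

import numpy as np
import pytest
from scipy import optimize

from ebqtl.design import DesignSpec, EffectDescriptor, build_design_spec
from ebqtl.eblasso import (EBlassoFit, FitControls, PriorSpec, SQFactors,
                           compute_sq, coordinate_update, fit,
                           penalized_marginal_loglik, posterior_summary,
                           update_lambda, update_noise_variance)
from ebqtl.maps import PhenotypeVector, genotypes_from_strings


def coord_objective(v, s, q, lam):
    return (-0.5 * math.log1p(v * s) + 0.5 * q * q * v / (1.0 + v * s)
            - lam * v)


def numeric_coordinate_max(s, q, lam):
    """1-D oracle: maximize the per-coordinate objective numerically.

    Locates the stationary point of the objective by bisection on its
    derivative (no use of the closed-form root), falling back to the
    boundary v = 0 when the derivative at zero is non-positive.
    """
    def deriv(v):
        u = 1.0 + v * s
        return -0.5 * s / u + 0.5 * q * q / (u * u) - lam

    if deriv(0.0) <= 0.0:
        return 0.0
    hi = 1.0
    while deriv(hi) > 0.0:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("unbounded objective")
    return float(optimize.brentq(deriv, 0.0, hi, xtol=1e-13, rtol=1e-15))


class TestCoordinateUpdate:
    def test_boundary_of_inclusion(self):
        # q^2 = 4 equals s + 2 lam = 2 + 2: exactly at the boundary
        assert coordinate_update(2.0, 2.0, 1.0) == 0.0
        # spec's worked instance: q^2 = 2 <= s + 2 lam = 1 + 1
        assert coordinate_update(1.0, 1.4142135, 0.5) == 0.0

    def test_interior_maximizer_closed_form(self):
        v = coordinate_update(1.0, 2.0, 0.5)
        u = -0.5 + math.sqrt(4.25)
        assert v == pytest.approx((u - 1.0), abs=1e-12)
        assert v == pytest.approx(0.5616, abs=1e-4)
        assert abs(v - numeric_coordinate_max(1.0, 2.0, 0.5)) < 1e-8

    def test_lambda_zero_rvm_limit(self):
        # (q^2 - s)/s^2 with s=1, q=2 -> 3
        assert coordinate_update(1.0, 2.0, 0.0) == pytest.approx(3.0)
        assert abs(3.0 - numeric_coordinate_max(1.0, 2.0, 0.0)) < 1e-7

    def test_degenerate_column_rejected(self):
        with pytest.raises(ValueError):
            coordinate_update(0.0, 1.0, 0.1)
        with pytest.raises(ValueError):
            coordinate_update(-1.0, 1.0, 0.1)

    def test_inclusion_law_exact(self):
        rng = np.random.default_rng(5)
        for _ in range(500):
            s = float(rng.uniform(0.01, 50))
            q = float(rng.normal(0, 5))
            lam = float(rng.choice([0.0, rng.uniform(0, 20)]))
            v = coordinate_update(s, q, lam)
            assert (v > 0) == (q * q > s + 2 * lam)
        # exact boundary stays out
        assert coordinate_update(2.0, math.sqrt(2.0 + 2 * 1.5), 1.5) == 0.0

    def test_oracle_agreement_sample(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            s = float(rng.uniform(0.05, 30))
            q = float(rng.normal(0, 6))
            lam = float(rng.choice([0.0, rng.uniform(0, 10)]))
            v = coordinate_update(s, q, lam)
            assert abs(v - numeric_coordinate_max(s, q, lam)) < 1e-8


def dense_sq_oracle(x, X_active, sigma2, sigma2_e, yc):
    """Builds C = s2e I + sum v_j x_j x_j' explicitly and inverts it."""
    n = yc.size
    C = sigma2_e * np.eye(n)
    for j in range(X_active.shape[1]):
        C += sigma2[j] * np.outer(X_active[:, j], X_active[:, j])
    Ci = np.linalg.inv(C)
    return float(x @ Ci @ x), float(x @ Ci @ yc)


class TestComputeSQ:
    def test_empty_active_set(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=15)
        yc = rng.normal(size=15)
        f = compute_sq(x, np.empty((15, 0)), [], 2.0, yc)
        assert f.s == pytest.approx(float(x @ x) / 2.0)
        assert f.q == pytest.approx(float(x @ yc) / 2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 25, 8
        X = rng.normal(size=(n, m))
        yc = rng.normal(size=n)
        M = 4
        sigma2 = rng.uniform(0.2, 3.0, M)
        s2e = float(rng.uniform(0.5, 2.0))
        X_act = X[:, :M]
        for j in range(M, m):
            f = compute_sq(X[:, j], X_act, sigma2, s2e, yc)
            s_o, q_o = dense_sq_oracle(X[:, j], X_act, sigma2, s2e, yc)
            assert f.s == pytest.approx(s_o, rel=1e-8)
            assert f.q == pytest.approx(q_o, rel=1e-8)

    def test_active_column_leave_one_out(self):
        rng = np.random.default_rng(3)
        n, M = 20, 3
        X_act = rng.normal(size=(n, M))
        sigma2 = rng.uniform(0.5, 2.0, M)
        yc = rng.normal(size=n)
        s2e = 1.2
        pos = 1
        f = compute_sq(X_act[:, pos], X_act, sigma2, s2e, yc,
                       active_position=pos)
        # oracle: drop the column's own contribution from C
        other = [j for j in range(M) if j != pos]
        s_o, q_o = dense_sq_oracle(X_act[:, pos], X_act[:, other],
                                   sigma2[other], s2e, yc)
        assert f.s == pytest.approx(s_o, rel=1e-8)
        assert f.q == pytest.approx(q_o, rel=1e-8)


class TestPosteriorSummary:
    def test_matches_dense_bayes_oracle(self):
        rng = np.random.default_rng(9)
        n, M = 30, 3
        X = rng.normal(size=(n, M))
        yc = rng.normal(size=n)
        sigma2 = rng.uniform(0.3, 2.0, M)
        s2e = 0.8
        beta, Sigma = posterior_summary(X, yc, sigma2, s2e)
        A = X.T @ X / s2e + np.diag(1.0 / sigma2)
        Sigma_o = np.linalg.inv(A)
        beta_o = Sigma_o @ X.T @ yc / s2e
        np.testing.assert_allclose(Sigma, Sigma_o, rtol=1e-10)
        np.testing.assert_allclose(beta, beta_o, rtol=1e-10)

    def test_ridge_limit_is_ols(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        yc = 1.7 * x + rng.normal(size=40) * 0.1
        beta, _ = posterior_summary(x[:, None], yc, [1e12], 1.0)
        ols = float(x @ yc / (x @ x))
        assert beta[0] == pytest.approx(ols, rel=1e-6)

    def test_shrinkage_limit_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        yc = 1.7 * x
        beta, _ = posterior_summary(x[:, None], yc, [1e-12], 1.0)
        assert abs(beta[0]) < 1e-8


class TestNoiseVarianceUpdate:
    def test_empty_active_is_sample_variance(self):
        rng = np.random.default_rng(1)
        yc = rng.normal(size=50)
        s2e = update_noise_variance(yc, 50, np.empty((0, 0)), np.empty(0),
                                    float(np.var(yc)))
        assert s2e == pytest.approx(float(yc @ yc) / 50)

    def test_fixed_point_matches_numeric_argmax(self):
        # iterate the stationary-point update at fixed variances; the fixed
        # point must agree with direct 1-D maximization of the marginal
        # likelihood in sigma2_e
        rng = np.random.default_rng(4)
        n, M = 30, 5
        X = rng.normal(size=(n, M))
        sigma2 = rng.uniform(0.3, 2.0, M)
        beta_true = rng.normal(size=M)
        yc = X @ beta_true + rng.normal(size=n) * 0.7
        yc -= yc.mean()
        var_y = float(np.var(yc))

        def marglik(s2e):
            C = s2e * np.eye(n) + (X * sigma2) @ X.T
            sign, logdet = np.linalg.slogdet(C)
            return -0.5 * (logdet + yc @ np.linalg.solve(C, yc))

        res = optimize.minimize_scalar(lambda t: -marglik(t),
                                       bounds=(1e-4, 10.0), method="bounded",
                                       options={"xatol": 1e-12})
        s2e = var_y
        for _ in range(400):
            beta, Sigma = posterior_summary(X, yc, sigma2, s2e)
            resid = yc - X @ beta
            s2e_new = update_noise_variance(resid, n, Sigma, sigma2, var_y)
            if abs(s2e_new - s2e) < 1e-14:
                break
            s2e = s2e_new
        assert s2e == pytest.approx(float(res.x), rel=1e-6)

    def test_noiseless_floor(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=20)
        s2e = update_noise_variance(np.zeros(20), 20, np.eye(1) * 1e-12,
                                    np.array([1.0]), 1.0)
        assert s2e > 0


class TestLambdaUpdate:
    def test_empty_active_set(self):
        prior = PriorSpec(a=2.0, b=4.0)
        assert update_lambda(0, 0.0, prior) == pytest.approx(0.25)
        # negative mode hits the floor
        assert update_lambda(0, 0.0, PriorSpec(0.5, 1.0)) == 1e-10

    def test_single_effect_example(self):
        assert update_lambda(1, 1.0, PriorSpec(1.0, 1.0)) == pytest.approx(0.5)

    def test_posterior_mode_property(self):
        # lambda maximizes (M + a - 1) log lam - lam (b + sum sigma2)
        rng = np.random.default_rng(6)
        for _ in range(20):
            M = int(rng.integers(1, 10))
            a = float(rng.uniform(0.5, 3))
            b = float(rng.uniform(0.1, 3))
            ssum = float(rng.uniform(0.1, 5))
            lam = update_lambda(M, ssum, PriorSpec(a, b))
            grid = np.linspace(1e-6, 10 * lam, 40001)
            obj = (M + a - 1) * np.log(grid) - grid * (b + ssum)
            assert abs(grid[np.argmax(obj)] - lam) < grid[1] - grid[0] + 1e-9


def make_population(n, m, seed):
    rng = np.random.default_rng(seed)
    letters = np.array(["A", "H", "B"])
    rows = letters[rng.integers(0, 3, size=(n, m))].tolist()
    return genotypes_from_strings(rows, [f"i{t}" for t in range(n)],
                                  [f"b{t}" for t in range(m)])


class TestFit:
    def test_pure_noise_near_empty(self):
        # null behavior: at most one false positive on average over seeds
        from ebqtl.report import significance_test
        n_false = []
        for seed in range(6):
            G = make_population(100, 20, seed)
            rng = np.random.default_rng(seed + 100)
            y = PhenotypeVector("t", rng.normal(size=100), G.individual_ids)
            spec = build_design_spec(G, True)
            result = fit(G, y, spec, PriorSpec(1.0, 0.1),
                         FitControls(track_objective=False))
            reports = significance_test(result, n=100)
            n_false.append(sum(r.significant for r in reports))
        assert np.mean(n_false) <= 1.0

    def test_planted_single_additive_effect(self):
        G = make_population(200, 50, 3)
        rng = np.random.default_rng(3)
        from ebqtl.design import effect_column
        target = EffectDescriptor("A", 7, 7)
        yv = 1.0 * effect_column(target, G) + rng.normal(size=200) * 0.5
        y = PhenotypeVector("t", yv, G.individual_ids)
        spec = build_design_spec(G, True)
        result = fit(G, y, spec, PriorSpec(0.5, 0.5),
                     FitControls(track_objective=False))
        active_descs = [d for d, _ in result.active]
        assert target in active_descs
        pos = active_descs.index(target)
        assert result.beta_hat[pos] > 0.5

    def test_determinism(self):
        G = make_population(60, 10, 5)
        rng = np.random.default_rng(5)
        y = PhenotypeVector("t", rng.normal(size=60), G.individual_ids)
        spec = build_design_spec(G, True)
        r1 = fit(G, y, spec, PriorSpec(0.1, 0.1), FitControls())
        r2 = fit(G, y, spec, PriorSpec(0.1, 0.1), FitControls())
        assert np.array_equal(r1.active_idx, r2.active_idx)
        assert np.array_equal(r1.beta_hat, r2.beta_hat)
        assert r1.sigma2_e == r2.sigma2_e

    def test_objective_monotone_within_sweeps(self):
        G = make_population(50, 8, 1)
        rng = np.random.default_rng(1)
        from ebqtl.design import effect_column
        yv = (effect_column(EffectDescriptor("A", 2, 2), G)
              + rng.normal(size=50) * 0.8)
        y = PhenotypeVector("t", yv, G.individual_ids)
        spec = build_design_spec(G, True)
        result = fit(G, y, spec, PriorSpec(0.5, 0.5), FitControls())
        trace = np.asarray(result.objective_trace)
        sweeps = np.asarray(result.trace_sweeps)
        assert trace.size > 0
        for s in np.unique(sweeps):
            seg = trace[sweeps == s]
            assert np.all(np.diff(seg) >= -1e-6 * np.maximum(1, np.abs(seg[:-1])))

    def test_dominates_single_column_models(self):
        # final penalized marginal log-likelihood beats every single-column
        # model evaluated at the fit's final (lambda, sigma2_e)
        from ebqtl.design import dense_design
        from ebqtl.eblasso import _ActiveSet
        G = make_population(20, 6, 9)
        rng = np.random.default_rng(9)
        from ebqtl.design import effect_column
        yv = (1.2 * effect_column(EffectDescriptor("A", 3, 3), G)
              + rng.normal(size=20) * 0.6)
        y = PhenotypeVector("t", yv, G.individual_ids)
        spec = build_design_spec(G, True)
        result = fit(G, y, spec, PriorSpec(0.5, 0.5),
                     FitControls(admission_zsq=0.0))
        yc = y.values - y.values.mean()
        final_act = _ActiveSet(20)
        for (desc, v), lin in zip(result.active, result.active_idx):
            from ebqtl.design import ColumnMaterializer
            final_act.add(int(lin), ColumnMaterializer(G).column(int(lin)), v)
        final_act.refresh(yc, result.sigma2_e)
        final_obj = penalized_marginal_loglik(final_act, yc, result.sigma2_e,
                                              result.lam)
        X = dense_design(G, True)
        for j in range(X.shape[1]):
            x = X[:, j]
            if np.all(x == x[0]):
                continue
            f = compute_sq(x, np.empty((20, 0)), [], result.sigma2_e, yc)
            v = coordinate_update(f.s, f.q, result.lam)
            single = _ActiveSet(20)
            if v > 0:
                single.add(j, x, v)
            single.refresh(yc, result.sigma2_e)
            obj = penalized_marginal_loglik(single, yc, result.sigma2_e,
                                            result.lam)
            assert final_obj >= obj - 1e-8

    def test_active_bound_warning_only(self, caplog):
        G = make_population(30, 8, 2)
        rng = np.random.default_rng(2)
        y = PhenotypeVector("t", rng.normal(size=30), G.individual_ids)
        spec = build_design_spec(G, True)
        result = fit(G, y, spec, PriorSpec(0.5, 0.5),
                     FitControls(max_active_warn=0, max_sweeps=2,
                                 admission_zsq=0.0))
        assert isinstance(result, EBlassoFit)
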