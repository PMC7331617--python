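import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import scipy.special
import scipy.stats

from bombnet import (
    FitResult,
    ModelSpec,
    aicc,
    dredge,
    enumerate_candidates,
    fit_model,
    lrt,
    vif_screen,
)


def _fake_fit(llf, k, n):
    return FitResult(
        spec=ModelSpec("y", "gaussian"), llf=llf, k=k, n=n,
        params=pd.Series(dtype=float), bse=pd.Series(dtype=float),
        deviance=None, converged=True,
    )


class TestVifScreen:
    def test_orthogonal_predictors_all_one(self):
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(50, 3)))
        df = pd.DataFrame(q, columns=["a", "b", "c"])
        df = df - df.mean()  # orthogonal to the intercept too
        kept, trace = vif_screen(df, threshold=3.0)
        assert kept == ["a", "b", "c"]
        assert np.allclose(trace["vif"], 1.0, atol=0.02)

    def test_duplicated_column_flagged_infinite_and_dropped(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=60)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=60)})
        kept, trace = vif_screen(df, threshold=3.0)
        assert len(kept) == 2 and "c" in kept
        first_step = trace[trace.step == 0]
        assert np.isinf(first_step[first_step.dropped].vif).all()

    def test_vifs_match_correlation_matrix_inverse(self):
        """Closed-form oracle: VIF_j equals the j-th diagonal of the inverse
        correlation matrix for standardized predictors."""
        rng = np.random.default_rng(2)
        cov = np.array([[1.0, 0.6, 0.3], [0.6, 1.0, 0.5], [0.3, 0.5, 1.0]])
        X = rng.multivariate_normal(np.zeros(3), cov, size=40_000)
        X = (X - X.mean(0)) / X.std(0)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        corr = np.corrcoef(X, rowvar=False)
        oracle = np.diag(np.linalg.inv(corr))
        _, trace = vif_screen(df, threshold=1e9)
        got = trace.set_index("predictor")["vif"]
        np.testing.assert_allclose(got[["a", "b", "c"]], oracle, rtol=1e-6)


class TestFitModel:
    def test_intercept_only_gaussian_recovers_mean(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"y": rng.normal(2.5, 1.0, 200)})
        fit = fit_model(ModelSpec("y", "gaussian"), df)
        assert fit.params["Intercept"] == pytest.approx(df.y.mean())
        assert fit.k == 2  # intercept + error variance

    def test_group_means_model_fits_exactly(self):
        # responses constant within groups: the group-factor fit is exact
        df = pd.DataFrame({"y": [2, 2, 7, 7], "g": ["a", "a", "b", "b"]})
        fit = fit_model(ModelSpec("y", "poisson", ("g",)), df)
        assert fit.deviance == pytest.approx(0.0, abs=1e-8)

    def test_poisson_recovery_within_three_se(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 3000)
        y = rng.poisson(np.exp(0.5 + 0.8 * x))
        fit = fit_model(ModelSpec("y", "poisson", ("x",)),
                        pd.DataFrame({"y": y, "x": x}))
        assert abs(fit.params["x"] - 0.8) < 3 * fit.bse["x"]
        assert 0.8 < fit.overdispersion < 1.25

    def test_poisson_rejects_non_integer_response(self):
        df = pd.DataFrame({"y": [1.5, 2.0, 3.0]})
        with pytest.raises(ValueError, match="integer"):
            fit_model(ModelSpec("y", "poisson"), df)

    def test_gamma_zero_epsilon_policy(self, caplog):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"y": np.r_[rng.gamma(2, 1, 30), 0.0]})
        with caplog.at_level("WARNING"):
            fit = fit_model(ModelSpec("y", "gamma"), df)
        assert fit.n == 31
        dropped = fit_model(ModelSpec("y", "gamma"), df, gamma_zero_policy="drop")
        assert dropped.n == 30

    def test_gamma_llf_matches_direct_maximization(self):
        """Independent oracle: intercept-only Gamma loglik maximized over
        (mean, shape) by a generic optimizer."""
        rng = np.random.default_rng(6)
        y = rng.gamma(2.0, 1.5, 120)
        fit = fit_model(ModelSpec("y", "gamma"), pd.DataFrame({"y": y}))

        def neg(theta):
            mu, a = np.exp(theta)
            return -np.sum(scipy.stats.gamma.logpdf(y, a=a, scale=mu / a))

        opt = scipy.optimize.minimize(neg, [0.5, 0.5], method="Nelder-Mead",
                                      options={"xatol": 1e-10, "fatol": 1e-10})
        assert fit.llf == pytest.approx(-opt.fun, abs=1e-6)

    def test_marginality_enforced(self):
        with pytest.raises(ValueError, match="marginality"):
            ModelSpec("y", "poisson", ("x:month",))

    def test_gamma_random_intercept_unsupported(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "patch": ["a", "b"]})
        with pytest.raises(NotImplementedError):
            fit_model(ModelSpec("y", "gamma", (), group="patch"), df)


class TestPoissonGLMMOracle:
    def _fixture(self):
        # regenerates the frozen dataset behind the reference values below
        rng = np.random.default_rng(42)
        G, ni = 12, 6
        u = rng.normal(0, 0.5, G)
        x = rng.normal(0, 1, G * ni)
        g = np.repeat(np.arange(G), ni)
        y = rng.poisson(np.exp(1.0 + 0.5 * x + u[g]))
        return pd.DataFrame({"y": y, "x": x, "patch": [f"P{i}" for i in g]})

    def test_matches_reference_mixed_model_fit(self):
        """Frozen reference from an independent adaptive-quadrature Poisson
        mixed-model fit of the same data (deviance reported relative to the
        saturated model, hence the offset in the loglik comparison)."""
        df = self._fixture()
        fit = fit_model(ModelSpec("y", "poisson", ("x",), group="patch"), df)
        ref_beta = {"Intercept": 0.7882522, "x": 0.5429605}
        ref_sigma = 0.6524331
        ref_llf_rel_saturated = -55.19136
        assert fit.converged
        assert fit.params["Intercept"] == pytest.approx(ref_beta["Intercept"], abs=0.02)
        assert fit.params["x"] == pytest.approx(ref_beta["x"], abs=0.02)
        assert fit.params["patch_re_sd"] == pytest.approx(ref_sigma, abs=0.02)
        y = df.y.to_numpy(float)
        saturated = float(
            np.sum(np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0)), 0.0)
                   - y - scipy.special.gammaln(y + 1))
        )
        assert fit.llf == pytest.approx(ref_llf_rel_saturated + saturated, abs=0.05)
        assert fit.k == 3  # intercept, slope, random-effect variance


class TestAicc:
    def test_formula_arithmetic(self):
        assert aicc(_fake_fit(-50.0, 3, 30)) == pytest.approx(106 + 24 / 26)

    def test_large_n_limit_is_aic(self):
        fit = _fake_fit(-50.0, 3, 100_000)
        assert abs(aicc(fit) - (100 + 6)) < 0.01

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError):
            aicc(_fake_fit(-50.0, 3, 4))

    def test_gaussian_delta_aicc_invariant_to_response_rescaling(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"y": rng.normal(0, 1, 60), "x": rng.normal(0, 1, 60)})
        def deltas(frame):
            f0 = fit_model(ModelSpec("y", "gaussian"), frame)
            f1 = fit_model(ModelSpec("y", "gaussian", ("x",)), frame)
            return aicc(f1) - aicc(f0)
        scaled = df.assign(y=df.y * 37.0)
        assert deltas(df) == pytest.approx(deltas(scaled), abs=1e-8)


class TestDredge:
    def test_single_predictor_cap_one_gives_two_models(self):
        assert len(enumerate_candidates(["x"], max_terms=1)) == 2

    def test_enumeration_count_matches_brute_force(self):
        """3 predictors + forced month + 3 month-interactions: independent
        brute-force count over all subsets filtered for marginality."""
        import itertools
        preds = ["a", "b", "c"]
        inters = ["a:month", "b:month", "c:month"]
        legal = 0
        for k in range(4):
            for mains in itertools.combinations(preds, k):
                ok_inters = [i for i in inters if i.split(":")[0] in mains]
                legal += 2 ** len(ok_inters)
        got = enumerate_candidates(preds, inters, forced=("month",))
        assert len(got) == legal == 27

    def test_null_model_always_included(self):
        cands = enumerate_candidates(["a", "b"], forced=("month",), max_terms=1)
        assert ("month",) in cands

    def test_recovers_strong_predictor(self):
        rng = np.random.default_rng(8)
        n = 200
        df = pd.DataFrame({
            "x": rng.normal(0, 1, n), "w1": rng.normal(0, 1, n),
            "w2": rng.normal(0, 1, n),
        })
        df["y"] = rng.poisson(np.exp(1.0 + 0.5 * df.x))
        sel = dredge(df, "y", "poisson", ["x", "w1", "w2"], max_terms=2)
        assert "x" in sel.best.spec.terms
        assert sel.table.delta_aicc.iloc[0] == 0.0
        assert sel.table.aicc.is_monotonic_increasing


class TestLrt:
    def test_identical_models(self):
        f = _fake_fit(-50.0, 3, 30)
        assert lrt(f, f) == (0.0, 0, 1.0)

    def test_chi2_384_df1_p_005(self):
        nested = _fake_fit(-51.92, 2, 30)
        full = _fake_fit(-50.0, 3, 30)
        chi2, df, p = lrt(nested, full)
        assert chi2 == pytest.approx(3.84)
        assert df == 1
        assert p == pytest.approx(0.050, abs=0.001)

    def test_nesting_violation_detected(self):
        with pytest.raises(ValueError, match="nested"):
            lrt(_fake_fit(-40.0, 2, 30), _fake_fit(-50.0, 3, 30))
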