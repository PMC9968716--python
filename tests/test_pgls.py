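"""PGLS engine: OLS equivalence, residual identities, recovery, profiles."""

import numpy as np
import pandas as pd
import pytest

from ecorules.pgls import (CategoricalCoding, DesignSpec, fit_pgls,
                           phylo_residuals, predict_profile, r_squared)
from ecorules.phylo import GLSContext, Phylogeny
from ecorules.synth import (BEAK_INTERCEPT, BEAK_SLOPE, SyntheticScenario,
                            _lambda_noise, simulate_traits, simulate_tree)


def _ols(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(y) - X.shape[1])
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
    return beta, se


class TestDesignSpec:
    def test_formula_roundtrip(self):
        spec = DesignSpec.from_formula("log_beak ~ log_mass * tmax")
        assert spec.fixed_terms == ("log_mass", "tmax")
        assert spec.interactions == (("log_mass", "tmax"),)
        assert spec.formula() == "log_beak ~ log_mass + tmax + log_mass:tmax"

    def test_three_way_star_expansion(self):
        spec = DesignSpec.from_formula("y ~ a * b * c")
        assert set(spec.fixed_terms) == {"a", "b", "c"}
        assert ("a", "b", "c") in spec.interactions
        assert len(spec.interactions) == 4  # three 2-way + one 3-way

    def test_interaction_without_main_effect_rejected(self):
        with pytest.raises(ValueError, match="missing from fixed"):
            DesignSpec(response="y", fixed_terms=("a",),
                       interactions=(("a", "b"),))

    def test_categorical_treatment_coding(self):
        spec = DesignSpec(
            response="y", fixed_terms=("habit",),
            categorical={"habit": CategoricalCoding(
                levels=("resident", "partial", "full"),
                reference="resident")})
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0],
                           "habit": ["resident", "partial", "full"]})
        X, _ = spec.build_design(df)
        assert list(X.columns) == ["(Intercept)", "habit[partial]",
                                   "habit[full]"]
        np.testing.assert_allclose(X["habit[partial]"], [0, 1, 0])


class TestOLSEquivalence:
    def test_fixed_lambda_zero_equals_ols(self, yule_tree_100):
        """With lambda pinned at 0 the GLS collapses to OLS exactly."""
        rng = np.random.default_rng(0)
        n = 50
        tree = simulate_tree(n, seed=5)
        df = pd.DataFrame({"species": tree.tip_labels,
                           "x": rng.standard_normal(n)})
        df["y"] = 1.0 + 2.0 * df["x"] + rng.standard_normal(n)
        spec = DesignSpec.from_formula("y ~ x")
        fit = fit_pgls(df, spec, tree, lambda_mode=0.0)
        X = np.column_stack([np.ones(n), df["x"]])
        beta, se = _ols(X, df["y"].to_numpy())
        np.testing.assert_allclose(fit.beta.to_numpy(), beta, atol=1e-8)
        np.testing.assert_allclose(fit.se.to_numpy(), se, atol=1e-8)

    def test_star_tree_ml_equals_ols(self, star_tree):
        """On a star tree V is proportional to I for every lambda."""
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"species": star_tree.tip_labels,
                           "x": rng.standard_normal(5)})
        df["y"] = 0.5 - 1.5 * df["x"] + 0.1 * rng.standard_normal(5)
        fit = fit_pgls(df, DesignSpec.from_formula("y ~ x"), star_tree)
        X = np.column_stack([np.ones(5), df["x"]])
        beta, _ = _ols(X, df["y"].to_numpy())
        np.testing.assert_allclose(fit.beta.to_numpy(), beta, atol=1e-8)


class TestFitProperties:
    def test_aic_identity_and_k(self, yule_tree_100, mixed_traits_100):
        df, _ = mixed_traits_100
        fit = fit_pgls(df, DesignSpec.from_formula("log_mass ~ temperature"),
                       yule_tree_100)
        assert fit.k == fit.k_coef + 2
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k)
        assert ((fit.p >= 0) & (fit.p <= 1)).all()

    def test_profile_loglik_beats_boundaries(self, yule_ctx_100,
                                             mixed_traits_100):
        df, _ = mixed_traits_100
        fit = fit_pgls(df, DesignSpec.from_formula("log_beak ~ log_mass"),
                       yule_ctx_100)
        for lam in (0.0, 1.0):
            alt = fit_pgls(df, fit.spec, yule_ctx_100, lambda_mode=lam,
                           compute_r2=False)
            assert fit.loglik >= alt.loglik - 1e-6

    def test_residual_normal_equations(self, yule_ctx_100, mixed_traits_100):
        """Raw residuals satisfy X' V^-1 e = 0 at the fitted lambda."""
        df, _ = mixed_traits_100
        fit = fit_pgls(df, DesignSpec.from_formula("log_beak ~ log_mass"),
                       yule_ctx_100)
        ctx = fit.ctx
        order = ctx.align(fit.residuals.index)
        e = np.empty(ctx.n)
        e[order] = phylo_residuals(fit).to_numpy()
        X = np.empty_like(fit.X.to_numpy())
        X[order] = fit.X.to_numpy()
        lam = fit.lambda_hat
        V = lam * ctx.C + (1 - lam) * np.diag(ctx.d)
        g = X.T @ np.linalg.solve(V, e)
        np.testing.assert_allclose(g, 0.0, atol=1e-8)

    def test_singular_design_names_columns(self, yule_tree_100,
                                           mixed_traits_100):
        df, _ = mixed_traits_100
        df = df.copy()
        df["dup"] = df["log_mass"]
        spec = DesignSpec(response="log_beak",
                          fixed_terms=("log_mass", "dup"))
        with pytest.raises(np.linalg.LinAlgError, match="dup"):
            fit_pgls(df, spec, yule_tree_100)

    def test_species_tree_mismatch_reported(self, yule_tree_100,
                                            mixed_traits_100):
        df, _ = mixed_traits_100
        from ecorules.phylo import PhyloError
        with pytest.raises(PhyloError, match="prune"):
            fit_pgls(df.iloc[:50], DesignSpec.from_formula("log_beak ~ log_mass"),
                     yule_tree_100)


class TestRSquared:
    def test_null_vs_null_is_zero(self, yule_ctx_100, mixed_traits_100):
        df, _ = mixed_traits_100
        null = fit_pgls(df, DesignSpec(response="log_mass"), yule_ctx_100,
                        compute_r2=False)
        assert r_squared(null, null) == pytest.approx(0.0)

    def test_perfect_fit_is_one(self, star_tree):
        df = pd.DataFrame({"species": star_tree.tip_labels,
                           "x": [1.0, 2.0, 3.0, 4.0, 5.0]})
        df["y"] = 2.0 + 3.0 * df["x"]
        fit = fit_pgls(df, DesignSpec.from_formula("y ~ x"), star_tree,
                       lambda_mode=0.0, compute_r2=False)
        null = fit_pgls(df, DesignSpec(response="y"), star_tree,
                        lambda_mode=0.0, compute_r2=False)
        assert r_squared(fit, null) == pytest.approx(1.0, abs=1e-10)

    def test_response_mismatch_rejected(self, yule_ctx_100,
                                        mixed_traits_100):
        df, _ = mixed_traits_100
        a = fit_pgls(df, DesignSpec(response="log_mass"), yule_ctx_100,
                     compute_r2=False)
        b = fit_pgls(df, DesignSpec(response="log_beak"), yule_ctx_100,
                     compute_r2=False)
        with pytest.raises(ValueError, match="mismatch"):
            r_squared(a, b)


class TestRecovery:
    def test_allometric_slope_recovery(self):
        """Mean fitted slope near the generating value over replicates."""
        slopes = []
        for seed in range(8):
            tree = simulate_tree(200, seed=300 + seed)
            sc = SyntheticScenario(n_tips=200, causal_model="null_allometry",
                                   seed=seed)
            df, _ = simulate_traits(tree, sc)
            fit = fit_pgls(df, DesignSpec.from_formula("log_beak ~ log_mass"),
                           tree, compute_r2=False)
            slopes.append(fit.beta["log_mass"])
        mc_se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - BEAK_SLOPE) < 3 * mc_se + 1e-3

    def test_coefficient_coverage(self):
        """95% CIs cover the generating slope at roughly nominal rate."""
        cover = 0
        n_rep = 25
        for seed in range(n_rep):
            tree = simulate_tree(150, seed=400 + seed)
            ctx = GLSContext.from_tree(tree)
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(150)
            y = 1.0 + 0.5 * x + _lambda_noise(ctx, 0.8, 1.0, rng)
            df = pd.DataFrame({"species": ctx.labels, "x": x, "y": y})
            fit = fit_pgls(df, DesignSpec.from_formula("y ~ x"), ctx,
                           compute_r2=False)
            from scipy import stats
            tcrit = stats.t.ppf(0.975, df=fit.n - fit.k_coef)
            lo = fit.beta["x"] - tcrit * fit.se["x"]
            hi = fit.beta["x"] + tcrit * fit.se["x"]
            cover += lo <= 0.5 <= hi
        assert 0.8 <= cover / n_rep <= 1.0


class TestPredictProfile:
    def _interaction_fit(self, sign=+1.0):
        tree = simulate_tree(120, seed=77)
        ctx = GLSContext.from_tree(tree)
        rng = np.random.default_rng(7)
        x = rng.standard_normal(120)
        m = rng.standard_normal(120)
        y = 1.0 + 0.5 * x + 0.3 * m + sign * 0.4 * x * m \
            + 0.1 * rng.standard_normal(120)
        df = pd.DataFrame({"species": ctx.labels, "x": x, "m": m, "y": y})
        return df, ctx

    def test_no_interaction_gives_parallel_curves(self):
        df, ctx = self._interaction_fit()
        fit = fit_pgls(df, DesignSpec.from_formula("y ~ x + m"), ctx,
                       compute_r2=False)
        prof = predict_profile(fit, "x", quantiles=(0.1, 0.9),
                               moderator="m", n_grid=5)
        lo = prof[prof["quantile"] == 0.1]["predicted"].to_numpy()
        hi = prof[prof["quantile"] == 0.9]["predicted"].to_numpy()
        diffs = hi - lo
        np.testing.assert_allclose(diffs, diffs[0], atol=1e-10)

    def test_positive_interaction_steepens_slope(self):
        df, ctx = self._interaction_fit(sign=+1.0)
        fit = fit_pgls(df, DesignSpec.from_formula("y ~ x * m"), ctx,
                       compute_r2=False)
        prof = predict_profile(fit, "x", quantiles=(0.1, 0.5, 0.9),
                               moderator="m", n_grid=5)
        slopes = []
        for q in (0.1, 0.5, 0.9):
            sub = prof[prof["quantile"] == q]
            slopes.append(np.polyfit(sub["value"], sub["predicted"], 1)[0])
        assert slopes[0] < slopes[1] < slopes[2]

    def test_three_way_corner_layout(self):
        """Min/max corner combinations of two moderators give 4 curves
        whose slopes equal the linear-predictor algebra."""
        rng = np.random.default_rng(11)
        tree = simulate_tree(150, seed=11)
        x, a, b = (rng.standard_normal(150) for _ in range(3))
        y = x + a + b + 0.5 * x * a + 0.25 * x * b + 0.1 * a * b \
            + 0.6 * x * a * b + 0.05 * rng.standard_normal(150)
        df = pd.DataFrame({"species": tree.tip_labels,
                           "x": x, "a": a, "b": b, "y": y})
        fit = fit_pgls(df, DesignSpec.from_formula("y ~ x * a * b"), tree,
                       compute_r2=False)
        for av in (a.min(), a.max()):
            for bv in (b.min(), b.max()):
                prof = predict_profile(fit, "x", moderator=None,
                                       fixed={"a": av, "b": bv}, n_grid=3)
                got = np.polyfit(prof["value"], prof["predicted"], 1)[0]
                expect = (fit.beta["x"] + fit.beta["x:a"] * av
                          + fit.beta["x:b"] * bv + fit.beta["x:a:b"] * av * bv)
                assert got == pytest.approx(expect, rel=1e-6)

    def test_extrapolation_warns(self, yule_ctx_100, mixed_traits_100):
        df, _ = mixed_traits_100
        fit = fit_pgls(df, DesignSpec.from_formula("log_beak ~ log_mass"),
                       yule_ctx_100, compute_r2=False)
        big = df["log_mass"].max() + 10
        with pytest.warns(UserWarning, match="extrapolat"):
            predict_profile(fit, "log_mass", grid=[0.0, big])
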