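import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from phytovuln.drivers import (
    DriverImportanceModel,
    akaike_weights,
    all_subsets,
    build_driver_dataset,
    fit_beta_glmm,
    shrink_unit_interval,
)
from phytovuln.vulnerability import VulnerabilityMap


def _simulate_beta(rng, n=500, betas=None, phi=20.0, n_vars=3, groups=None, sigma_u=0.0):
    """Logit-linear beta response in the given coefficients."""
    X = rng.normal(size=(n, n_vars))
    betas = np.zeros(n_vars) if betas is None else np.asarray(betas)
    eta = -0.3 + X @ betas
    if groups is not None:
        u = rng.normal(0, sigma_u, size=groups.max() + 1)
        eta = eta + u[groups]
    mu = expit(eta)
    y = rng.beta(mu * phi, (1 - mu) * phi)
    df = pd.DataFrame(X, columns=[f"d_v{i}" for i in range(n_vars)])
    df["relative_vulnerability"] = y
    df["locality"] = groups if groups is not None else np.arange(n)
    return df


class TestBetaFit:
    def test_recovers_single_strong_effect(self, rng):
        df = _simulate_beta(rng, n=500, betas=[0.8, 0.0, 0.0], phi=20.0)
        fit = fit_beta_glmm(df, ["d_v0"], random_intercept=False)
        assert fit.converged
        assert abs(fit.params["d_v0"] - 0.8) < 2 * fit.bse["d_v0"]

    def test_coverage_over_replicates(self):
        """True coefficient inside +/-2 SE in at least 90% of simulations."""
        hits = 0
        n_rep = 40
        for i in range(n_rep):
            rng = np.random.default_rng(100 + i)
            df = _simulate_beta(rng, n=500, betas=[0.5], phi=20.0, n_vars=1)
            fit = fit_beta_glmm(df, ["d_v0"], random_intercept=False)
            if abs(fit.params["d_v0"] - 0.5) < 2 * fit.bse["d_v0"]:
                hits += 1
        assert hits / n_rep >= 0.9

    def test_intercept_only_symmetric_response(self, rng):
        y = np.concatenate([rng.beta(5, 5, 400)])
        df = pd.DataFrame({"relative_vulnerability": y, "locality": np.arange(400)})
        fit = fit_beta_glmm(df, [], random_intercept=False)
        assert abs(fit.params["const"]) < 0.1  # logit-scale mean approx 0

    def test_noise_variable_increases_aic_on_average(self):
        worse = 0
        n_rep = 20
        for i in range(n_rep):
            rng = np.random.default_rng(200 + i)
            df = _simulate_beta(rng, n=300, betas=[0.6, 0.0], phi=15.0, n_vars=2)
            base = fit_beta_glmm(df, ["d_v0"], random_intercept=False)
            noisy = fit_beta_glmm(df, ["d_v0", "d_v1"], random_intercept=False)
            if noisy.aic > base.aic:
                worse += 1
        assert worse / n_rep > 0.5

    def test_random_intercept_recovers_group_variance(self):
        rng = np.random.default_rng(42)
        groups = np.repeat(np.arange(20), 25)
        df = _simulate_beta(rng, n=500, betas=[0.5], phi=25.0, n_vars=1,
                            groups=groups, sigma_u=0.5)
        fit = fit_beta_glmm(df, ["d_v0"], random_intercept=True)
        assert fit.converged
        assert abs(fit.params["d_v0"] - 0.5) < 3 * max(fit.bse["d_v0"], 0.05)
        assert 0.2 < fit.sigma_u < 1.0

    def test_singleton_localities_reject_random_intercept(self, rng):
        df = _simulate_beta(rng, n=50, betas=[0.2], n_vars=1)
        with pytest.raises(ValueError, match="singleton"):
            fit_beta_glmm(df, ["d_v0"], random_intercept=True)

    def test_too_few_records_rejected(self, rng):
        df = _simulate_beta(rng, n=5, n_vars=1)
        with pytest.raises(ValueError, match="at least 10"):
            fit_beta_glmm(df, ["d_v0"])

    def test_shrink_keeps_off_boundary(self):
        y = np.array([0.0, 0.5, 1.0])
        out = shrink_unit_interval(y)
        assert out.min() > 0 and out.max() < 1
        assert out[1] == pytest.approx(0.5)


class TestSubsetsAndWeights:
    def test_enumeration_matches_oracle_for_three_variables(self):
        subs = all_subsets(("a", "b", "c"))
        # 2^3 = 8 models including the intercept-only model
        assert len(subs) == 8
        oracle = {(), ("a",), ("b",), ("c",), ("a", "b"), ("a", "c"),
                  ("b", "c"), ("a", "b", "c")}
        assert set(subs) == oracle

    def test_akaike_weights_sum_to_one_and_order(self):
        w = akaike_weights(np.array([100.0, 102.0, 110.0]))
        assert w.sum() == pytest.approx(1.0)
        assert w[0] > w[1] > w[2]
        assert w[0] / w[1] == pytest.approx(np.exp(1.0))


class TestBuildDriverDataset:
    def _grids(self):
        from phytovuln import generate_climate
        return generate_climate((25, 25), seed=3)

    def test_zero_delta_when_future_equals_present(self):
        grids = self._grids()
        g = grids["present"]
        rich = np.where(g.mask, 2, 0)
        vm = VulnerabilityMap(richness=rich, threatened=np.zeros_like(rich),
                              relative_vulnerability=np.where(g.mask, 0.4, np.nan))
        ds = build_driver_dataset(vm, g, g)
        assert len(ds) == g.n_land
        assert all((ds[f"d_{v}"] == 0).all() for v in g.variables)

    def test_deltas_match_direct_subtraction(self, rng):
        grids = self._grids()
        g, f = grids["present"], grids["future_severe"]
        rich = np.where(g.mask, 1, 0)
        vm = VulnerabilityMap(richness=rich, threatened=rich,
                              relative_vulnerability=np.where(g.mask, 0.5, np.nan))
        ds = build_driver_dataset(vm, g, f)
        pick = rng.choice(len(ds), 10, replace=False)
        for i in pick:
            r, c = int(ds["row"].iloc[i]), int(ds["col"].iloc[i])
            assert ds["d_tmean"].iloc[i] == pytest.approx(
                f.values["tmean"][r, c] - g.values["tmean"][r, c])

    def test_misaligned_grids_rejected(self):
        from phytovuln import generate_climate
        a = generate_climate((25, 25), seed=1)["present"]
        b = generate_climate((30, 30), seed=1)["present"]
        vm = VulnerabilityMap(richness=np.ones((25, 25), int),
                              threatened=np.zeros((25, 25), int),
                              relative_vulnerability=np.full((25, 25), 0.5))
        with pytest.raises(ValueError, match="misaligned"):
            build_driver_dataset(vm, a, b)


class TestImportanceIteration:
    def test_single_variable_gets_full_importance(self, rng):
        df = _simulate_beta(rng, n=300, betas=[0.9], phi=20.0, n_vars=1)
        res = DriverImportanceModel(df, variables=["d_v0"]).fit(
            n_iter=5, n_points=150, seed=1)
        row = res.table.set_index("variable").loc["d_v0"]
        # with one strong variable the containing models dominate
        assert row["wg"] > 0.9
        assert row["N"] == 5

    def test_true_driver_dominates_importance(self, rng):
        df = _simulate_beta(rng, n=800, betas=[1.2, 0.0, 0.0], phi=20.0)
        res = DriverImportanceModel(df).fit(n_iter=8, n_points=400, seed=2)
        tab = res.table.set_index("variable")
        assert tab["wg"].idxmax() == "d_v0"
        assert tab.loc["d_v0", "N"] == 8
        assert tab.loc["d_v0", "N"] >= 2 * max(tab.loc["d_v1", "N"], tab.loc["d_v2", "N"], 1)
        assert tab.loc["d_v0", "coefficient"] > 0
        assert tab.loc["d_v0", "z"] > 2

    def test_invariance_to_variable_order_and_scaling(self, rng):
        df = _simulate_beta(rng, n=400, betas=[0.8, 0.3], phi=20.0, n_vars=2)
        a = DriverImportanceModel(df, variables=["d_v0", "d_v1"]).fit(
            n_iter=4, n_points=200, seed=3)
        b = DriverImportanceModel(df, variables=["d_v1", "d_v0"]).fit(
            n_iter=4, n_points=200, seed=3)
        ta = a.table.set_index("variable")["wg"]
        tb = b.table.set_index("variable")["wg"]
        for v in ("d_v0", "d_v1"):
            assert ta[v] == pytest.approx(tb[v], abs=1e-9)
        # affine rescaling of a predictor: weights unchanged, coefficient rescales
        df2 = df.copy()
        df2["d_v0"] = df2["d_v0"] * 10.0
        c = DriverImportanceModel(df2, variables=["d_v0", "d_v1"]).fit(
            n_iter=4, n_points=200, seed=3)
        tc = c.table.set_index("variable")
        assert tc.loc["d_v0", "wg"] == pytest.approx(ta["d_v0"], abs=0.02)
        assert tc.loc["d_v0", "coefficient"] == pytest.approx(
            a.table.set_index("variable").loc["d_v0", "coefficient"] / 10.0, rel=0.05)

    def test_weights_within_iteration_sum_to_one(self, rng):
        df = _simulate_beta(rng, n=300, betas=[0.5, 0.0], phi=15.0, n_vars=2)
        res = DriverImportanceModel(df).fit(n_iter=3, n_points=200, seed=4)
        assert (res.iterations["best_weight"] <= 1.0).all()
        # summed wg over complementary subsets: each iteration's weights sum to 1,
        # so wg of any variable is at most 1
        assert (res.table["wg"] <= 1.0 + 1e-9).all()

    def test_requires_enough_records(self, rng):
        df = _simulate_beta(rng, n=100, n_vars=1)
        with pytest.raises(ValueError, match="n_points"):
            DriverImportanceModel(df, variables=["d_v0"]).fit(n_iter=2, n_points=500)
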