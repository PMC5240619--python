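"""Stand-scale inference: correlations, power, model averaging, SAR, summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from divcarbon import stand

ALL_PREDICTORS = ("diversity",) + stand.ENV_PREDICTORS


def brute_force_tau(x, y):
    c = d = 0
    for (xi, yi), (xj, yj) in itertools.combinations(zip(x, y), 2):
        s = (xi - xj) * (yi - yj)
        c += s > 0
        d += s < 0
    return (c - d) / math.comb(len(x), 2)


class TestKendall:
    def test_perfect_concordance(self):
        tau, _ = stand.kendall_tau([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert tau == pytest.approx(1.0)

    def test_antisymmetry(self):
        x = np.array([1, 3, 2, 5, 4])
        y = np.array([2, 1, 4, 3, 5])
        t1, _ = stand.kendall_tau(x, y)
        t2, _ = stand.kendall_tau(-x, y)
        assert t1 == pytest.approx(-t2)

    def test_matches_pair_enumeration(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        tau, _ = stand.kendall_tau(x, y)
        assert tau == pytest.approx(brute_force_tau(x, y), rel=1e-10)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            stand.kendall_tau([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])


class TestPower:
    def test_large_network_detectable_effects(self):
        p = stand.detectable_effect(158)
        assert round(p.r_min, 2) == 0.22
        assert round(p.tau_min, 2) == 0.14

    def test_small_network_detectable_effects(self):
        p = stand.detectable_effect(40)
        assert round(p.r_min, 2) == 0.43
        assert round(p.tau_min, 2) == 0.28

    def test_r_min_shrinks_with_n(self):
        rs = [stand.detectable_effect(n).r_min for n in (10, 50, 200, 1000, 5000)]
        assert all(a > b for a, b in zip(rs, rs[1:]))
        assert rs[-1] < 0.05

    def test_tau_below_r(self):
        p = stand.detectable_effect(100)
        assert 0 < p.tau_min < p.r_min < 1


class TestAllSubsets:
    @staticmethod
    def _world(n=150, seed=0, driver="cwd", coef=0.8, noise=0.5):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.standard_normal((n, len(ALL_PREDICTORS))),
                          columns=ALL_PREDICTORS)
        df["ln_carbon"] = 1.0 + coef * df[driver] + rng.normal(0, noise, n)
        return df

    def test_akaike_weights_closed_form(self):
        w = stand.akaike_weights([100.0, 102.0])
        assert w[0] == pytest.approx(1 / (1 + math.exp(-1)), rel=1e-6)  # 0.7311
        assert w[1] == pytest.approx(math.exp(-1) / (1 + math.exp(-1)), rel=1e-6)

    def test_weights_shift_invariant(self):
        a = np.array([10.0, 11.5, 14.0])
        assert np.allclose(stand.akaike_weights(a), stand.akaike_weights(a + 57.0))

    def test_all_128_models_fitted(self):
        ms = stand.fit_all_subsets(self._world(), "ln_carbon")
        assert len(ms.candidates) == 2 ** 7
        assert ms.candidates["weight"].sum() == pytest.approx(1.0)

    def test_true_driver_dominates(self):
        ms = stand.fit_all_subsets(self._world(), "ln_carbon")
        assert ms.sum_weights["cwd"] > 0.98
        assert ms.averaged_coef["cwd"] == pytest.approx(0.8, abs=0.15)

    def test_null_predictor_shrinks_to_zero(self):
        ms = stand.fit_all_subsets(self._world(), "ln_carbon")
        assert abs(ms.averaged_coef["texture"]) < 0.1

    def test_small_sample_refused(self):
        with pytest.raises(ValueError):
            stand.fit_all_subsets(self._world(n=10), "ln_carbon")

    def test_confidence_set_rule(self):
        ms = stand.fit_all_subsets(self._world(), "ln_carbon", confidence=0.95)
        cand = ms.candidates
        inside = cand[cand["in_set"]]
        # cumulative weight below threshold until the last included model
        assert inside["weight"].cumsum().iloc[-1] >= 0.95
        assert inside["weight"].cumsum().iloc[:-1].lt(0.95).all()


class TestSAR:
    def test_lambda_zero_equals_ols(self):
        df, coords = stand.simulate_sar_field(n=80, lam=0.5, seed=4)
        res = stand.fit_sar_error(df["y"], df[["x1"]], coords, lam=0.0)
        ols = sm.OLS(df["y"], sm.add_constant(df[["x1"]])).fit()
        assert np.allclose(res.params.to_numpy(), ols.params.to_numpy(), atol=1e-8)

    def test_lambda_recovery(self):
        df, coords = stand.simulate_sar_field(n=150, lam=0.6, seed=2)
        res = stand.fit_sar_error(df["y"], df[["x1"]], coords)
        assert abs(res.lam - 0.6) < 0.15
        assert res.params["x1"] == pytest.approx(0.5, abs=0.2)

    def test_ml_dominates_ols(self):
        df, coords = stand.simulate_sar_field(n=100, lam=0.5, seed=7)
        res = stand.fit_sar_error(df["y"], df[["x1"]], coords)
        assert res.llf >= res.llf_ols - 1e-9

    def test_singular_design_rejected(self):
        df, coords = stand.simulate_sar_field(n=50, lam=0.0, seed=0)
        df["x2"] = df["x1"]
        with pytest.raises(np.linalg.LinAlgError):
            stand.fit_sar_error(df["y"], df[["x1", "x2"]], coords)


class TestContinentSummaries:
    @staticmethod
    def _groups(shift=0.0, seed=0, n=40):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "continent": ["A"] * n + ["B"] * n + ["C"] * n,
            "carbon": np.concatenate([
                rng.normal(150, 20, n), rng.normal(150, 20, n),
                rng.normal(150 + shift, 20, n),
            ]),
        })

    def test_same_distribution_shares_letter(self):
        out = stand.continent_summaries(self._groups(0.0), "carbon",
                                        transform="log", n_boot=300, seed=1)
        assert out["tukey_group"].nunique() == 1

    def test_shifted_group_gets_distinct_letter(self):
        out = stand.continent_summaries(self._groups(80.0), "carbon",
                                        transform="log", n_boot=300, seed=1)
        c_letter = out.loc[out["continent"] == "C", "tukey_group"].iloc[0]
        a_letter = out.loc[out["continent"] == "A", "tukey_group"].iloc[0]
        assert set(c_letter).isdisjoint(set(a_letter))

    def test_ci_brackets_mean(self):
        out = stand.continent_summaries(self._groups(30.0), "carbon",
                                        n_boot=300, seed=2)
        assert ((out["ci_lo"] <= out["mean"]) & (out["mean"] <= out["ci_hi"])).all()

    def test_bootstrap_ci_coverage(self):
        # nominal 95% CI for the mean of N(0,1), n=100
        rng = np.random.default_rng(11)
        hits = 0
        n_seeds = 200
        for _ in range(n_seeds):
            v = rng.standard_normal(100)
            boot = rng.choice(v, size=(500, 100), replace=True).mean(axis=1)
            lo, hi = np.percentile(boot, [2.5, 97.5])
            hits += lo <= 0 <= hi
        assert 0.90 <= hits / n_seeds <= 0.99


class TestStructuralCorrelates:
    def test_schema_and_allometric_link(self, small_world, resolved_stems, subplot_table):
        from divcarbon import alpha, carbon
        cplot = carbon.aggregate_carbon(resolved_stems, small_world.plots, scale="plot")
        dplot = alpha.diversity_profiles(small_world.stems, scale="plot")
        out = stand.structural_correlates(cplot, dplot)
        assert len(out) == 8
        ba_row = out[(out["response"] == "carbon") & (out["attribute"] == "basal_area")]
        assert ba_row["tau"].iloc[0] > 0  # carbon is built from basal area
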