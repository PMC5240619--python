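"""Trait structure, null sampling curves, occurrence models."""

import math

import numpy as np
import pandas as pd
import pytest

from divcarbon import mechanisms


def _stems(rows):
    return pd.DataFrame(rows, columns=["plot_id", "subplot_id", "taxon", "family",
                                       "genus", "species", "id_level", "diameter_cm"])


def _traits(wd, maxd):
    n = len(wd)
    return pd.DataFrame({
        "taxon": [f"s{i}" for i in range(n)],
        "genus": [f"g{i}" for i in range(n)],
        "family": ["f0"] * n,
        "rel_freq": np.full(n, 1.0 / n),
        "wood_density": wd,
        "max_diameter": maxd,
    })


class TestTraitSummaries:
    def test_weighted_mean_arithmetic(self):
        # basal areas proportional to D^2: choose D so BA ratio is 1:3
        traits = _traits([0.5, 0.9, 0.7], [50.0, 80.0, 60.0])
        stems = _stems([
            ("P1", 1, "s0", "f0", "g0", "s0", "species", 20.0),
            ("P1", 1, "s1", "f0", "g1", "s1", "species", 20.0 * math.sqrt(3)),
        ])
        out = mechanisms.trait_summaries(stems, traits, scale="plot")
        assert out["cwm_wd"].iloc[0] == pytest.approx(0.25 * 0.5 + 0.75 * 0.9)

    def test_monoculture_has_zero_dispersion(self):
        traits = _traits([0.5, 0.9], [50.0, 80.0])
        stems = _stems([("P1", 1, "s0", "f0", "g0", "s0", "species", d)
                        for d in (15.0, 25.0, 40.0)])
        out = mechanisms.trait_summaries(stems, traits, scale="plot")
        assert out["fdis"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["sd_wd"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_row_order_invariance(self, small_world):
        ts1 = mechanisms.trait_summaries(small_world.stems, small_world.traits, scale="plot")
        shuffled = small_world.stems.sample(frac=1.0, random_state=9)
        ts2 = mechanisms.trait_summaries(shuffled, small_world.traits, scale="plot")
        merged = ts1.merge(ts2, on="unit_id", suffixes=("_a", "_b"))
        assert np.allclose(merged["fdis_a"], merged["fdis_b"])
        assert np.allclose(merged["cwm_wd_a"], merged["cwm_wd_b"])

    def test_threshold_flags(self):
        traits = _traits([0.5, 0.85], [50.0, 90.0])
        stems = _stems([
            ("P1", 1, "s0", "f0", "g0", "s0", "species", 20.0),
            ("P2", 1, "s1", "f0", "g1", "s1", "species", 20.0),
        ])
        out = mechanisms.trait_summaries(stems, traits, scale="plot").set_index("plot_id")
        assert not out.loc["P1", "has_large"] and not out.loc["P1", "has_dense"]
        assert out.loc["P2", "has_large"] and out.loc["P2", "has_dense"]


class TestNullCurve:
    pool = _traits(
        wd=np.concatenate([np.full(20, 0.9), np.full(80, 0.5)]),
        maxd=np.concatenate([np.full(20, 90.0), np.full(80, 40.0)]),
    )

    def test_single_draw(self):
        c = mechanisms.null_sampling_curve(self.pool, richness_grid=[1])
        assert c.p_expected[0] == pytest.approx(20 / 100)

    def test_exact_combinatorial_value(self):
        c = mechanisms.null_sampling_curve(self.pool, richness_grid=[5])
        expect = 1 - math.comb(80, 5) / math.comb(100, 5)
        assert c.p_expected[0] == pytest.approx(expect, rel=1e-10)
        assert expect == pytest.approx(0.6807, abs=2e-4)

    def test_pigeonhole_saturation(self):
        c = mechanisms.null_sampling_curve(self.pool, richness_grid=[81, 90, 100])
        assert np.all(c.p_expected == 1.0)

    def test_monotone_in_richness(self):
        c = mechanisms.null_sampling_curve(self.pool)
        assert np.all(np.diff(c.p_expected) >= -1e-12)

    def test_frequency_mode_agrees_when_frequencies_equal(self):
        grid = [1, 5, 10, 20]
        uni = mechanisms.null_sampling_curve(self.pool, richness_grid=grid)
        n_rep = 8000
        freq = mechanisms.null_sampling_curve(self.pool, richness_grid=grid,
                                              mode="frequency", n_rep=n_rep, seed=3)
        for pu, pf in zip(uni.p_expected, freq.p_expected):
            se = math.sqrt(pu * (1 - pu) / n_rep)
            assert abs(pu - pf) <= max(2 * se, 0.012)

    def test_frequency_mode_monotone_within_mc_error(self):
        freq = mechanisms.null_sampling_curve(
            self.pool, richness_grid=[2, 10, 30, 60], mode="frequency",
            n_rep=4000, seed=1)
        assert np.all(np.diff(freq.p_expected) >= -2 * math.sqrt(0.25 / 4000))

    def test_threshold_must_split_pool(self):
        with pytest.raises(ValueError):
            mechanisms.null_sampling_curve(self.pool, threshold=1000.0)


class TestOccurrenceModel:
    def test_saturated_outcome_flagged(self):
        df = pd.DataFrame({"has_large": [True] * 100, "richness": range(100),
                           "plot_id": np.repeat(range(25), 4)})
        out = mechanisms.occurrence_glmm(df)
        assert out["saturated"] and out["rate"] == 1.0

    def test_richness_driven_sampling_recovered(self):
        # the generator samples communities from the pool, so richer subplots
        # are likelier to include a potentially large species
        from divcarbon import synthgen
        from divcarbon.config import SimConfig
        cfg = SimConfig(n_plots_per_continent=22, continents=("SouthAmerica",),
                        pool_size=250, mean_richness=80.0, logseries_alpha=60.0,
                        seed=77)
        data = synthgen.make_plots(cfg, synthgen.make_pool(cfg, "SouthAmerica"))
        ts = mechanisms.trait_summaries(data.stems, data.traits, scale="subplot")
        out = mechanisms.occurrence_glmm(ts)
        assert out["saturated"] or (out["slope"] > 0 and out["p"] < 0.05)


class TestCwmRegressions:
    def test_constructed_driver_recovered_and_schema(self):
        rng = np.random.default_rng(0)
        n = 120
        ts = pd.DataFrame({
            "unit_id": [f"U{i}" for i in range(n)],
            "plot_id": [f"U{i}" for i in range(n)],
            "cwm_wd": rng.uniform(0.4, 0.9, n),
            "cwm_maxd": rng.uniform(40, 90, n),
            "sd_wd": rng.uniform(0, 0.2, n),
            "fdis": rng.uniform(0, 2, n),
        })
        carbon = pd.DataFrame({
            "unit_id": ts["unit_id"],
            "carbon": np.exp(3.0 + 2.0 * ts["cwm_wd"] + rng.normal(0, 0.1, n)),
        })
        out = mechanisms.cwm_fd_regressions(carbon, ts, scale="plot")
        assert len(out) == 4  # one model per trait metric
        wd_row = out[out["predictor"] == "cwm_wd"].iloc[0]
        assert wd_row["coef"] > 0 and wd_row["p"] < 1e-6

    def test_permuted_predictor_is_null(self):
        rng = np.random.default_rng(1)
        n = 150
        ts = pd.DataFrame({
            "unit_id": [f"U{i}" for i in range(n)],
            "plot_id": [f"U{i}" for i in range(n)],
            "cwm_wd": rng.uniform(0.4, 0.9, n),
            "cwm_maxd": rng.uniform(40, 90, n),
            "sd_wd": rng.uniform(0, 0.2, n),
            "fdis": rng.uniform(0, 2, n),
        })
        carbon = pd.DataFrame({"unit_id": ts["unit_id"],
                               "carbon": np.exp(rng.normal(5, 0.3, n))})
        out = mechanisms.cwm_fd_regressions(carbon, ts, scale="plot")
        assert (out["p"] > 0.001).all()
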