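"""Allometry and carbon aggregation."""

import math

import numpy as np
import pandas as pd
import pytest

from divcarbon import carbon
from divcarbon.config import HeightModel


@pytest.fixture
def model():
    return HeightModel("X", a=50.0, b=0.03, c=0.8)


class TestHeight:
    def test_closed_form(self, model):
        # 50 * (1 - exp(-0.03 * 30**0.8)), high-precision reference
        assert carbon.estimate_height(30.0, model) == pytest.approx(18.30443106992564, rel=1e-12)

    def test_monotone_in_diameter(self, model):
        assert carbon.estimate_height(40.0, model) > carbon.estimate_height(20.0, model)

    def test_asymptote(self):
        steep = HeightModel("X", a=50.0, b=500.0, c=0.8)
        for d in (10.0, 30.0, 120.0):
            assert carbon.estimate_height(d, steep) == pytest.approx(50.0, abs=1e-9)

    def test_positive_coefficients_enforced(self):
        with pytest.raises(ValueError):
            HeightModel("X", a=50.0, b=-0.1, c=0.8)


class TestStemAGB:
    def test_reference_value(self):
        # 0.0673 * (0.6 * 30^2 * 25)^0.976, checked by 30-digit arithmetic
        assert carbon.stem_agb(0.6, 30.0, 25.0) == pytest.approx(723.1373980850497, rel=1e-12)

    def test_unit_argument(self):
        # rho * D^2 * H = 1 isolates the coefficient
        assert carbon.stem_agb(1.0, 1.0, 1.0) == pytest.approx(0.0673)

    def test_power_law_scaling_in_density(self):
        ratio = carbon.stem_agb(1.2, 30.0, 25.0) / carbon.stem_agb(0.6, 30.0, 25.0)
        assert ratio == pytest.approx(2**0.976, rel=1e-12)

    @pytest.mark.parametrize("arg", ["rho", "d", "h"])
    def test_strictly_increasing(self, arg):
        base = dict(wood_density=0.6, diameter=30.0, height=25.0)
        hi = dict(base)
        key = {"rho": "wood_density", "d": "diameter", "h": "height"}[arg]
        hi[key] = base[key] * 1.01
        assert carbon.stem_agb(**hi) > carbon.stem_agb(**base)

    def test_missing_density_rejected(self):
        with pytest.raises(ValueError):
            carbon.stem_agb(np.nan, 30.0, 25.0)


def _stem(plot, sp, genus, fam, d=20.0, sub=1, level="species"):
    return {"plot_id": plot, "subplot_id": sub, "taxon": sp or genus or fam,
            "family": fam, "genus": genus, "species": sp,
            "id_level": level, "diameter_cm": d}


class TestResolveWoodDensity:
    traits = pd.DataFrame({
        "taxon": ["sp1", "sp2", "sp3"],
        "genus": ["g1", "g1", "g2"],
        "family": ["f1", "f1", "f1"],
        "wood_density": [0.5, 0.7, 0.9],
        "max_diameter": [80.0, 60.0, 50.0],
    })

    def test_species_match(self):
        stems = pd.DataFrame([_stem("P1", "sp1", "g1", "f1")])
        out = carbon.resolve_wood_density(stems, self.traits)
        assert out["wood_density"].iloc[0] == 0.5
        assert out["wd_source"].iloc[0] == "species"

    def test_genus_mean(self):
        stems = pd.DataFrame([_stem("P1", None, "g1", "f1", level="genus")])
        out = carbon.resolve_wood_density(stems, self.traits)
        assert out["wood_density"].iloc[0] == pytest.approx(0.6)  # mean(0.5, 0.7)
        assert out["wd_source"].iloc[0] == "genus"

    def test_family_then_plot_fallback(self):
        stems = pd.DataFrame([
            _stem("P1", "sp1", "g1", "f1"),
            _stem("P1", "sp3", "g2", "f1", d=30.0),
            _stem("P1", None, None, "f9", level="family"),  # unknown family -> plot mean
        ])
        out = carbon.resolve_wood_density(stems, self.traits)
        assert out["wood_density"].iloc[2] == pytest.approx((0.5 + 0.9) / 2)
        assert out["wd_source"].iloc[2] == "plot"

    def test_unresolvable_plot_errors(self):
        stems = pd.DataFrame([_stem("P1", None, None, None, level="unidentified")])
        with pytest.raises(ValueError, match="P1"):
            carbon.resolve_wood_density(stems, self.traits)


class TestAggregate:
    plots = pd.DataFrame({
        "plot_id": ["P1"], "lat": [0.0], "lon": [0.0],
        "area_ha": [1.0], "continent": ["SouthAmerica"],
    })

    def _resolved(self, stems):
        out = stems.copy()
        out["wood_density"] = 0.6
        out["height_m"] = 25.0
        out["agb_kg"] = carbon.stem_agb(0.6, out["diameter_cm"], 25.0)
        return out

    def test_single_stem_reference_carbon(self):
        stems = self._resolved(pd.DataFrame([_stem("P1", "sp1", "g1", "f1", d=30.0)]))
        out = carbon.aggregate_carbon(stems, self.plots, scale="plot")
        assert out["carbon"].iloc[0] == pytest.approx(0.471 * 0.7231373980850497, rel=1e-9)
        assert out["carbon"].iloc[0] / out["agb"].iloc[0] == pytest.approx(0.471)

    def test_equal_basal_areas_give_zero_gini(self):
        stems = self._resolved(pd.DataFrame(
            [_stem("P1", "sp1", "g1", "f1", d=20.0, sub=s) for s in (1, 2, 3)]))
        out = carbon.aggregate_carbon(stems, self.plots, scale="plot")
        assert out["size_inequality"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_area_normalisation(self):
        small = self.plots.assign(area_ha=0.96)
        stems = self._resolved(pd.DataFrame([_stem("P1", "sp1", "g1", "f1", d=30.0)]))
        ref = carbon.aggregate_carbon(stems, self.plots, scale="plot")["carbon"].iloc[0]
        out = carbon.aggregate_carbon(stems, small, scale="plot")["carbon"].iloc[0]
        assert out == pytest.approx(ref / 0.96)

    def test_empty_subplots_flagged(self):
        stems = self._resolved(pd.DataFrame([_stem("P1", "sp1", "g1", "f1", sub=1)]))
        out = carbon.aggregate_carbon(stems, self.plots, scale="subplot")
        assert len(out) == 25
        assert out["empty_unit"].sum() == 24
        assert (out.loc[out["empty_unit"], "carbon"] == 0).all()

    def test_plot_carbon_is_area_weighted_subplot_mean(self, small_world, resolved_stems):
        plot = carbon.aggregate_carbon(resolved_stems, small_world.plots, scale="plot")
        sub = carbon.aggregate_carbon(resolved_stems, small_world.plots, scale="subplot")
        merged = sub.groupby("plot_id").apply(
            lambda g: np.average(g["carbon"], weights=g["area_ha"]),
            include_groups=False,
        )
        for pid, expect in merged.items():
            got = plot.loc[plot["plot_id"] == pid, "carbon"].iloc[0]
            assert got == pytest.approx(expect, rel=1e-9)

    def test_subplot_stems_and_area_conserve_plot_totals(self, small_world, resolved_stems):
        plot = carbon.aggregate_carbon(resolved_stems, small_world.plots, scale="plot")
        sub = carbon.aggregate_carbon(resolved_stems, small_world.plots, scale="subplot")
        by_plot = sub.groupby("plot_id")[["n_stems", "area_ha"]].sum()
        for pid, row in by_plot.iterrows():
            ref = plot.loc[plot["plot_id"] == pid].iloc[0]
            assert row["n_stems"] == ref["n_stems"]
            assert row["area_ha"] == pytest.approx(ref["area_ha"])


def test_gini_known_values():
    assert carbon.gini([1, 1, 1, 1]) == pytest.approx(0.0, abs=1e-12)
    # one owner holds everything: Gini -> (n-1)/n
    assert carbon.gini([0, 0, 0, 10]) == pytest.approx(0.75)
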