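"""Shared fixtures: small synthetic worlds reused across test modules."""

from __future__ import annotations

import pandas as pd
import pytest

from divcarbon import alpha, carbon, synthgen
from divcarbon.config import SimConfig


@pytest.fixture(scope="session")
def small_world() -> synthgen.SyntheticDataset:
    """One-continent, 15-plot inventory with the default carbon coupling."""
    cfg = SimConfig(
        n_plots_per_continent=15,
        continents=("SouthAmerica",),
        pool_size=250,
        mean_richness=80.0,
        logseries_alpha=60.0,
        seed=1234,
    )
    return synthgen.generate(cfg)


@pytest.fixture(scope="session")
def resolved_stems(small_world):
    st = carbon.resolve_wood_density(small_world.stems, small_world.traits)
    return carbon.add_height_and_agb(st, small_world.plots)


@pytest.fixture(scope="session")
def subplot_table(small_world, resolved_stems) -> pd.DataFrame:
    """Subplot-scale carbon joined with observed richness."""
    csub = carbon.aggregate_carbon(resolved_stems, small_world.plots, scale="subplot")
    dsub = alpha.diversity_profiles(small_world.stems, scale="subplot")
    return csub.merge(
        dsub[["plot_id", "subplot_id", "richness"]],
        on=["plot_id", "subplot_id"], how="left",
    )


def make_coupled_world(beta_true: float, n_plots: int, seed: int,
                       noise_sd: float = 0.25, **kw) -> pd.DataFrame:
    """Generate a world and return its subplot carbon/richness table."""
    cfg = SimConfig(
        n_plots_per_continent=n_plots,
        continents=("SouthAmerica",),
        beta_true=beta_true,
        noise_sd=noise_sd,
        seed=seed,
        **kw,
    )
    data = synthgen.generate(cfg)
    st = carbon.resolve_wood_density(data.stems, data.traits)
    st = carbon.add_height_and_agb(st, data.plots)
    csub = carbon.aggregate_carbon(st, data.plots, scale="subplot")
    dsub = alpha.diversity_profiles(data.stems, scale="subplot")
    return csub.merge(
        dsub[["plot_id", "subplot_id", "richness"]],
        on=["plot_id", "subplot_id"], how="left",
    )
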