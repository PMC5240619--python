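"""Stem-level allometry and per-unit-area aboveground carbon aggregation.

Each stem's aboveground biomass follows the pantropical moist-forest
allometry

    AGB [kg] = 0.0673 * (rho * D**2 * H) ** 0.976

with wood density rho (g cm^-3) resolved taxonomically, diameter D (cm,
>= 10 at breast height or above buttresses) and height H (m) predicted
from regional Weibull height-diameter models. Biomass converts to carbon
with the mean tropical-angiosperm carbon fraction of 47.1%. Aggregation
yields stand structure alongside carbon: basal area, basal-area-weighted
mean wood density, stem density and the Gini coefficient of stem basal
areas (size inequality).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CARBON_FRACTION, DEFAULT_HEIGHT_MODELS, SUBPLOT_AREA_HA, HeightModel

AGB_COEF = 0.0673
AGB_EXP = 0.976

__all__ = [
    "estimate_height",
    "stem_agb",
    "resolve_wood_density",
    "add_height_and_agb",
    "aggregate_carbon",
    "gini",
    "HeightModel",
]


def estimate_height(diameter, model: HeightModel):
    """Predict stem height (m) from diameter (cm) with a Weibull model.

    H = a * (1 - exp(-b * D**c)); monotone increasing in D with asymptote a.
    """
    d = np.asarray(diameter, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    h = model.a * (1.0 - np.exp(-model.b * np.power(d, model.c)))
    return h if h.ndim else float(h)


def stem_agb(wood_density, diameter, height):
    """Aboveground biomass of a stem in kg from rho (g cm^-3), D (cm), H (m)."""
    rho = np.asarray(wood_density, dtype=float)
    d = np.asarray(diameter, dtype=float)
    h = np.asarray(height, dtype=float)
    if np.any(~np.isfinite(rho)) or np.any(rho <= 0):
        raise ValueError("wood density must be resolved and positive")
    if np.any(~np.isfinite(h)) or np.any(h <= 0):
        raise ValueError("height must be estimated and positive")
    agb = AGB_COEF * np.power(rho * d * d * h, AGB_EXP)
    return agb if agb.ndim else float(agb)


def resolve_wood_density(stems: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Attach wood density to every stem by taxonomic fallback.

    Resolution order: exact species match in the trait table, else the genus
    mean, else the family mean, else the mean of already-resolved stems in
    the same plot. The provenance of each value is recorded in `wd_source`
    ({species, genus, family, plot}).

    Raises if any plot ends with zero resolvable stems.
    """
    out = stems.copy()
    sp_wd = traits.set_index("taxon")["wood_density"]
    genus_wd = traits.groupby("genus")["wood_density"].mean()
    family_wd = traits.groupby("family")["wood_density"].mean()

    wd = out["species"].map(sp_wd)
    source = pd.Series(np.where(wd.notna(), "species", ""), index=out.index)

    m = wd.isna() & out["genus"].notna()
    wd.loc[m] = out.loc[m, "genus"].map(genus_wd)
    source.loc[m & wd.notna()] = "genus"

    m = wd.isna() & out["family"].notna()
    wd.loc[m] = out.loc[m, "family"].map(family_wd)
    source.loc[m & wd.notna()] = "family"

    if wd.isna().any():
        plot_mean = wd.groupby(out["plot_id"]).transform("mean")
        m = wd.isna()
        wd.loc[m] = plot_mean.loc[m]
        source.loc[m & wd.notna()] = "plot"

    if wd.isna().any():
        bad = out.loc[wd.isna(), "plot_id"].unique().tolist()
        raise ValueError(f"no resolvable wood density in plot(s): {bad}")

    out["wood_density"] = wd.astype(float)
    out["wd_source"] = source
    return out


def add_height_and_agb(
    stems: pd.DataFrame,
    plots: pd.DataFrame,
    height_models=DEFAULT_HEIGHT_MODELS,
) -> pd.DataFrame:
    """Add height (m) and agb_kg columns using each plot's continental model."""
    out = stems.copy()
    continent = out["plot_id"].map(plots.set_index("plot_id")["continent"])
    if continent.isna().any():
        missing = out.loc[continent.isna(), "plot_id"].unique().tolist()
        raise KeyError(f"stems reference unknown plots: {missing}")
    h = np.empty(len(out))
    for cont, idx in out.groupby(continent).groups.items():
        model = height_models[cont]
        h[out.index.get_indexer(idx)] = estimate_height(
            out.loc[idx, "diameter_cm"].to_numpy(), model
        )
    out["height_m"] = h
    out["agb_kg"] = stem_agb(
        out["wood_density"].to_numpy(), out["diameter_cm"].to_numpy(), h
    )
    return out


def gini(values) -> float:
    """Gini coefficient of a non-negative sample (0 = perfect equality)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        return float("nan")
    total = x.sum()
    if total == 0:
        return 0.0
    ranks = np.arange(1, n + 1)
    return float((2.0 * np.sum(ranks * x) / (n * total)) - (n + 1.0) / n)


def aggregate_carbon(
    stems: pd.DataFrame,
    plots: pd.DataFrame,
    scale: str = "plot",
    subplots_per_plot: int | None = None,
) -> pd.DataFrame:
    """Aggregate resolved stems to per-unit-area carbon and structure.

    scale="plot" yields one row per plot; scale="subplot" one row per
    (plot, subplot) cell of area plot_area / n_subplots, including empty
    cells (carbon 0, flagged in `empty_unit`). All per-area quantities are
    normalised by the unit's area in hectares:

        carbon [Mg C ha^-1] = 0.471 * sum(AGB kg) / 1000 / area
        basal_area [m^2 ha^-1] = sum(pi * (D/200)**2) / area
    """
    if scale not in ("plot", "subplot"):
        raise ValueError("scale must be 'plot' or 'subplot'")
    required = {"wood_density", "agb_kg", "height_m"}
    if not required <= set(stems.columns):
        raise ValueError("stems must be resolved (resolve_wood_density, add_height_and_agb)")

    meta = plots.set_index("plot_id")
    st = stems.copy()
    st["ba_m2"] = np.pi * (st["diameter_cm"] / 200.0) ** 2

    rows = []
    for plot_id, grp in st.groupby("plot_id", sort=True):
        area = float(meta.loc[plot_id, "area_ha"])
        if scale == "plot":
            rows.append(_unit_row(str(plot_id), plot_id, None, grp, area))
        else:
            n_sub = subplots_per_plot or int(round(area / SUBPLOT_AREA_HA))
            sub_area = area / n_sub
            by_sub = dict(tuple(grp.groupby("subplot_id")))
            for s in range(1, n_sub + 1):
                sub = by_sub.get(s, grp.iloc[0:0])
                rows.append(_unit_row(f"{plot_id}:{s:02d}", plot_id, s, sub, sub_area))
    out = pd.DataFrame(rows)
    return out


def _unit_row(unit_id: str, plot_id, subplot_id, grp: pd.DataFrame, area: float) -> dict:
    n = len(grp)
    if n == 0:
        return {
            "unit_id": unit_id, "plot_id": plot_id, "subplot_id": subplot_id,
            "area_ha": area, "n_stems": 0, "agb": 0.0, "carbon": 0.0,
            "basal_area": 0.0, "ba_weighted_wd": np.nan, "stem_density": 0.0,
            "size_inequality": np.nan, "empty_unit": True,
        }
    agb_mg = grp["agb_kg"].sum() / 1000.0
    ba = grp["ba_m2"].to_numpy()
    return {
        "unit_id": unit_id, "plot_id": plot_id, "subplot_id": subplot_id,
        "area_ha": area, "n_stems": n,
        "agb": agb_mg / area,
        "carbon": CARBON_FRACTION * agb_mg / area,
        "basal_area": ba.sum() / area,
        "ba_weighted_wd": float(np.average(grp["wood_density"], weights=ba)),
        "stem_density": n / area,
        "size_inequality": gini(ba),
        "empty_unit": False,
    }
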