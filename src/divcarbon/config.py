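"""Configuration objects for simulation and pipeline runs.

All tunable parameters of the synthetic-inventory generator and of the
analysis stages live here, with defaults chosen to emulate lowland
closed-canopy humid tropical forest inventory networks: 1 ha plots split
into 25 contiguous 0.04 ha subplots, 400-700 stems (>=10 cm diameter) per
hectare, continental species pools with log-series-like abundance
structure, and climate restricted to MAT >= 20 degC and MAP >= 1300 mm.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

CARBON_FRACTION = 0.471  # mean carbon fraction of aboveground biomass, tropical angiosperms
MIN_DIAMETER_CM = 10.0   # inventory census threshold (d.b.h.)
SUBPLOT_AREA_HA = 0.04   # 20 m x 20 m grid cell

CONTINENTS = ("SouthAmerica", "Africa", "Asia")


@dataclass(frozen=True)
class HeightModel:
    """Regional Weibull height-diameter model H = a * (1 - exp(-b * D**c)).

    H in metres, D in cm. a is the asymptotic height; b, c control the
    approach to the asymptote. All coefficients must be positive.
    """

    continent: str
    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("Weibull height coefficients must be positive")


#: Shipped regional defaults (asymptote a in m). Overridable via RunConfig;
#: only internal consistency matters when analysing synthetic inventories.
DEFAULT_HEIGHT_MODELS: Mapping[str, HeightModel] = {
    "SouthAmerica": HeightModel("SouthAmerica", a=42.6, b=0.0482, c=0.831),
    "Africa": HeightModel("Africa", a=50.5, b=0.0471, c=0.812),
    "Asia": HeightModel("Asia", a=57.1, b=0.0332, c=0.847),
}

#: Latitude/longitude anchor of each simulated continental block (degrees).
CONTINENT_ORIGINS: Mapping[str, tuple[float, float]] = {
    "SouthAmerica": (-5.0, -65.0),
    "Africa": (0.0, 20.0),
    "Asia": (2.0, 113.0),
}


@dataclass
class EnvFieldSpec:
    """Gaussian-random-field spec for one environmental covariate.

    mean/sd on the covariate's own scale; range_km is the e-folding range of
    the exponential spatial covariance; lo/hi clip to the study domain.
    """

    mean: float
    sd: float
    range_km: float = 300.0
    lo: float | None = None
    hi: float | None = None


def default_env_fields() -> dict[str, EnvFieldSpec]:
    # CWD <= 0 by convention (more negative = stronger water deficit).
    return {
        "cwd": EnvFieldSpec(mean=-180.0, sd=130.0, hi=0.0),
        "mat": EnvFieldSpec(mean=25.5, sd=1.4, lo=20.0),
        "map": EnvFieldSpec(mean=2300.0, sd=450.0, lo=1300.0),
        "teb": EnvFieldSpec(mean=8.0, sd=4.0, lo=0.5),
        "cn": EnvFieldSpec(mean=12.0, sd=3.0, lo=4.0),
        "texture": EnvFieldSpec(mean=5.0, sd=2.0, lo=1.0, hi=9.0),
    }


@dataclass
class SimConfig:
    """Ground-truth parameters of the synthetic inventory generator.

    The generator emulates three continental networks of 1 ha plots. The
    within-subplot diversity->carbon coupling beta_true is the key ground
    truth: expected ln(subplot carbon per ha) is

        a0 + plot effect + env effects + beta_true*ln(richness)
           + gamma_stems*(ln stems - plot mean ln stems) + N(0, noise_sd)

    so beta_true = 0 defines a null world with no diversity effect at any
    scale.
    """

    n_plots_per_continent: int = 50
    continents: Sequence[str] = CONTINENTS
    plot_area: float = 1.0
    subplots_per_plot: int = 25
    stems_per_ha_range: tuple[int, int] = (400, 700)
    pool_size: int = 1000
    # Log-series shape of the regional pool abundance distribution; Africa low
    # to emulate its consistently low alpha diversity.
    logseries_alpha: Mapping[str, float] | float = field(
        default_factory=lambda: {"SouthAmerica": 120.0, "Africa": 35.0, "Asia": 130.0}
    )
    # Target expected per-plot species richness (sets species occupancies).
    mean_richness: Mapping[str, float] | float = field(
        default_factory=lambda: {"SouthAmerica": 150.0, "Africa": 75.0, "Asia": 160.0}
    )
    decay_rate: float = 0.001          # km^-1 decay of expected Sorensen similarity
    near_similarity_corr: float = 0.5  # latent presence correlation between adjacent plots
    occupancy_exponent: float = 0.4    # q ~ rel_freq**exponent occupancy-frequency law
    occupancy_max: float = 0.9         # ubiquity cap: no species occupies > this share of plots
    bbox_km: tuple[float, float] = (500.0, 500.0)
    env_fields: dict[str, EnvFieldSpec] = field(default_factory=default_env_fields)
    env_effects: Mapping[str, float] = field(default_factory=lambda: {"cwd": 0.15})
    beta_true: float = 0.096           # ln C per ln S at 0.04 ha, the coupling under study
    gamma_stems: float = 1.0           # ln C per centred ln(stem count)
    noise_sd: float = 0.25             # lognormal subplot carbon noise
    plot_effect_sd: float = 0.30       # between-plot lognormal carbon variation
    carbon_base: float = 165.0         # median subplot carbon (Mg C ha^-1) at mean covariates
    # Taxonomic identification: per-plot fraction of stems identified to
    # species ~ Beta(mean*kappa, (1-mean)*kappa); remainder split below.
    ident_species_mean: float = 0.90
    ident_kappa: float = 80.0
    ident_rest_split: tuple[float, float, float] = (0.70, 0.15, 0.15)  # genus, family, unidentified
    # Species traits.
    wd_mean: float = 0.60
    wd_sd: float = 0.15
    wd_bounds: tuple[float, float] = (0.20, 1.15)
    ln_maxd_mean: float = 3.69   # ln(40 cm): large-statured species are a minority
    ln_maxd_sd: float = 0.45
    maxd_bounds: tuple[float, float] = (20.0, 250.0)
    pareto_shape: float = 2.2    # stem diameter tail index (truncated at 10 cm)
    seed: int = 0

    def per_continent(self, value, continent: str) -> float:
        if isinstance(value, Mapping):
            return float(value[continent])
        return float(value)

    def validate(self) -> None:
        if self.pool_size < 2:
            raise ValueError("pool_size must be >= 2")
        if self.n_plots_per_continent < 1:
            raise ValueError("n_plots_per_continent must be positive")
        if self.subplots_per_plot < 1:
            raise ValueError("subplots_per_plot must be positive")
        lo, hi = self.stems_per_ha_range
        if lo <= 0 or hi < lo:
            raise ValueError("stems_per_ha_range must be a positive interval")
        if min(self.bbox_km) <= 0:
            raise ValueError("degenerate bounding box")
        for cont in self.continents:
            if self.per_continent(self.logseries_alpha, cont) <= 0:
                raise ValueError("logseries_alpha must be positive")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (see workflow.run_all)."""

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "divcarbon_run"
    seed: int = 0
    n_boot: int = 10000
    min_ident_for_beta: float = 0.90
    rarefy_to: int = 300
    diversity_metric: str = "fishers_alpha"
    large_diameter_threshold: float = 70.0
    dense_wood_threshold: float = 0.8
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "simulate": True,
            "carbon": True,
            "diversity": True,
            "beta": True,
            "stand": True,
            "within": True,
            "mechanisms": True,
        }
    )


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, list):
        return [_to_plain(v) for v in obj]
    return obj


def dump_config(cfg: RunConfig | SimConfig) -> str:
    """Serialize a config to YAML (lossless round trip via load_config)."""
    return yaml.safe_dump(_to_plain(cfg), sort_keys=True)


def _sim_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "env_fields" in d and d["env_fields"] is not None:
        d["env_fields"] = {k: EnvFieldSpec(**v) for k, v in d["env_fields"].items()}
    for key in ("stems_per_ha_range", "bbox_km", "ident_rest_split", "wd_bounds", "maxd_bounds"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    if "continents" in d:
        d["continents"] = tuple(d["continents"])
    return SimConfig(**d)


def load_config(text: str) -> RunConfig:
    """Parse YAML produced by dump_config (or hand-written) into a RunConfig."""
    raw = yaml.safe_load(io.StringIO(text)) or {}
    if "sim" in raw:  # full RunConfig document
        sim = _sim_from_dict(raw.pop("sim"))
        return RunConfig(sim=sim, **raw)
    return RunConfig(sim=_sim_from_dict(raw))
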