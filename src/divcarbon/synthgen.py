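"""Synthetic continental forest-inventory generator with known ground truth.

The generator emulates networks of 1 ha plots (25 contiguous 0.04 ha
subplots each) sampled from continental species pools so that every
downstream stage of the analysis can be validated by parameter recovery:

* Pool structure: per-species abundances drawn from a log-series with the
  configured Fisher alpha, giving realistic rank-abundance skew; wood
  density from a truncated normal and ln(maximum diameter) from a normal.
* Spatial turnover: species presence/absence across plots follows a
  Gaussian-copula threshold model. Per-species occupancy q_s comes from
  the pool relative frequencies (scaled so expected plot richness matches
  the configured target), and the pairwise latent correlation is set by
  tetrachoric inversion so that the EXPECTED pairwise Sorensen similarity
  between plots at distance d equals s0 * exp(-decay_rate * d), until it
  floors at the chance-overlap baseline of independent communities.
* Stem sizes: truncated Pareto diameters (minimum 10 cm, capped at the
  species' maximum diameter) so large stems dominate biomass.
* Environment: Gaussian random fields with exponential spatial covariance
  sampled at plot locations, clipped to the humid lowland tropical domain.
* Carbon coupling: subplot stem diameters are rescaled so that expected
  ln(subplot carbon) contains a configurable beta_true * ln(richness)
  term - the ground truth that the within-plot pipeline must recover.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri, owens_t
from scipy.stats import logser, truncnorm

from .carbon import add_height_and_agb, resolve_wood_density
from .config import (
    CONTINENT_ORIGINS,
    DEFAULT_HEIGHT_MODELS,
    MIN_DIAMETER_CM,
    SimConfig,
)

__all__ = ["SpeciesPool", "SyntheticDataset", "make_pool", "make_plots",
           "inject_carbon_coupling", "generate"]

_MAX_OCCUPANCY = 0.995


@dataclass
class SpeciesPool:
    """A continental species pool with abundance structure and traits."""

    continent: str
    traits: pd.DataFrame  # taxon, genus, family, rel_freq, wood_density, max_diameter

    @property
    def species_id(self) -> np.ndarray:
        return self.traits["taxon"].to_numpy()

    @property
    def rel_freq(self) -> np.ndarray:
        return self.traits["rel_freq"].to_numpy()

    def __len__(self) -> int:
        return len(self.traits)


@dataclass
class SyntheticDataset:
    """Stems + plots + traits tables with the generating truth attached."""

    stems: pd.DataFrame
    plots: pd.DataFrame
    traits: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.stems.to_csv(out / "stems.csv", index=False, float_format="%.6f")
        self.plots.to_csv(out / "plots.csv", index=False, float_format="%.6f")
        self.traits.to_csv(out / "traits.csv", index=False, float_format="%.6f")
        (out / "truth.json").write_text(json.dumps(self.truth, indent=2, sort_keys=True))

    @classmethod
    def read(cls, in_dir) -> "SyntheticDataset":
        p = pathlib.Path(in_dir)
        truth = json.loads((p / "truth.json").read_text()) if (p / "truth.json").exists() else {}
        return cls(
            stems=pd.read_csv(p / "stems.csv"),
            plots=pd.read_csv(p / "plots.csv"),
            traits=pd.read_csv(p / "traits.csv"),
            truth=truth,
        )


def _rng_for(config: SimConfig, continent: str, stage: int) -> np.random.Generator:
    """Deterministic substream per (seed, continent, stage)."""
    idx = list(config.continents).index(continent) if continent in config.continents else 97
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(idx, stage)))


def make_pool(config: SimConfig, continent: str) -> SpeciesPool:
    """Draw a continental species pool from the configured distributions."""
    config.validate()
    g = config.pool_size
    alpha = config.per_continent(config.logseries_alpha, continent)
    rng = _rng_for(config, continent, 0)

    # Log-series parameter x = N/(N+alpha) at the notional community size N
    # for which the pool's expected richness equals its actual size.
    n_notional = alpha * np.expm1(g / alpha)
    x = n_notional / (n_notional + alpha)
    abund = logser.rvs(x, size=g, random_state=rng).astype(float)
    order = np.argsort(-abund, kind="stable")
    rel_freq = abund[order] / abund.sum()

    lo, hi = config.wd_bounds
    a, b = (lo - config.wd_mean) / config.wd_sd, (hi - config.wd_mean) / config.wd_sd
    wd = truncnorm.rvs(a, b, loc=config.wd_mean, scale=config.wd_sd, size=g, random_state=rng)
    maxd = np.exp(rng.normal(config.ln_maxd_mean, config.ln_maxd_sd, size=g))
    maxd = np.clip(maxd, *config.maxd_bounds)

    tag = continent[:2].lower()
    n_gen = max(2, g // 3)
    n_fam = max(2, n_gen // 4)
    genus_of_species = rng.integers(0, n_gen, size=g)
    family_of_genus = rng.integers(0, n_fam, size=n_gen)
    traits = pd.DataFrame({
        "taxon": [f"{tag}_sp{i:04d}" for i in range(g)],
        "genus": [f"{tag}_gen{genus_of_species[i]:03d}" for i in range(g)],
        "family": [f"{tag}_fam{family_of_genus[genus_of_species[i]]:02d}" for i in range(g)],
        "rel_freq": rel_freq,
        "wood_density": wd,
        "max_diameter": maxd,
    })
    return SpeciesPool(continent=continent, traits=traits)


def _occupancies(pool: SpeciesPool, mean_richness: float,
                 exponent: float = 0.5, q_max: float = _MAX_OCCUPANCY) -> np.ndarray:
    """Per-species plot occupancy from pool relative frequency.

    Power-law occupancy-frequency relation q_s = min(q_max, c * f_s^exponent)
    with c solved so that expected plot richness sum(q_s) matches the
    target. The sub-linear exponent keeps even dominant species below
    ubiquity, which holds the chance-overlap similarity floor of
    independent communities at realistic levels.
    """
    f = np.clip(pool.rel_freq, 1e-12, 1.0) ** exponent

    def total(log_c):
        return np.minimum(np.exp(log_c) * f, q_max).sum()

    target = min(mean_richness, q_max * len(f) - 1e-6)
    log_c = brentq(lambda lc: total(lc) - target, -30.0, 30.0, xtol=1e-12)
    return np.minimum(np.exp(log_c) * f, q_max)


def _orthant_upper(z: np.ndarray, r: np.ndarray) -> np.ndarray:
    """P(Z1 > z, Z2 > z) for standard bivariate normal with correlation r.

    Owen's T identity: P(Z1<=x, Z2<=x; r) = Phi(x) - 2*T(x, sqrt((1-r)/(1+r))).
    """
    a = np.sqrt((1.0 - r) / (1.0 + r))
    return ndtr(-z) - 2.0 * owens_t(-z, a)


def _latent_corr_for(q: float, rho_target: np.ndarray) -> np.ndarray:
    """Tetrachoric inversion: latent Gaussian correlation giving the requested
    presence-indicator correlation for a species with occupancy q."""
    z = ndtri(1.0 - q)
    r_grid = np.concatenate([np.linspace(0.0, 0.95, 39), np.linspace(0.96, 0.9995, 9)])
    p11_grid = _orthant_upper(np.full_like(r_grid, z), r_grid)
    p11_target = q * q + q * (1.0 - q) * rho_target
    return np.interp(p11_target, p11_grid, r_grid)


def _nearest_psd_chol(r_mat: np.ndarray) -> np.ndarray:
    """Cholesky factor after clipping eigenvalues and restoring unit diagonal."""
    vals, vecs = np.linalg.eigh(r_mat)
    vals = np.clip(vals, 1e-9, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / d[:, None] / d[None, :]
    return np.linalg.cholesky(fixed + 1e-10 * np.eye(len(fixed)))


def _grf(coords_dist: np.ndarray, sd: float, range_km: float,
         rng: np.random.Generator) -> np.ndarray:
    cov = sd * sd * np.exp(-coords_dist / range_km)
    chol = np.linalg.cholesky(cov + 1e-8 * sd * sd * np.eye(len(cov)))
    return chol @ rng.standard_normal(len(cov))


def _trunc_pareto(u: np.ndarray, shape: float, lo: float, hi: np.ndarray) -> np.ndarray:
    """Inverse CDF of a Pareto(shape) truncated to [lo, hi]."""
    tail = 1.0 - (lo / hi) ** shape
    return lo * (1.0 - u * tail) ** (-1.0 / shape)


def make_plots(config: SimConfig, pool: SpeciesPool) -> SyntheticDataset:
    """Lay out plots, assemble communities and draw stems for one continent.

    Presence/absence per species follows the Gaussian-copula model described
    in the module docstring; stem counts are uniform in stems_per_ha_range;
    every present species receives at least one stem and the remainder are
    multinomial in pool relative frequency.
    """
    from .beta import haversine_km

    config.validate()
    if len(pool) < 2:
        raise ValueError("empty or degenerate species pool")
    cont = pool.continent
    n_plots = config.n_plots_per_continent
    rng = _rng_for(config, cont, 1)

    bx, by = config.bbox_km
    xy = np.column_stack([rng.uniform(0, bx, n_plots), rng.uniform(0, by, n_plots)])
    lat0, lon0 = CONTINENT_ORIGINS.get(cont, (0.0, 0.0))
    lat = lat0 + xy[:, 1] / 110.574
    lon = lon0 + xy[:, 0] / (111.320 * np.cos(np.radians(lat0)))
    dist = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(dist, 0.0)

    # Target presence correlation from the similarity-decay law.
    q = _occupancies(pool, config.per_continent(config.mean_richness, cont),
                     exponent=config.occupancy_exponent, q_max=config.occupancy_max)
    sum_q = q.sum()
    a_floor = float(np.sum(q * q) / sum_q)      # chance-overlap Sorensen baseline
    b_span = 1.0 - a_floor
    s0 = a_floor + b_span * config.near_similarity_corr
    rho = (s0 * np.exp(-config.decay_rate * dist) - a_floor) / b_span
    rho = np.clip(rho, 0.0, 1.0)
    np.fill_diagonal(rho, 1.0)

    # Group species by (rounded) occupancy so the latent correlation matrix
    # and its Cholesky factor are shared within each group.
    presence = np.zeros((len(pool), n_plots), dtype=bool)
    z_thresh = ndtri(1.0 - q)
    bins = np.round(q, 3)
    for qb in np.unique(bins):
        members = np.flatnonzero(bins == qb)
        r_latent = _latent_corr_for(float(qb), rho)
        np.fill_diagonal(r_latent, 1.0)
        chol = _nearest_psd_chol(r_latent)
        zlat = chol @ rng.standard_normal((n_plots, members.size))
        presence[members] = (zlat > z_thresh[members][None, :]).T

    # Stems.
    lo_n, hi_n = config.stems_per_ha_range
    plot_ids = [f"{cont[:2].upper()}-{i + 1:03d}" for i in range(n_plots)]
    taxa = pool.species_id
    rel = pool.rel_freq
    stem_rows = []
    for j in range(n_plots):
        present = np.flatnonzero(presence[:, j])
        if present.size == 0:  # degenerate; force the commonest species
            present = np.array([0])
        n_target = int(round(rng.integers(lo_n, hi_n + 1) * config.plot_area))
        n_stems = max(n_target, present.size)
        counts = np.ones(present.size, dtype=int)
        extra = n_stems - present.size
        if extra > 0:
            p = rel[present] / rel[present].sum()
            counts += rng.multinomial(extra, p)
        sp_idx = np.repeat(present, counts)
        stem_rows.append((j, sp_idx))

    all_plot = np.concatenate([np.full(s.size, j) for j, s in stem_rows])
    all_sp = np.concatenate([s for _, s in stem_rows])
    n_total = all_sp.size
    subplot = rng.integers(1, config.subplots_per_plot + 1, size=n_total)
    diam = _trunc_pareto(
        rng.uniform(size=n_total), config.pareto_shape,
        MIN_DIAMETER_CM, pool.traits["max_diameter"].to_numpy()[all_sp],
    )

    # Identification masking: per-plot species-ID rate, remainder split
    # genus / family / unidentified.
    pm = config.ident_species_mean
    if pm >= 1.0:
        p_species = np.ones(n_plots)
    else:
        p_species = rng.beta(pm * config.ident_kappa, (1 - pm) * config.ident_kappa,
                             size=n_plots)
    gsplit, fsplit, usplit = config.ident_rest_split
    u = rng.uniform(size=n_total)
    p_sp_stem = p_species[all_plot]
    rest = 1.0 - p_sp_stem
    level = np.select(
        [u < p_sp_stem,
         u < p_sp_stem + rest * gsplit,
         u < p_sp_stem + rest * (gsplit + fsplit)],
        ["species", "genus", "family"],
        default="unidentified",
    )

    tr = pool.traits
    genus_arr = tr["genus"].to_numpy()[all_sp]
    family_arr = tr["family"].to_numpy()[all_sp]
    species_arr = taxa[all_sp]
    taxon = np.select(
        [level == "species", level == "genus", level == "family"],
        [species_arr, genus_arr, family_arr],
        default=None,
    )
    stems = pd.DataFrame({
        "plot_id": np.array(plot_ids)[all_plot],
        "subplot_id": subplot,
        "taxon": taxon,
        "family": np.where(level == "unidentified", None, family_arr),
        "genus": np.where(np.isin(level, ["species", "genus"]), genus_arr, None),
        "species": np.where(level == "species", species_arr, None),
        "id_level": level,
        "diameter_cm": diam,
    })

    # Environment: Gaussian random fields at plot locations.
    env_rng = _rng_for(config, cont, 2)
    env_cols = {}
    for name, spec in config.env_fields.items():
        vals = spec.mean + _grf(dist, spec.sd, spec.range_km, env_rng)
        vals = np.clip(vals, spec.lo if spec.lo is not None else -np.inf,
                       spec.hi if spec.hi is not None else np.inf)
        if name == "texture":
            vals = np.round(vals)
        env_cols[name] = vals

    plots = pd.DataFrame({
        "plot_id": plot_ids, "lat": lat, "lon": lon,
        "area_ha": config.plot_area, "continent": cont, **env_cols,
    })
    truth = {
        "continent": cont,
        "decay_rate": config.decay_rate,
        "sorensen_floor": a_floor,
        "sorensen_at_zero": s0,
        "mean_occupancy_sum": float(sum_q),
        "pool_size": len(pool),
        "seed": config.seed,
    }
    return SyntheticDataset(stems=stems, plots=plots, traits=pool.traits.copy(), truth=truth)


def _subplot_carbon_target(dataset: SyntheticDataset, config: SimConfig,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Per-subplot target ln carbon from the generating model."""
    stems = dataset.stems
    plots = dataset.plots.set_index("plot_id")
    # Plot-level systematic part: base + environment effects + plot effect.
    ln_base = np.log(config.carbon_base)
    plot_term = {}
    for pid, row in plots.iterrows():
        term = ln_base + rng.normal(0.0, config.plot_effect_sd)
        for name, coef in config.env_effects.items():
            spec = config.env_fields[name]
            term += coef * (row[name] - spec.mean) / spec.sd
        plot_term[pid] = term

    sp = stems[stems["id_level"] == "species"]
    rich = sp.groupby(["plot_id", "subplot_id"])["taxon"].nunique()
    nstem = stems.groupby(["plot_id", "subplot_id"]).size()

    rows = []
    for (pid, sid), n in nstem.items():
        s = int(rich.get((pid, sid), 0))
        rows.append({"plot_id": pid, "subplot_id": sid, "n_stems": int(n), "richness": s})
    df = pd.DataFrame(rows)
    ln_n = np.log(df["n_stems"].astype(float))
    ln_n_centred = ln_n - ln_n.groupby(df["plot_id"]).transform("mean")
    ok = df["richness"] >= 1
    target = np.full(len(df), np.nan)
    target[ok] = (
        df.loc[ok, "plot_id"].map(plot_term).to_numpy()
        + config.beta_true * (np.log(df.loc[ok, "richness"].astype(float)) - np.log(15.0))
        + config.gamma_stems * ln_n_centred[ok]
        + (rng.normal(0.0, config.noise_sd, size=int(ok.sum())) if config.noise_sd > 0 else 0.0)
    )
    df["ln_carbon_target"] = target
    return df


def inject_carbon_coupling(dataset: SyntheticDataset, config: SimConfig,
                           height_models=DEFAULT_HEIGHT_MODELS) -> SyntheticDataset:
    """Rescale subplot stem diameters to realise the diversity-carbon truth.

    Each subplot's stems are transformed D -> 10 + f * (D - 10) with f
    solved so that the subplot's pipeline-computed carbon equals the target
    exp(a_plot + beta_true*ln S + gamma*(centred ln n) + noise). Subplots
    with no species-level identification keep their original diameters.
    """
    if config.beta_true != 0.0 and config.subplots_per_plot < 2:
        raise ValueError("carbon coupling requires >= 2 subplots per plot")
    rng = _rng_for(config, "inject", 3)
    targets = _subplot_carbon_target(dataset, config, rng)

    stems = resolve_wood_density(dataset.stems, dataset.traits)
    stems = add_height_and_agb(stems, dataset.plots, height_models)
    plots = dataset.plots.set_index("plot_id")

    sub_area = {pid: plots.loc[pid, "area_ha"] / config.subplots_per_plot
                for pid in plots.index}
    new_diam = stems["diameter_cm"].to_numpy().copy()
    grouped = stems.groupby(["plot_id", "subplot_id"], sort=False)
    tkey = targets.set_index(["plot_id", "subplot_id"])["ln_carbon_target"]

    from .carbon import AGB_COEF, AGB_EXP, CARBON_FRACTION
    from .carbon import estimate_height

    for (pid, sid), grp in grouped:
        t = tkey.get((pid, sid), np.nan)
        if not np.isfinite(t):
            continue
        target_mg = np.exp(t) * sub_area[pid]  # Mg C in the subplot
        d0 = grp["diameter_cm"].to_numpy()
        rho_s = grp["wood_density"].to_numpy()
        model = height_models[plots.loc[pid, "continent"]]

        def carbon_of(f):
            d = MIN_DIAMETER_CM + f * (d0 - MIN_DIAMETER_CM)
            h = estimate_height(d, model)
            agb = AGB_COEF * np.power(rho_s * d * d * h, AGB_EXP)
            return CARBON_FRACTION * agb.sum() / 1000.0

        lo, hi = 1e-9, 1.0
        while carbon_of(hi) < target_mg:
            hi *= 2.0
            if hi > 1e6:
                raise RuntimeError("carbon target unattainable")  # pragma: no cover
        f_hat = brentq(lambda f: carbon_of(f) - target_mg, lo, hi, xtol=1e-12, rtol=1e-14)
        idx = stems.index.get_indexer(grp.index)
        new_diam[idx] = MIN_DIAMETER_CM + f_hat * (d0 - MIN_DIAMETER_CM)

    out_stems = dataset.stems.copy()
    out_stems["diameter_cm"] = new_diam
    truth = dict(dataset.truth)
    truth.update({
        "beta_true": config.beta_true,
        "gamma_stems": config.gamma_stems,
        "noise_sd": config.noise_sd,
        "plot_effect_sd": config.plot_effect_sd,
        "carbon_base": config.carbon_base,
        "env_effects": dict(config.env_effects),
    })
    return SyntheticDataset(stems=out_stems, plots=dataset.plots,
                            traits=dataset.traits, truth=truth)


def generate(config: SimConfig, height_models=DEFAULT_HEIGHT_MODELS) -> SyntheticDataset:
    """Full multi-continent synthetic inventory with carbon coupling."""
    parts = []
    for cont in config.continents:
        pool = make_pool(config, cont)
        parts.append(make_plots(config, pool))
    merged = SyntheticDataset(
        stems=pd.concat([p.stems for p in parts], ignore_index=True),
        plots=pd.concat([p.plots for p in parts], ignore_index=True),
        traits=pd.concat([p.traits for p in parts], ignore_index=True),
        truth={"continents": {p.truth["continent"]: p.truth for p in parts}},
    )
    out = inject_carbon_coupling(merged, config, height_models)
    out.truth["config_seed"] = config.seed
    return out
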