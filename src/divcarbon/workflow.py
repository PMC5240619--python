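"""End-to-end orchestration: input validation, localities, full pipeline runs.

run_all executes simulate -> carbon -> diversity -> beta -> stand ->
within -> mechanisms as toggled in a RunConfig, writes every stage's
artifacts to the output directory, and returns a RunReport whose content
(including output file hashes) is reproducible bit-for-bit under the same
configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import alpha, beta, carbon, mechanisms, stand, synthgen, within
from .config import RunConfig, dump_config

logger = logging.getLogger("divcarbon")

__all__ = ["validate_inputs", "locality_clusters", "run_all", "RunReport"]

REQUIRED_STEM_COLS = ("plot_id", "subplot_id", "taxon", "family", "genus",
                      "species", "id_level", "diameter_cm")
REQUIRED_PLOT_COLS = ("plot_id", "lat", "lon", "area_ha", "continent")


def validate_inputs(
    stems: pd.DataFrame,
    plots: pd.DataFrame,
    traits: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate inventory tables against the study-domain constraints.

    Hard rules: required columns present; stem diameters >= 10 cm (smaller
    stems are rejected row-wise, as below the census threshold); stems
    reference known plots. Soft (warning-level) rules: plot area in
    {0.96, 1.0} ha, MAT >= 20 degC and MAP >= 1300 mm, identification
    levels of >= 80% of stems to genus and >= 60% to species per plot.

    Returns the cleaned stems and an issue table (level, scope, message).
    """
    for col in REQUIRED_STEM_COLS:
        if col not in stems.columns:
            raise ValueError(f"stems missing required column {col!r}")
    for col in REQUIRED_PLOT_COLS:
        if col not in plots.columns:
            raise ValueError(f"plots missing required column {col!r}")
    if plots["plot_id"].duplicated().any():
        raise ValueError("duplicate plot_id in plots table")

    issues = []
    clean = stems.copy()
    small = clean["diameter_cm"] < 10.0
    if small.any():
        issues.append({"level": "reject", "scope": "stems",
                       "message": f"{int(small.sum())} stem(s) below the 10 cm census threshold"})
        clean = clean[~small]
    unknown = ~clean["plot_id"].isin(plots["plot_id"])
    if unknown.any():
        raise ValueError(f"stems reference unknown plots: "
                         f"{sorted(clean.loc[unknown, 'plot_id'].unique())}")

    odd_area = ~plots["area_ha"].isin([0.96, 1.0])
    if odd_area.any():
        issues.append({"level": "warn", "scope": "plots",
                       "message": f"{int(odd_area.sum())} plot(s) with area outside {{0.96, 1.0}} ha"})
    if "mat" in plots and (plots["mat"] < 20).any():
        issues.append({"level": "warn", "scope": "plots",
                       "message": "MAT below 20 degC: outside the humid lowland domain"})
    if "map" in plots and (plots["map"] < 1300).any():
        issues.append({"level": "warn", "scope": "plots",
                       "message": "MAP below 1300 mm: outside the humid lowland domain"})
    if "altitude_m" in plots and (plots["altitude_m"] > 1217).any():
        issues.append({"level": "warn", "scope": "plots",
                       "message": "altitude above 1217 m: outside the lowland domain"})

    ident = clean.assign(
        to_species=clean["id_level"] == "species",
        to_genus=clean["id_level"].isin(["species", "genus"]),
    ).groupby("plot_id")[["to_species", "to_genus"]].mean()
    low_sp = ident["to_species"] < 0.60
    low_gen = ident["to_genus"] < 0.80
    if low_sp.any():
        issues.append({"level": "warn", "scope": "plots",
                       "message": f"{int(low_sp.sum())} plot(s) with <60% of stems identified to species"})
    if low_gen.any():
        issues.append({"level": "warn", "scope": "plots",
                       "message": f"{int(low_gen.sum())} plot(s) with <80% of stems identified to genus"})
    return clean, pd.DataFrame(issues, columns=["level", "scope", "message"])


def locality_clusters(plots: pd.DataFrame, radius_km: float = 5.0,
                      method: str = "single") -> pd.Series:
    """Cluster plots into localities by inter-plot great-circle distance.

    Single linkage with a distance cap (default 5 km) — chains of nearby
    plots merge into one locality even if their endpoints are farther
    apart. method="complete" gives the stricter every-pair-within-radius
    reading. Labels are integers ordered by first appearance in plot_id
    order, so they are stable under row reordering.
    """
    p = plots.sort_values("plot_id").reset_index(drop=True)
    if len(p) == 1:
        return pd.Series([1], index=p["plot_id"], name="locality")
    lat, lon = p["lat"].to_numpy(), p["lon"].to_numpy()
    d = beta.haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method=method)
    raw = fcluster(z, t=radius_km, criterion="distance")
    # stable relabel by first occurrence
    mapping, nxt = {}, 1
    labels = []
    for r in raw:
        if r not in mapping:
            mapping[r] = nxt
            nxt += 1
        labels.append(mapping[r])
    return pd.Series(labels, index=p["plot_id"], name="locality")


@dataclass
class RunReport:
    config_hash: str
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    output_hashes: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _hash_file(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(cfg: RunConfig) -> RunReport:
    """Execute the full pipeline per the RunConfig stage toggles."""
    out = pathlib.Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = dump_config(cfg)
    (out / "config.yaml").write_text(cfg_text)
    report = RunReport(config_hash=hashlib.sha256(cfg_text.encode()).hexdigest()[:16])
    on = cfg.stages

    cfg.sim.seed = cfg.seed
    data = None
    if on.get("simulate", True):
        logger.info("simulate: generating synthetic inventory")
        data = synthgen.generate(cfg.sim)
        data.write(out)
        report.stages["simulate"] = {
            "n_stems": len(data.stems), "n_plots": len(data.plots),
        }
    else:
        data = synthgen.SyntheticDataset.read(out)
        report.stages["simulate"] = "skipped (read existing tables)"

    stems, issues = validate_inputs(data.stems, data.plots, data.traits)
    report.warnings.extend(issues["message"].tolist())

    resolved = carbon.resolve_wood_density(stems, data.traits)
    resolved = carbon.add_height_and_agb(resolved, data.plots)

    carbon_plot = carbon_sub = None
    if on.get("carbon", True):
        logger.info("carbon: aggregating stem biomass")
        carbon_plot = carbon.aggregate_carbon(resolved, data.plots, scale="plot")
        carbon_sub = carbon.aggregate_carbon(resolved, data.plots, scale="subplot",
                                             subplots_per_plot=cfg.sim.subplots_per_plot)
        carbon_plot.to_csv(out / "carbon_plot.csv", index=False, float_format="%.6f")
        carbon_sub.to_csv(out / "carbon_subplot.csv", index=False, float_format="%.6f")
        report.stages["carbon"] = {"mean_plot_carbon": round(float(carbon_plot["carbon"].mean()), 3)}

    div_plot = div_sub = None
    if on.get("diversity", True):
        logger.info("diversity: computing alpha-diversity profiles")
        div_plot = alpha.diversity_profiles(stems, scale="plot", rarefy_to=cfg.rarefy_to)
        div_sub = alpha.diversity_profiles(stems, scale="subplot", rarefy_to=cfg.rarefy_to)
        div_plot.to_csv(out / "diversity_plot.csv", index=False, float_format="%.6f")
        div_sub.to_csv(out / "diversity_subplot.csv", index=False, float_format="%.6f")
        report.stages["diversity"] = {
            "mean_richness": round(float(div_plot["richness"].mean()), 2)}

    if on.get("beta", True):
        logger.info("beta: distance decay of Sorensen similarity")
        pairs = beta.pairwise_similarity(stems, data.plots, min_ident=cfg.min_ident_for_beta)
        pairs.to_csv(out / "pairs.csv", index=False, float_format="%.6f")
        decay = {}
        for cont, sub in pairs.groupby("continent"):
            if len(sub) < 10:
                report.warnings.append(f"beta: too few pairs in {cont}")
                continue
            fit = beta.fit_distance_decay(sub, n_boot=min(cfg.n_boot, 500), seed=cfg.seed)
            decay[cont] = {"alpha": fit.alpha, "beta": fit.beta,
                           "ci_alpha": fit.ci_alpha, "ci_beta": fit.ci_beta}
        (out / "decay_fit.json").write_text(json.dumps(decay, indent=2, sort_keys=True))
        report.stages["beta"] = {c: round(v["beta"], 6) for c, v in decay.items()}

    if on.get("stand", True) and carbon_plot is not None and div_plot is not None:
        logger.info("stand: among-plot inference")
        joined = (
            carbon_plot.merge(div_plot, on="plot_id")
            .merge(data.plots[["plot_id", "continent", "lat", "lon",
                               "cwd", "mat", "map", "teb", "cn", "texture"]], on="plot_id")
        )
        joined["ln_carbon"] = np.log(joined["carbon"])
        joined["diversity"] = joined[cfg.diversity_metric]
        stand_out = {}
        for cont, sub in joined.groupby("continent"):
            tau, p = stand.kendall_tau(sub["carbon"], sub["diversity"])
            power = stand.detectable_effect(len(sub))
            ms = stand.fit_all_subsets(sub, "ln_carbon")
            sar = stand.fit_sar_error(
                sub["ln_carbon"], sub[["diversity", "cwd", "mat", "map", "teb", "cn", "texture"]],
                sub[["lat", "lon"]].to_numpy(),
            )
            stand_out[cont] = {
                "kendall_tau": tau, "kendall_p": p,
                "detectable_r": power.r_min, "detectable_tau": power.tau_min,
                "averaged_coef": ms.averaged_coef, "sum_weights": ms.sum_weights,
                "sar_lambda": sar.lam,
                "sar_diversity_coef": float(sar.params["diversity"]),
            }
        (out / "stand.json").write_text(json.dumps(stand_out, indent=2, sort_keys=True))
        summaries = stand.continent_summaries(
            joined, "carbon", transform="log", n_boot=cfg.n_boot, seed=cfg.seed)
        summaries.to_csv(out / "continent_summaries.csv", index=False, float_format="%.4f")
        report.stages["stand"] = {c: round(v["kendall_tau"], 4) for c, v in stand_out.items()}

    if on.get("within", True) and carbon_sub is not None and div_sub is not None:
        logger.info("within: subplot-scale slopes")
        sub_table = carbon_sub.merge(
            div_sub[["plot_id", "subplot_id", "richness"]],
            on=["plot_id", "subplot_id"], how="left",
        )
        slopes = within.fit_all_plot_slopes(sub_table)
        slopes.to_csv(out / "slopes.csv", index=False, float_format="%.6f")
        summ = within.summarize_slopes(slopes, n_boot=cfg.n_boot, seed=cfg.seed)
        (out / "slope_summary.json").write_text(json.dumps({
            "mean_beta": summ.mean_beta, "se_mean": summ.se_mean,
            "boot_ci": list(summ.boot_ci), "wilcoxon_p": summ.wilcoxon_p,
            "n_pos": summ.n_pos, "n_neg": summ.n_neg,
            "doubling_pct": summ.doubling_pct,
        }, indent=2, sort_keys=True))
        report.stages["within"] = {"mean_beta": round(summ.mean_beta, 4),
                                   "doubling_pct": round(summ.doubling_pct, 2)}

    if on.get("mechanisms", True) and carbon_sub is not None:
        logger.info("mechanisms: trait structure and null models")
        ts_sub = mechanisms.trait_summaries(
            stems, data.traits, scale="subplot",
            large_threshold=cfg.large_diameter_threshold,
            dense_threshold=cfg.dense_wood_threshold,
        )
        ts_sub.to_csv(out / "trait_summaries_subplot.csv", index=False, float_format="%.6f")
        curves = []
        for cont, pool_tr in data.traits.groupby(data.traits["taxon"].str[:2]):
            curve = mechanisms.null_sampling_curve(
                pool_tr, trait="max_diameter", threshold=cfg.large_diameter_threshold,
                mode="uniform",
            )
            cdf = curve.as_frame()
            cdf["pool"] = cont
            curves.append(cdf)
        pd.concat(curves, ignore_index=True).to_csv(
            out / "null_curves.csv", index=False, float_format="%.6f")
        glmm = mechanisms.occurrence_glmm(ts_sub, outcome="has_large")
        (out / "occurrence_glmm.json").write_text(json.dumps(glmm, indent=2, sort_keys=True))
        report.stages["mechanisms"] = {"occurrence_slope": None if glmm["saturated"]
                                       else round(glmm["slope"], 4),
                                       "saturated": glmm["saturated"]}

    for f in sorted(out.iterdir()):
        if f.suffix in (".csv", ".json", ".yaml") and f.name != "report.json":
            report.output_hashes[f.name] = _hash_file(f)
    (out / "report.json").write_text(report.to_json())
    return report
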