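"""Selection-effect and niche-complementarity diagnostics.

Community trait structure (community-weighted means, trait dispersion,
functional dispersion) is summarised per unit and related to carbon;
null models give the expected probability that a random community of S
species sampled from the continental pool contains at least one
"high-functioning" species (potentially large, max diameter >= 70 cm, or
densely wooded, >= 0.8 g cm^-3 by default). A rising observed occurrence
of such species with richness, at the rate expected by chance, is the
signature of a selection effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.special import gammaln
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

__all__ = [
    "trait_summaries",
    "null_sampling_curve",
    "occurrence_glmm",
    "cwm_fd_regressions",
    "NullCurve",
]

LARGE_DIAMETER_CM = 70.0
DENSE_WOOD = 0.8


def trait_summaries(
    stems: pd.DataFrame,
    traits: pd.DataFrame,
    scale: str = "plot",
    large_threshold: float = LARGE_DIAMETER_CM,
    dense_threshold: float = DENSE_WOOD,
) -> pd.DataFrame:
    """Community trait summaries per unit, weighted by basal area.

    cwm_wd / cwm_maxd: basal-area-weighted community means of wood density
    and species maximum diameter; sd_wd: basal-area-weighted SD of wood
    density across species; fdis: functional dispersion, the weighted mean
    distance of species to the weighted centroid in z-scored
    (wood density, ln max diameter) trait space (z-scores over the full
    trait table so units are comparable). has_large / has_dense flag the
    presence of any species over the corresponding trait threshold.
    """
    if scale not in ("plot", "subplot"):
        raise ValueError("scale must be 'plot' or 'subplot'")
    tr = traits.set_index("taxon")
    z_wd = (tr["wood_density"] - tr["wood_density"].mean()) / tr["wood_density"].std(ddof=1)
    ln_maxd = np.log(tr["max_diameter"])
    z_maxd = (ln_maxd - ln_maxd.mean()) / ln_maxd.std(ddof=1)

    sp = stems[stems["species"].isin(tr.index)].copy()
    if sp.empty:
        raise ValueError("no stems with resolvable species traits")
    sp["ba"] = np.pi * (sp["diameter_cm"] / 200.0) ** 2
    keys = ["plot_id"] if scale == "plot" else ["plot_id", "subplot_id"]

    rows = []
    for key, grp in sp.groupby(keys, sort=True):
        by_sp = grp.groupby("species")["ba"].sum()
        w = by_sp / by_sp.sum()
        wd = tr.loc[by_sp.index, "wood_density"]
        maxd = tr.loc[by_sp.index, "max_diameter"]
        cwm_wd = float(np.average(wd, weights=w))
        pts = np.column_stack([z_wd.loc[by_sp.index], z_maxd.loc[by_sp.index]])
        centroid = np.average(pts, axis=0, weights=w)
        fdis = float(np.average(np.linalg.norm(pts - centroid, axis=1), weights=w))
        sd_wd = float(np.sqrt(np.average((wd - cwm_wd) ** 2, weights=w)))
        row = {
            "cwm_wd": cwm_wd,
            "cwm_maxd": float(np.average(maxd, weights=w)),
            "sd_wd": sd_wd,
            "fdis": fdis,
            "has_large": bool((maxd >= large_threshold).any()),
            "has_dense": bool((wd >= dense_threshold).any()),
            "richness": int(len(by_sp)),
        }
        if scale == "plot":
            row["unit_id"] = str(key[0] if isinstance(key, tuple) else key)
            row["plot_id"] = key[0] if isinstance(key, tuple) else key
        else:
            row["unit_id"] = f"{key[0]}:{int(key[1]):02d}"
            row["plot_id"], row["subplot_id"] = key
        rows.append(row)
    out = pd.DataFrame(rows)
    front = ["unit_id", "plot_id"] + (["subplot_id"] if scale == "subplot" else [])
    return out[front + [c for c in out.columns if c not in front]]


@dataclass
class NullCurve:
    """Expected probability of sampling >= 1 qualifying species vs richness."""

    richness_grid: np.ndarray
    p_expected: np.ndarray
    mode: str
    trait: str
    threshold: float
    n_qualifying: int
    pool_size: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "richness": self.richness_grid, "p_expected": self.p_expected,
            "mode": self.mode, "trait": self.trait, "threshold": self.threshold,
        })


def _hyper_complement(pool: int, qualifying: int, s: np.ndarray) -> np.ndarray:
    """P(at least one of K qualifying in S uniform draws) = 1 - C(G-K,S)/C(G,S)."""
    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    out = np.ones(s.size, dtype=float)
    feasible = s <= pool - qualifying
    sf = s[feasible]
    out[feasible] = 1.0 - np.exp(log_comb(pool - qualifying, sf) - log_comb(pool, sf))
    return out


def null_sampling_curve(
    pool: pd.DataFrame,
    trait: str = "max_diameter",
    threshold: float = LARGE_DIAMETER_CM,
    mode: str = "uniform",
    richness_grid=None,
    n_rep: int = 10000,
    seed: int = 0,
) -> NullCurve:
    """Null expectation of containing a high-functioning species.

    pool: trait table with columns `trait` and, for frequency mode,
    `rel_freq`. Uniform mode is exact (hypergeometric complement);
    frequency mode samples species without replacement proportionally to
    occurrence frequency via the Gumbel top-k race (n_rep Monte-Carlo
    replicates per grid point).
    """
    if mode not in ("uniform", "frequency"):
        raise ValueError("mode must be 'uniform' or 'frequency'")
    qual = (pool[trait] >= threshold).to_numpy()
    g, k = len(pool), int(qual.sum())
    if k == 0 or k == g:
        raise ValueError("pool must contain species above and below the threshold")
    grid = np.arange(1, g + 1) if richness_grid is None else np.asarray(richness_grid, dtype=int)
    if grid.max() > g:
        raise ValueError("richness exceeds pool size")

    if mode == "uniform":
        p = _hyper_complement(g, k, grid)
    else:
        w = pool["rel_freq"].to_numpy(dtype=float)
        if np.any(w <= 0):
            raise ValueError("rel_freq must be positive")
        logw = np.log(w / w.sum())
        rng = np.random.default_rng(seed)
        keys = logw[None, :] + rng.gumbel(size=(n_rep, g))
        order = np.argsort(-keys, axis=1)        # rank species per replicate
        qual_sorted = qual[order]                # qualifying flags in draw order
        first_qual = np.where(
            qual_sorted.any(axis=1), qual_sorted.argmax(axis=1) + 1, g + 1
        )
        # community of size S contains a qualifier iff the first one appears
        # within the first S ranks
        p = np.array([(first_qual <= s).mean() for s in grid])
    return NullCurve(
        richness_grid=grid, p_expected=p, mode=mode, trait=trait,
        threshold=threshold, n_qualifying=k, pool_size=g,
    )


def occurrence_glmm(subplot_traits: pd.DataFrame, outcome: str = "has_large"):
    """Logistic mixed model of qualifying-species occurrence on richness.

    has_large (or has_dense) ~ richness with a plot random intercept,
    fitted by variational Bayes. Returns a dict with slope, SE, two-sided
    p (normal approximation) and a saturation flag when the outcome never
    varies (as when virtually every unit holds a potentially large
    species).
    """
    df = subplot_traits[[outcome, "richness", "plot_id"]].dropna().copy()
    if df["plot_id"].nunique() < 20:
        raise ValueError("need >= 20 plots of subplot data")
    y = df[outcome].astype(int)
    if y.nunique() < 2:
        return {"outcome": outcome, "saturated": True, "rate": float(y.mean()),
                "slope": np.nan, "se": np.nan, "p": np.nan}
    df["y"] = y
    state = np.random.get_state()  # fit_vb draws from the global RNG
    try:
        np.random.seed(20170117)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = BinomialBayesMixedGLM.from_formula(
                "y ~ richness", {"plot": "0 + C(plot_id)"}, df
            )
            res = model.fit_vb()
    finally:
        np.random.set_state(state)
    i = list(res.model.exog_names).index("richness")
    slope, se = float(res.fe_mean[i]), float(res.fe_sd[i])
    p = float(2 * st.norm.sf(abs(slope / se)))
    return {"outcome": outcome, "saturated": False, "rate": float(y.mean()),
            "slope": slope, "se": se, "p": p}


def cwm_fd_regressions(
    carbon: pd.DataFrame,
    trait_summary: pd.DataFrame,
    scale: str = "plot",
) -> pd.DataFrame:
    """Carbon as a function of each community trait metric, one model each.

    Plot scale: OLS per continent when a continent column is present,
    otherwise pooled OLS. Subplot scale: linear mixed model with a plot
    random intercept. Trait predictors are z-scored within each model's
    data so coefficients are comparable.
    """
    preds = ["cwm_wd", "cwm_maxd", "sd_wd", "fdis"]
    df = carbon.merge(trait_summary, on="unit_id", suffixes=("", "_tr"))
    df = df[df["carbon"] > 0].copy()
    df["ln_carbon"] = np.log(df["carbon"])
    if df.empty:
        raise ValueError("no joined units with positive carbon")

    rows = []
    if scale == "plot":
        groups = df.groupby("continent") if "continent" in df else [("all", df)]
        for cont, sub in groups:
            for p in preds:
                d = sub[["ln_carbon", p]].dropna()
                z = (d[p] - d[p].mean()) / d[p].std(ddof=1)
                res = sm.OLS(d["ln_carbon"], sm.add_constant(z)).fit()
                rows.append({"scale": "plot", "group": cont, "predictor": p,
                             "coef": float(res.params[p]), "se": float(res.bse[p]),
                             "p": float(res.pvalues[p]), "n": len(d)})
    elif scale == "subplot":
        for p in preds:
            d = df[["ln_carbon", p, "plot_id"]].dropna().copy()
            d["z"] = (d[p] - d[p].mean()) / d[p].std(ddof=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = smf.mixedlm("ln_carbon ~ z", d, groups=d["plot_id"]).fit(reml=False)
            rows.append({"scale": "subplot", "group": "all", "predictor": p,
                         "coef": float(res.params["z"]), "se": float(res.bse["z"]),
                         "p": float(res.pvalues["z"]), "n": len(d)})
    else:
        raise ValueError("scale must be 'plot' or 'subplot'")
    return pd.DataFrame(rows)
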