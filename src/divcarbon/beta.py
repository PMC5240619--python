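"""Beta diversity: pairwise Sorensen similarity and its decay with distance.

The distance-decay model follows the log-linear form ln(similarity) =
alpha + beta * distance, fitted as a binomial-family GLM with log link on
the raw plot pairs. Confidence envelopes come from bootstrap resampling of
plots (not pairs - pairwise rows sharing a plot are not independent),
rebuilding the pair table for each resample. A gamma-diversity null model
gives the similarity expected from random draws out of the continental
species pool, so observed similarity can be expressed as a deviation from
the chance expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "sorensen",
    "haversine_km",
    "pairwise_similarity",
    "fit_distance_decay",
    "gamma_null_similarity",
    "DecayFit",
]


def sorensen(taxa_a, taxa_b) -> float:
    """Presence-absence Sorensen similarity 2a / (2a + b + c)."""
    sa, sb = set(taxa_a), set(taxa_b)
    if not sa or not sb:
        raise ValueError("taxon sets must be non-empty")
    shared = len(sa & sb)
    return 2.0 * shared / (len(sa) + len(sb))


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points in decimal degrees."""
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    if np.any(np.abs(lat1) > 90) or np.any(np.abs(lat2) > 90):
        raise ValueError("latitude out of range")
    if np.any(np.abs(lon1) > 180) or np.any(np.abs(lon2) > 180):
        raise ValueError("longitude out of range")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    return d if d.ndim else float(d)


def plot_taxon_sets(stems: pd.DataFrame) -> dict:
    """Species-level taxon set per plot (genus/family-only stems excluded)."""
    sp = stems[stems["id_level"] == "species"]
    return {pid: set(grp["taxon"]) for pid, grp in sp.groupby("plot_id")}


def pairwise_similarity(
    stems: pd.DataFrame,
    plots: pd.DataFrame,
    min_ident: float = 0.90,
) -> pd.DataFrame:
    """All within-continent plot pairs with Sorensen similarity and distance.

    Restricted to plots whose fraction of stems identified to species
    exceeds `min_ident`, mirroring the identification filter applied before
    fitting distance decay.
    """
    frac = (
        stems.assign(is_sp=stems["id_level"] == "species")
        .groupby("plot_id")["is_sp"].mean()
    )
    keep = frac[frac > min_ident].index
    sets = plot_taxon_sets(stems[stems["plot_id"].isin(keep)])
    meta = plots.set_index("plot_id")

    rows = []
    for cont, sub in meta.loc[meta.index.isin(sets)].groupby("continent"):
        ids = list(sub.index)
        lat = sub["lat"].to_numpy()
        lon = sub["lon"].to_numpy()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if not sets[ids[i]] or not sets[ids[j]]:
                    continue
                rows.append({
                    "plot_a": ids[i], "plot_b": ids[j], "continent": cont,
                    "sorensen": sorensen(sets[ids[i]], sets[ids[j]]),
                    "distance_km": haversine_km(lat[i], lon[i], lat[j], lon[j]),
                })
    return pd.DataFrame(rows)


@dataclass
class DecayFit:
    """Fitted distance-decay curve ln(similarity) = alpha + beta * distance."""

    alpha: float
    beta: float
    ci_alpha: tuple[float, float]
    ci_beta: tuple[float, float]
    n_boot: int
    n_plots: int
    n_pairs: int

    def predict(self, distance_km):
        return np.exp(self.alpha + self.beta * np.asarray(distance_km, dtype=float))

    def summary(self) -> str:
        return (
            f"Distance decay (binomial log-link GLM, {self.n_pairs} pairs from "
            f"{self.n_plots} plots)\n"
            f"  alpha = {self.alpha:.4f}  95% CI [{self.ci_alpha[0]:.4f}, {self.ci_alpha[1]:.4f}]\n"
            f"  beta  = {self.beta:.6f} km^-1  95% CI [{self.ci_beta[0]:.6f}, {self.ci_beta[1]:.6f}]\n"
            f"  ({self.n_boot} plot-level bootstrap resamples)"
        )


def _glm_log_binomial(sim: np.ndarray, dist: np.ndarray) -> tuple[float, float]:
    x = sm.add_constant(dist)
    start = np.array([np.log(max(sim.mean(), 1e-6)), -1e-6])
    with warnings.catch_warnings():
        # log link on binomial can exceed (0,1) off-support; fits stay inside here
        warnings.simplefilter("ignore")
        model = sm.GLM(sim, x, family=sm.families.Binomial(link=sm.families.links.Log()))
        try:
            res = model.fit(start_params=start, maxiter=200)
        except Exception:
            res = model.fit_regularized(alpha=0.0, start_params=start)  # pragma: no cover
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError("distance-decay GLM failed to converge")
    return float(res.params[0]), float(res.params[1])


def fit_distance_decay(
    pairs: pd.DataFrame,
    n_boot: int = 10000,
    seed: int = 0,
) -> DecayFit:
    """Fit the decay model and bootstrap 95% envelopes over plots."""
    if len(pairs) < 10:
        raise ValueError("need at least 10 plot pairs")
    plots = sorted(set(pairs["plot_a"]) | set(pairs["plot_b"]))
    if len(plots) < 3:
        raise ValueError("pairs must involve at least 3 plots")

    sim = pairs["sorensen"].to_numpy(dtype=float)
    dist = pairs["distance_km"].to_numpy(dtype=float)
    alpha, beta = _glm_log_binomial(sim, dist)

    # Pair lookup for fast bootstrap reassembly.
    idx = {p: k for k, p in enumerate(plots)}
    ia = pairs["plot_a"].map(idx).to_numpy()
    ib = pairs["plot_b"].map(idx).to_numpy()
    mat_sim = np.full((len(plots), len(plots)), np.nan)
    mat_dist = np.full_like(mat_sim, np.nan)
    mat_sim[ia, ib] = mat_sim[ib, ia] = sim
    mat_dist[ia, ib] = mat_dist[ib, ia] = dist

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 2))
    n = len(plots)
    for b in range(n_boot):
        take = rng.integers(0, n, size=n)
        ii, jj = np.triu_indices(n, k=1)
        pi, pj = take[ii], take[jj]
        keep = pi != pj  # a plot paired with its own copy is not a pair
        s = mat_sim[pi[keep], pj[keep]]
        d = mat_dist[pi[keep], pj[keep]]
        ok = ~np.isnan(s)
        try:
            boots[b] = _glm_log_binomial(s[ok], d[ok])
        except Exception:
            boots[b] = np.nan
    boots = boots[~np.isnan(boots).any(axis=1)]
    lo_a, hi_a = np.percentile(boots[:, 0], [2.5, 97.5])
    lo_b, hi_b = np.percentile(boots[:, 1], [2.5, 97.5])
    return DecayFit(
        alpha=alpha, beta=beta,
        ci_alpha=(float(lo_a), float(hi_a)), ci_beta=(float(lo_b), float(hi_b)),
        n_boot=n_boot, n_plots=len(plots), n_pairs=len(pairs),
    )


def expected_shared_uniform(s_a: int, s_b: int, pool_size: int) -> float:
    """Closed-form expected shared-species count under uniform pool draws.

    Drawing S_a and S_b species uniformly without replacement from a pool of
    G, each species is in both samples with probability (S_a/G)(S_b/G), so
    E[shared] = S_a * S_b / G.
    """
    if s_a > pool_size or s_b > pool_size:
        raise ValueError("plot richness exceeds pool size")
    return s_a * s_b / pool_size


def gamma_null_similarity(
    richness_by_plot: pd.Series,
    pool_size: int,
    observed: pd.DataFrame | None = None,
    mode: str = "uniform",
    rel_freq=None,
    n_rep: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Expected pairwise Sorensen similarity under random pool sampling.

    mode="uniform" samples each plot's observed richness uniformly without
    replacement from the pool (Monte-Carlo, with the closed-form expected
    shared count also reported); mode="frequency" weights draws by the
    species' relative occurrence frequencies. When an observed pair table
    is supplied, returns observed minus expected similarity per pair.
    """
    if mode not in ("uniform", "frequency"):
        raise ValueError("mode must be 'uniform' or 'frequency'")
    if (richness_by_plot > pool_size).any():
        raise ValueError("plot richness exceeds pool size")
    if mode == "frequency":
        w = np.asarray(rel_freq, dtype=float)
        if w.size != pool_size or np.any(w <= 0):
            raise ValueError("frequency mode needs positive rel_freq of pool size")
        logw = np.log(w / w.sum())

    rng = np.random.default_rng(seed)
    plots = list(richness_by_plot.index)
    draws = {}
    for pid in plots:
        s = int(richness_by_plot[pid])
        if mode == "uniform":
            # membership indicator matrix n_rep x pool
            member = np.zeros((n_rep, pool_size), dtype=bool)
            for r in range(n_rep):
                member[r, rng.choice(pool_size, size=s, replace=False)] = True
        else:
            # Gumbel top-k trick: exact weighted sampling without replacement.
            keys = logw + rng.gumbel(size=(n_rep, pool_size))
            top = np.argpartition(-keys, s - 1, axis=1)[:, :s]
            member = np.zeros((n_rep, pool_size), dtype=bool)
            np.put_along_axis(member, top, True, axis=1)
        draws[pid] = member

    obs_lookup = {}
    if observed is not None:
        for _, r in observed.iterrows():
            obs_lookup[frozenset((r["plot_a"], r["plot_b"]))] = r["sorensen"]

    rows = []
    for i in range(len(plots)):
        for j in range(i + 1, len(plots)):
            a, b = plots[i], plots[j]
            shared = (draws[a] & draws[b]).sum(axis=1)
            s_a, s_b = int(richness_by_plot[a]), int(richness_by_plot[b])
            exp_sim = float(np.mean(2.0 * shared / (s_a + s_b)))
            row = {
                "plot_a": a, "plot_b": b, "expected_sorensen": exp_sim,
                "expected_shared": float(shared.mean()),
            }
            if mode == "uniform":
                row["expected_shared_exact"] = expected_shared_uniform(s_a, s_b, pool_size)
            key = frozenset((a, b))
            if key in obs_lookup:
                row["observed_sorensen"] = obs_lookup[key]
                row["deviation"] = obs_lookup[key] - exp_sim
            rows.append(row)
    return pd.DataFrame(rows)
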