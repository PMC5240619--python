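"""Stand-scale (among 1 ha plots) diversity-carbon inference.

Four tools: bivariate Kendall tau correlations with a power analysis for
the minimum detectable effect; all-subsets OLS with AICc model averaging
over the 95% confidence set; a simultaneous autoregressive (SAR) error
model fitted by maximum likelihood to absorb spatially autocorrelated
residuals; and continental summaries (bootstrap CIs plus ANOVA/Tukey
grouping letters).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.optimize import minimize_scalar
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "kendall_tau",
    "detectable_effect",
    "simulated_power",
    "fit_all_subsets",
    "fit_sar_error",
    "simulate_sar_field",
    "continent_summaries",
    "structural_correlates",
    "PowerResult",
    "ModelSet",
    "SAREResults",
]

ENV_PREDICTORS = ("cwd", "mat", "map", "teb", "cn", "texture")


def kendall_tau(x, y) -> tuple[float, float]:
    """Tie-corrected Kendall tau-b with two-sided normal-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5 or x.size != y.size:
        raise ValueError("need >= 5 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Kendall tau undefined for a constant vector")
    res = st.kendalltau(x, y, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class PowerResult:
    """Minimum detectable correlation at a given sample size."""

    n: int
    alpha_level: float
    power: float
    r_min: float
    tau_min: float


def detectable_effect(n: int, alpha_level: float = 0.05, power: float = 0.80) -> PowerResult:
    """Smallest Pearson r (and Kendall tau) detectable with given power.

    Fisher-z power analysis: r_min = tanh((z_{1-a/2} + z_power)/sqrt(n-3)),
    converted to tau through the bivariate-normal relation
    tau = (2/pi) * arcsin(r).
    """
    if n <= 3:
        raise ValueError("power analysis requires n > 3")
    z = st.norm.ppf(1 - alpha_level / 2) + st.norm.ppf(power)
    r_min = float(np.tanh(z / np.sqrt(n - 3)))
    tau_min = float(2.0 / np.pi * np.arcsin(r_min))
    return PowerResult(n=n, alpha_level=alpha_level, power=power, r_min=r_min, tau_min=tau_min)


def simulated_power(n: int, r: float, n_rep: int = 5000, seed: int = 0,
                    alpha_level: float = 0.05) -> float:
    """Monte-Carlo check of the closed-form power analysis.

    Draws bivariate-normal samples with correlation r and reports the
    fraction of two-sided Pearson tests rejecting at alpha_level.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    c = np.linalg.cholesky(np.array([[1.0, r], [r, 1.0]]))
    for _ in range(n_rep):
        xy = rng.standard_normal((n, 2)) @ c.T
        hits += st.pearsonr(xy[:, 0], xy[:, 1]).pvalue < alpha_level
    return hits / n_rep


# ---------------------------------------------------------------------------
# All-subsets OLS with AICc model averaging


def akaike_weights(aicc) -> np.ndarray:
    """Akaike weights exp(-delta/2) / sum, invariant to a constant shift."""
    a = np.asarray(aicc, dtype=float)
    w = np.exp(-(a - a.min()) / 2.0)
    return w / w.sum()


@dataclass
class ModelSet:
    """All-subsets OLS candidates with AICc weights and averaged effects.

    candidates: one row per model (terms, k, aicc, delta, weight, in_set).
    averaged_coef / averaged_se: full-model-averaged coefficient and
    unconditional SE per predictor over the 95% confidence set (a predictor
    absent from a model contributes a zero coefficient).
    sum_weights: summed Akaike weights of all models containing each
    predictor (variable-importance weights).
    """

    response: str
    predictors: tuple[str, ...]
    candidates: pd.DataFrame
    averaged_coef: dict[str, float] = field(default_factory=dict)
    averaged_se: dict[str, float] = field(default_factory=dict)
    sum_weights: dict[str, float] = field(default_factory=dict)
    n: int = 0

    def summary(self) -> str:
        lines = [
            f"All-subsets OLS of {self.response} on {len(self.predictors)} predictors "
            f"({len(self.candidates)} models, n={self.n})",
            f"{'predictor':>12} {'coef':>10} {'SE':>10} {'sum(w)':>8}",
        ]
        for p in self.predictors:
            lines.append(
                f"{p:>12} {self.averaged_coef[p]:>10.4f} "
                f"{self.averaged_se[p]:>10.4f} {self.sum_weights[p]:>8.3f}"
            )
        return "\n".join(lines)


def _ols_fit(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS coefficients, their SEs, and the Gaussian log-likelihood."""
    n = y.size
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    xtx_inv = np.linalg.pinv(x.T @ x)
    se = np.sqrt(np.diag(xtx_inv) * rss / (n - x.shape[1]))
    return beta, se, ll


def fit_all_subsets(
    df: pd.DataFrame,
    response: str,
    predictors=("diversity",) + ENV_PREDICTORS,
    confidence: float = 0.95,
    standardize: bool = True,
) -> ModelSet:
    """Fit every predictor subset by OLS and average over the AICc set.

    Predictors are z-scored (so coefficients are comparable across fits and
    continents); the intercept is always included. AICc = AIC +
    2K(K+1)/(n-K-1) with K counting coefficients plus the error variance.
    Akaike weights w_m = exp(-delta_m/2) normalised over all candidates.
    Averaging uses the smallest set of top models whose cumulative weight
    reaches `confidence`, with full-model (zero-substitution) averaging and
    unconditional standard errors.
    """
    predictors = tuple(predictors)
    data = df[[response, *predictors]].dropna()
    n = len(data)
    k_max = len(predictors) + 2
    if n <= k_max + 2:
        raise ValueError(f"n={n} too small for AICc with {len(predictors)} predictors")

    y = data[response].to_numpy(dtype=float)
    xmat = data[list(predictors)].to_numpy(dtype=float)
    if standardize:
        xmat = (xmat - xmat.mean(0)) / xmat.std(0, ddof=1)

    rows = []
    for r in range(len(predictors) + 1):
        for combo in itertools.combinations(range(len(predictors)), r):
            x = np.column_stack([np.ones(n), xmat[:, combo]]) if combo else np.ones((n, 1))
            beta, se, ll = _ols_fit(y, x)
            k = len(combo) + 2  # intercept + slopes + sigma^2
            aic = -2 * ll + 2 * k
            aicc = aic + 2 * k * (k + 1) / (n - k - 1)
            rows.append({
                "terms": tuple(predictors[i] for i in combo),
                "k": k, "loglik": ll, "aicc": aicc,
                "coef": dict(zip((predictors[i] for i in combo), beta[1:])),
                "se": dict(zip((predictors[i] for i in combo), se[1:])),
            })
    cand = pd.DataFrame(rows)
    cand["delta"] = cand["aicc"] - cand["aicc"].min()
    cand["weight"] = akaike_weights(cand["aicc"])
    # Deterministic ordering: AICc, then fewer parameters, then term names.
    cand = cand.sort_values(
        ["aicc", "k", "terms"], key=lambda s: s.map(str) if s.name == "terms" else s
    ).reset_index(drop=True)

    cum = cand["weight"].cumsum()
    in_set = np.zeros(len(cand), dtype=bool)
    first_over = int(np.argmax(cum.to_numpy() >= confidence))
    in_set[: first_over + 1] = True
    cand["in_set"] = in_set

    sel = cand[cand["in_set"]]
    wsel = sel["weight"].to_numpy()
    wsel = wsel / wsel.sum()
    averaged, avg_se, sumw = {}, {}, {}
    for p in predictors:
        b = np.array([m.get(p, 0.0) for m in sel["coef"]])
        s = np.array([m.get(p, 0.0) for m in sel["se"]])
        bbar = float(np.sum(wsel * b))
        averaged[p] = bbar
        avg_se[p] = float(np.sum(wsel * np.sqrt(s**2 + (b - bbar) ** 2)))
        sumw[p] = float(cand.loc[[p in t for t in cand["terms"]], "weight"].sum())

    return ModelSet(
        response=response, predictors=predictors, candidates=cand,
        averaged_coef=averaged, averaged_se=avg_se, sum_weights=sumw, n=n,
    )


# ---------------------------------------------------------------------------
# Simultaneous autoregressive error model


def knn_weights(coords: np.ndarray, k: int = 8) -> np.ndarray:
    """Row-standardised symmetric k-nearest-neighbour spatial weights.

    coords: (n, 2) array of (lat, lon) in degrees; neighbourhood from
    great-circle distance; adjacency symmetrised (i~j if either is among
    the other's k nearest) before row standardisation.
    """
    from .beta import haversine_km

    n = coords.shape[0]
    if n <= k:
        raise ValueError("need more points than neighbours")
    lat, lon = coords[:, 0], coords[:, 1]
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(d, np.inf)
    adj = np.zeros((n, n), dtype=bool)
    order = np.argsort(d, axis=1)[:, :k]
    adj[np.repeat(np.arange(n), k), order.ravel()] = True
    adj |= adj.T
    w = adj.astype(float)
    return w / w.sum(axis=1, keepdims=True)


@dataclass
class SAREResults:
    """ML fit of y = X beta + u, u = lambda W u + eps."""

    params: pd.Series
    bse: pd.Series
    lam: float
    llf: float
    llf_ols: float
    sigma2: float
    n: int

    def summary(self) -> str:
        lines = [
            f"SAR error model (ML), n={self.n}, lambda={self.lam:.4f}, "
            f"logLik={self.llf:.2f} (OLS logLik={self.llf_ols:.2f})",
            f"{'term':>12} {'coef':>10} {'SE':>10} {'z':>8}",
        ]
        for t in self.params.index:
            zval = self.params[t] / self.bse[t] if self.bse[t] > 0 else np.nan
            lines.append(f"{t:>12} {self.params[t]:>10.4f} {self.bse[t]:>10.4f} {zval:>8.2f}")
        return "\n".join(lines)


def _sar_loglik_parts(y, x, w_eigs, w, lam):
    n = y.size
    s = np.eye(n) - lam * w
    ys, xs = s @ y, s @ x
    beta, _, _, _ = np.linalg.lstsq(xs, ys, rcond=None)
    resid = ys - xs @ beta
    sigma2 = float(resid @ resid) / n
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + np.sum(np.log1p(-lam * w_eigs))
    return ll, beta, sigma2, xs


def fit_sar_error(
    y,
    x: pd.DataFrame,
    coords: np.ndarray,
    k_neighbors: int = 8,
    lam: float | None = None,
) -> SAREResults:
    """Maximum-likelihood simultaneous autoregressive error regression.

    The log-determinant term uses the eigenvalues of the symmetrised,
    row-standardised weight matrix (similarity-transformed so they are
    real). Pass lam=0.0 to constrain the spatial parameter, which
    reproduces OLS exactly.
    """
    ydat = np.asarray(y, dtype=float)
    names = ["const", *x.columns]
    xmat = np.column_stack([np.ones(ydat.size), x.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(xmat) < xmat.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    w = knn_weights(np.asarray(coords, dtype=float), k=k_neighbors)
    # W = D^-1 A with A symmetric: eigenvalues equal those of D^-1/2 A D^-1/2.
    deg = w.sum(axis=1)  # all ones after row standardisation; kept for clarity
    a = w * deg[:, None]
    dhalf = np.sqrt(a.sum(axis=1))
    w_eigs = np.linalg.eigvalsh(a / dhalf[:, None] / dhalf[None, :])

    ll_ols, *_ = _sar_loglik_parts(ydat, xmat, w_eigs, w, 0.0)

    if lam is None:
        lo = 1.0 / w_eigs.min() + 1e-6 if w_eigs.min() < 0 else -0.999
        res = minimize_scalar(
            lambda l: -_sar_loglik_parts(ydat, xmat, w_eigs, w, l)[0],
            bounds=(lo, 0.999), method="bounded",
            options={"xatol": 1e-8},
        )
        lam_hat = float(res.x)
    else:
        lam_hat = float(lam)

    ll, beta, sigma2, xs = _sar_loglik_parts(ydat, xmat, w_eigs, w, lam_hat)
    cov = sigma2 * ydat.size / (ydat.size - xmat.shape[1]) * np.linalg.pinv(xs.T @ xs)
    bse = np.sqrt(np.diag(cov))
    return SAREResults(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        lam=lam_hat, llf=float(ll), llf_ols=float(ll_ols),
        sigma2=sigma2, n=ydat.size,
    )


def simulate_sar_field(
    n: int = 150,
    lam: float = 0.6,
    beta=(1.0, 0.5),
    sigma: float = 1.0,
    k_neighbors: int = 8,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a SAR-error world for parameter-recovery checks.

    Returns a frame with response y, predictor x1, and (lat, lon) coords.
    """
    rng = np.random.default_rng(seed)
    coords = np.column_stack([rng.uniform(-5, 5, n), rng.uniform(-5, 5, n)])
    w = knn_weights(coords, k=k_neighbors)
    x1 = rng.standard_normal(n)
    eps = rng.normal(0, sigma, n)
    u = np.linalg.solve(np.eye(n) - lam * w, eps)
    y = beta[0] + beta[1] * x1 + u
    return pd.DataFrame({"y": y, "x1": x1, "lat": coords[:, 0], "lon": coords[:, 1]}), coords


# ---------------------------------------------------------------------------
# Continental summaries and structural correlates


def _tukey_letters(groups: list[str], reject: dict[frozenset, bool]) -> dict[str, str]:
    """Compact letter display from pairwise significance decisions."""
    letters: dict[str, str] = {g: "" for g in groups}
    cliques: list[set[str]] = []
    for g in groups:
        placed = False
        for clique in cliques:
            if all(not reject.get(frozenset((g, h)), False) for h in clique):
                clique.add(g)
                placed = True
        if not placed:
            cliques.append({g})
    # merge-proof: drop cliques contained in others
    cliques = [c for i, c in enumerate(cliques)
               if not any(c < d for j, d in enumerate(cliques) if i != j)]
    for label, clique in zip("ABCDEFGHIJ", cliques):
        for g in clique:
            letters[g] += label
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def continent_summaries(
    df: pd.DataFrame,
    value: str,
    group: str = "continent",
    transform: str | None = None,
    n_boot: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Group means with percentile bootstrap CIs and Tukey grouping letters.

    CIs are for the mean on the original scale; the ANOVA and Tukey
    comparisons run on the transformed scale ("log", "sqrt" or None) to
    meet model assumptions.
    """
    data = df[[group, value]].dropna()
    names = sorted(data[group].unique())
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    rng = np.random.default_rng(seed)

    rows = []
    for g in names:
        v = data.loc[data[group] == g, value].to_numpy(dtype=float)
        if v.size < 5:
            raise ValueError(f"group {g} has fewer than 5 observations")
        boot = rng.choice(v, size=(n_boot, v.size), replace=True).mean(axis=1)
        lo, hi = np.percentile(boot, [2.5, 97.5])
        rows.append({group: g, "n": v.size, "mean": float(v.mean()),
                     "ci_lo": float(lo), "ci_hi": float(hi)})
    out = pd.DataFrame(rows)

    tv = data[value].to_numpy(dtype=float)
    if transform == "log":
        tv = np.log(tv)
    elif transform == "sqrt":
        tv = np.sqrt(tv)
    elif transform is not None:
        raise ValueError("transform must be None, 'log' or 'sqrt'")
    tk = pairwise_tukeyhsd(tv, data[group].to_numpy(), alpha=0.05)
    pair_order = list(itertools.combinations(tk.groupsunique, 2))
    reject = {frozenset(pair): bool(rej) for pair, rej in zip(pair_order, tk.reject)}
    letters = _tukey_letters(names, reject)
    out["tukey_group"] = out[group].map(letters)
    return out


def structural_correlates(carbon: pd.DataFrame, diversity: pd.DataFrame) -> pd.DataFrame:
    """Kendall correlations of carbon and richness with stand structure.

    Eight rows: {carbon, richness} x {basal_area, ba_weighted_wd,
    stem_density, size_inequality}.
    """
    merged = carbon.merge(diversity, on="unit_id", suffixes=("", "_div"))
    if merged.empty:
        raise ValueError("no matching unit_id keys")
    rows = []
    for response in ("carbon", "richness"):
        for attr in ("basal_area", "ba_weighted_wd", "stem_density", "size_inequality"):
            sub = merged[[response, attr]].dropna()
            tau, p = kendall_tau(sub[response], sub[attr])
            rows.append({"response": response, "attribute": attr,
                         "tau": tau, "p": p, "n": len(sub)})
    return pd.DataFrame(rows)
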