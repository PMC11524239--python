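"""Variance components, heritability, genetic correlations, breeding values.

The mixed model is ``y = X m + Z1 b + Z2 f + e`` (fixed effects plus
random block and family effects) or its genomic analogue with a single
random effect whose covariance is sigma2_g * K.  Variance components are
estimated by REML: the residual variance is profiled out and the
restricted log-likelihood maximized over log variance ratios
(bounded scalar search for one component, Nelder-Mead with a coarse
grid start for several).  The genomic model is solved in the
eigenbasis of K so the whole fit is a one-dimensional search.

Open-pollinated (half-sib) families are related by more than the ideal
1/4, so narrow-sense heritability uses the conventional open-pollination
multiplier 2.5 (configurable): h2 = 2.5 sigma2_f / (sigma2_f + sigma2_b
+ sigma2_e), and analogously 2.5 sigma2_g / (sigma2_g + sigma2_e) for
the SNP-based model.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, eigh

from .io import log_kv

_LOG_GAMMA_MIN, _LOG_GAMMA_MAX = -25.0, 12.0
_BOUNDARY_GAMMA = 1e-8


class REMLConvergenceError(RuntimeError):
    def __init__(self, msg, best=None):
        super().__init__(msg)
        self.best = best


@dataclass
class RandomEffect:
    """One random term: either an incidence matrix Z (iid levels) or a
    covariance matrix K (correlated effect, e.g. genomic)."""

    name: str
    Z: np.ndarray | None = None
    K: np.ndarray | None = None
    levels: list | None = None

    def gram(self) -> np.ndarray:
        if self.K is not None:
            return np.asarray(self.K, dtype=float)
        return self.Z @ self.Z.T


@dataclass
class MixedModelSpec:
    y: np.ndarray
    X: np.ndarray
    random: list[RandomEffect]

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X rows must match y")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("X must have full column rank")


@dataclass
class VarianceComponents:
    kind: str                       # "pedigree" | "genomic"
    components: dict                # name -> sigma^2
    sigma2_e: float
    loglik: float
    converged: bool = True
    boundary: dict = field(default_factory=dict)   # name -> bool

    def total(self) -> float:
        return sum(self.components.values()) + self.sigma2_e


@dataclass
class REMLResult:
    vc: VarianceComponents
    beta: np.ndarray
    blups: dict                      # name -> (levels, values) arrays
    n_dropped: int = 0


def incidence(labels) -> RandomEffect:
    """Build a 0/1 incidence random effect from a label vector."""
    labels = np.asarray(labels)
    levels, idx = np.unique(labels, return_inverse=True)
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), idx] = 1.0
    return RandomEffect(name="", Z=Z, levels=list(levels))


def reml_loglik(y: np.ndarray, X: np.ndarray, effects: list[RandomEffect],
                components: dict, sigma2_e: float) -> float:
    """Restricted log-likelihood at fixed variance components.

    ll = -1/2 [ log|V| + log|X' V^-1 X| + y' P y + (n-p) log 2 pi ]
    with V = sum sigma2_k G_k + sigma2_e I.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    V = sigma2_e * np.eye(n)
    for re_ in effects:
        V = V + components[re_.name] * re_.gram()
    c, low = cho_factor(V, lower=True)
    logdet_V = 2 * np.log(np.diag(c)).sum()
    Vi_X = cho_solve((c, low), X)
    Vi_y = cho_solve((c, low), y)
    XtViX = X.T @ Vi_X
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    yPy = y @ Vi_y - (X.T @ Vi_y) @ beta
    return -0.5 * (logdet_V + logdet_XtViX + yPy + (n - p) * math.log(2 * math.pi))


class _HSolver:
    """Solve with H = I + sum gamma_k G_k and compute log|H|.

    When every random term is an incidence (Z) term, H is a low-rank
    update of the identity and Woodbury reduces every solve to the
    total number of random levels; otherwise dense Cholesky is used.
    """

    def __init__(self, effects: list[RandomEffect], grams, gammas):
        self.ok = True
        if all(r.Z is not None for r in effects):
            Zs = [r.Z * math.sqrt(g) for r, g in zip(effects, gammas) if g > 0]
            if Zs:
                Zall = np.hstack(Zs)
                C = np.eye(Zall.shape[1]) + Zall.T @ Zall
                try:
                    self._c = cho_factor(C, lower=True)
                except np.linalg.LinAlgError:
                    self.ok = False
                    return
                self._Z = Zall
                self.logdet = 2 * np.log(np.diag(self._c[0])).sum()
            else:
                self._Z = None
                self.logdet = 0.0
            self._dense = None
        else:
            n = grams[0].shape[0]
            H = np.eye(n)
            for g, G in zip(gammas, grams):
                H = H + g * G
            try:
                self._dense = cho_factor(H, lower=True)
            except np.linalg.LinAlgError:
                self.ok = False
                return
            self.logdet = 2 * np.log(np.diag(self._dense[0])).sum()

    def solve(self, B: np.ndarray) -> np.ndarray:
        if self._dense is not None:
            return cho_solve(self._dense, B)
        if self._Z is None:
            return B
        return B - self._Z @ cho_solve(self._c, self._Z.T @ B)


def _profiled_neg2(theta: np.ndarray, y, X, effects, grams):
    """-2 x profiled restricted log-likelihood (up to a constant) at
    gamma = exp(theta), with sigma2_e profiled out."""
    n, p = X.shape
    gammas = [math.exp(t) for t in theta]
    sol = _HSolver(effects, grams, gammas)
    if not sol.ok:
        return np.inf
    Hi_X = sol.solve(X)
    Hi_y = sol.solve(y)
    XtHiX = X.T @ Hi_X
    sign, logdet_XtHiX = np.linalg.slogdet(XtHiX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtHiX, X.T @ Hi_y)
    q = y @ Hi_y - (X.T @ Hi_y) @ beta
    if q <= 0:
        return np.inf
    return (n - p) * math.log(q / (n - p)) + sol.logdet + logdet_XtHiX


def fit_reml(spec: MixedModelSpec, kind: str = "pedigree",
             maxiter: int = 4000) -> REMLResult:
    """REML estimates, BLUPs and restricted log-likelihood.

    One random term uses a bounded golden-section/Brent search over the
    log variance ratio; several use Nelder-Mead started from the best
    point of a coarse grid.  A component shrinking to the lower bound is
    reported as 0 with its boundary flag set.
    """
    keep = np.isfinite(spec.y)
    n_dropped = int((~keep).sum())
    y = spec.y[keep]
    X = spec.X[keep]
    effects = [RandomEffect(r.name,
                            None if r.Z is None else r.Z[keep],
                            None if r.K is None else r.K[np.ix_(keep, keep)],
                            r.levels)
               for r in spec.random]
    n, p = X.shape
    k = len(effects)
    if n <= p + k:
        raise ValueError("too few observations for the model")
    grams = [r.gram() for r in effects]

    obj = lambda th: _profiled_neg2(np.atleast_1d(th), y, X, effects, grams)
    if k == 1:
        res = optimize.minimize_scalar(
            lambda t: obj([t]), bounds=(_LOG_GAMMA_MIN, _LOG_GAMMA_MAX),
            method="bounded", options={"xatol": 1e-11, "maxiter": maxiter})
        theta = np.array([res.x])
        success = res.success
    else:
        grid = [-6.0, -2.0, 0.0, 2.0]
        best_t, best_v = None, np.inf
        for t in np.array(np.meshgrid(*[grid] * k)).reshape(k, -1).T:
            v = obj(t)
            if v < best_v:
                best_t, best_v = t, v
        res = optimize.minimize(obj, best_t, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": maxiter, "maxfev": maxiter})
        theta = np.asarray(res.x)
        success = res.success
        if not success:
            # a component drifting to the boundary leaves NM on a flat
            # plateau; snap near-boundary coordinates and retry once
            snapped = np.where(theta < -10.0, _LOG_GAMMA_MIN, theta)
            if obj(snapped) <= res.fun + 1e-8:
                theta, success = snapped, True
            else:
                res2 = optimize.minimize(
                    obj, theta, method="Nelder-Mead",
                    options={"xatol": 1e-8, "fatol": 1e-10,
                             "maxiter": maxiter, "maxfev": maxiter})
                theta, success = np.asarray(res2.x), res2.success
    if not np.isfinite(obj(theta)):
        raise REMLConvergenceError("REML objective not finite at optimum",
                                   best=theta)

    gammas = np.exp(np.clip(theta, _LOG_GAMMA_MIN, _LOG_GAMMA_MAX))
    boundary = {r.name: g < _BOUNDARY_GAMMA for r, g in zip(effects, gammas)}
    gammas = np.where(gammas < _BOUNDARY_GAMMA, 0.0, gammas)

    sol = _HSolver(effects, grams, gammas)
    Hi_X = sol.solve(X)
    Hi_y = sol.solve(y)
    XtHiX = X.T @ Hi_X
    beta = np.linalg.solve(XtHiX, X.T @ Hi_y)
    q = y @ Hi_y - (X.T @ Hi_y) @ beta
    sigma2_e = q / (n - p)
    components = {r.name: float(g * sigma2_e) for r, g in zip(effects, gammas)}
    ll = reml_loglik(y, X, effects, components, sigma2_e)

    # BLUPs: u_k = sigma2_k M_k' V^-1 (y - X beta)
    Vi_r = sol.solve(y - X @ beta) / sigma2_e
    blups = {}
    for r_eff in effects:
        s2 = components[r_eff.name]
        if r_eff.Z is not None:
            u = s2 * (r_eff.Z.T @ Vi_r)
            blups[r_eff.name] = (r_eff.levels, u)
        else:
            blups[r_eff.name] = (None, s2 * (r_eff.gram() @ Vi_r))

    vc = VarianceComponents(kind, components, float(sigma2_e), float(ll),
                            converged=bool(success), boundary=boundary)
    if not success:
        raise REMLConvergenceError(
            "REML did not converge", best=REMLResult(vc, beta, blups, n_dropped))
    log_kv("fit_reml", kind=kind, loglik=round(ll, 4),
           **{f"sigma2_{k_}": round(v, 6) for k_, v in components.items()},
           sigma2_e=round(float(sigma2_e), 6))
    return REMLResult(vc, beta, blups, n_dropped)


def fit_reml_genomic(y: np.ndarray, X: np.ndarray, K: np.ndarray,
                     eig: tuple[np.ndarray, np.ndarray] | None = None,
                     ) -> tuple[REMLResult, tuple[np.ndarray, np.ndarray]]:
    """Genomic REML (V = sigma2_g K + sigma2_e I) via the eigenbasis of K.

    Rotating by the eigenvectors U makes V diagonal, reducing the fit to
    a 1-D search over the ratio sigma2_g / sigma2_e.  Returns the fit and
    the (eigenvalues, U) pair for reuse (e.g. by a GWAS scan).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    keep = np.isfinite(y)
    y, X = y[keep], X[keep]
    if eig is None or not keep.all():
        d, U = eigh(np.asarray(K, dtype=float)[np.ix_(keep, keep)])
        d = np.clip(d, 0.0, None)
    else:
        d, U = eig
    n, p = X.shape
    yr = U.T @ y
    Xr = U.T @ X

    def neg2(theta: float) -> float:
        lam = math.exp(theta)
        w = 1.0 / (1.0 + lam * d)
        XtWX = (Xr * w[:, None]).T @ Xr
        sign, logdet_XtWX = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtWX, (Xr * w[:, None]).T @ yr)
        r = yr - Xr @ beta
        q = float(r @ (w * r))
        if q <= 0:
            return np.inf
        logdet_H = float(np.log1p(lam * d).sum())
        return (n - p) * math.log(q / (n - p)) + logdet_H + logdet_XtWX

    res = optimize.minimize_scalar(neg2, bounds=(_LOG_GAMMA_MIN, _LOG_GAMMA_MAX),
                                   method="bounded", options={"xatol": 1e-11})
    lam = math.exp(res.x)
    boundary = lam < _BOUNDARY_GAMMA
    if boundary:
        lam = 0.0
    w = 1.0 / (1.0 + lam * d)
    XtWX = (Xr * w[:, None]).T @ Xr
    beta = np.linalg.solve(XtWX, (Xr * w[:, None]).T @ yr)
    r = yr - Xr @ beta
    sigma2_e = float(r @ (w * r)) / (n - p)
    sigma2_g = lam * sigma2_e
    eff = [RandomEffect("g", K=np.asarray(K, dtype=float)[np.ix_(keep, keep)])]
    ll = reml_loglik(y, X, eff, {"g": sigma2_g}, sigma2_e)
    # GBLUP individual genetic values
    Vi_r = (U @ (w * (U.T @ (y - X @ beta)))) / sigma2_e
    gblup = sigma2_g * (eff[0].K @ Vi_r)
    vc = VarianceComponents("genomic", {"g": float(sigma2_g)}, sigma2_e,
                            float(ll), True, {"g": boundary})
    log_kv("fit_reml_genomic", sigma2_g=round(sigma2_g, 6),
           sigma2_e=round(sigma2_e, 6), loglik=round(float(ll), 4))
    return REMLResult(vc, beta, {"g": (None, gblup)}), (d, U)


# ---------------------------------------------------------------------------
# heritability and genetic correlation
# ---------------------------------------------------------------------------

@dataclass
class HeritabilityEstimate:
    trait: str
    site_scope: str
    method: str          # "pedigree" | "snp"
    h2: float
    coefficient: float
    warning: bool = False


def heritability_pedigree(vc: VarianceComponents, coefficient: float = 2.5,
                          trait: str = "", site_scope: str = "pooled",
                          ) -> HeritabilityEstimate:
    """h2 = c * sigma2_f / (sigma2_f + sigma2_b + sigma2_e)."""
    if vc.kind != "pedigree":
        raise ValueError("pedigree-kind variance components required")
    s2f = vc.components.get("family", 0.0)
    s2b = vc.components.get("block", 0.0)
    denom = s2f + s2b + vc.sigma2_e
    if denom <= 0:
        raise ValueError("zero phenotypic variance")
    h2 = coefficient * s2f / denom
    warn = h2 > 1
    if warn:
        warnings.warn(f"h2 = {h2:.3f} > 1 for trait {trait!r}")
    return HeritabilityEstimate(trait, site_scope, "pedigree", float(h2),
                                coefficient, warn)


def heritability_snp(vc: VarianceComponents, coefficient: float = 2.5,
                     trait: str = "", site_scope: str = "pooled",
                     ) -> HeritabilityEstimate:
    """h2_SNP = c * sigma2_g / (sigma2_g + sigma2_e)."""
    if vc.kind != "genomic":
        raise ValueError("genomic-kind variance components required")
    s2g = vc.components.get("g", 0.0)
    denom = s2g + vc.sigma2_e
    if denom <= 0:
        raise ValueError("zero phenotypic variance")
    h2 = coefficient * s2g / denom
    warn = h2 > 1
    if warn:
        warnings.warn(f"h2_SNP = {h2:.3f} > 1 for trait {trait!r}")
    return HeritabilityEstimate(trait, site_scope, "snp", float(h2),
                                coefficient, warn)


@dataclass
class GeneticCorrelationEstimate:
    trait_i: str
    trait_j: str
    method: str
    r_g: float
    components: dict = field(default_factory=dict)


def genetic_correlation_pedigree(y_i: np.ndarray, y_j: np.ndarray,
                                 X: np.ndarray, random: list[RandomEffect],
                                 family_name: str = "family",
                                 printed_denominator: bool = False,
                                 names: tuple[str, str] = ("i", "j"),
                                 ) -> GeneticCorrelationEstimate:
    """Family-effect correlation via the sum-trait variance identity.

    cov_f(i, j) = [var_f(i + j) - var_f(i) - var_f(j)] / 2, each variance
    from a univariate REML fit with the same design.  The default
    denominator is sqrt(var_f(i) * var_f(j)); ``printed_denominator``
    switches to sqrt(var_f(i) + var_f(j)).
    """
    y_i = np.asarray(y_i, dtype=float).ravel()
    y_j = np.asarray(y_j, dtype=float).ravel()
    fits = {}
    for key, y in (("i", y_i), ("j", y_j), ("sum", y_i + y_j)):
        fits[key] = fit_reml(MixedModelSpec(y, X, random)).vc
    vi = fits["i"].components[family_name]
    vj = fits["j"].components[family_name]
    vs = fits["sum"].components[family_name]
    if vi <= 0 or vj <= 0:
        raise ValueError("zero family variance: genetic correlation undefined")
    cov = (vs - vi - vj) / 2.0
    denom = math.sqrt(vi + vj) if printed_denominator else math.sqrt(vi * vj)
    return GeneticCorrelationEstimate(
        names[0], names[1], "pedigree", float(cov / denom),
        {"cov_f": cov, "var_f_i": vi, "var_f_j": vj})


def genetic_correlation_snp(beta_i: np.ndarray, beta_j: np.ndarray,
                            names: tuple[str, str] = ("i", "j"),
                            ) -> GeneticCorrelationEstimate:
    """Uncentered correlation of per-SNP effect vectors:
    r_g = [sum(b_i b_j)/m] / sqrt([sum(b_i^2)/m][sum(b_j^2)/m])."""
    beta_i = np.asarray(beta_i, dtype=float).ravel()
    beta_j = np.asarray(beta_j, dtype=float).ravel()
    if beta_i.shape != beta_j.shape:
        raise ValueError("effect vectors must have equal length")
    m = beta_i.size
    ni, nj = (beta_i ** 2).sum() / m, (beta_j ** 2).sum() / m
    if ni == 0 or nj == 0:
        raise ValueError("zero-norm effect vector")
    r = ((beta_i * beta_j).sum() / m) / math.sqrt(ni * nj)
    return GeneticCorrelationEstimate(names[0], names[1], "snp", float(r),
                                      {"m": m})


# ---------------------------------------------------------------------------
# breeding values
# ---------------------------------------------------------------------------

def breeding_values(pheno: pd.DataFrame, design: pd.DataFrame,
                    traits: list[str]) -> pd.DataFrame:
    """Family breeding values BV = G + GxE per trait and site.

    G is the family main-effect BLUP from the pooled fit (fixed intercept
    + site, random block, family and family-by-site when several sites
    exist); GxE is the family-by-site BLUP (0 for a single site, so
    BV = G exactly).  Standardized BVs are z-scores across families
    within each trait x site.
    """
    df = design.merge(pheno, on="individual_id")
    sites = sorted(df["site_id"].unique())
    multi = len(sites) > 1
    X = np.column_stack([np.ones(len(df))]
                        + [(df["site_id"] == s).astype(float).to_numpy()
                           for s in sites[1:]])
    re_block = incidence(df["block_id"])
    re_block.name = "block"
    re_family = incidence(df["family_id"])
    re_family.name = "family"
    random = [re_block, re_family]
    if multi:
        re_fs = incidence(df["family_id"] + "|" + df["site_id"])
        re_fs.name = "family_site"
        random.append(re_fs)

    rows = []
    for trait in traits:
        fit = fit_reml(MixedModelSpec(df[trait].to_numpy(), X, random))
        fam_levels, fam_u = fit.blups["family"]
        g = dict(zip(fam_levels, fam_u))
        gxe = {}
        if multi:
            fs_levels, fs_u = fit.blups["family_site"]
            gxe = dict(zip(fs_levels, fs_u))
        for site in sites:
            for fam in fam_levels:
                key = f"{fam}|{site}"
                missing_fs = multi and key not in gxe
                ge = 0.0 if not multi else gxe.get(key, 0.0)
                rows.append({"trait": trait, "family": fam, "site": site,
                             "G": g[fam], "GxE": ge, "BV": g[fam] + ge,
                             "flag": "no_site_data" if missing_fs else ""})
    out = pd.DataFrame(rows)
    # standardize across families within trait x site
    def _std(s):
        sd = s.std(ddof=1)
        return (s - s.mean()) / sd if sd > 0 else s * 0.0
    out["BV_std"] = out.groupby(["trait", "site"])["BV"].transform(_std)
    return out


# ---------------------------------------------------------------------------
# trait summaries (correlation matrix, PCA, spatial tables)
# ---------------------------------------------------------------------------

def summarize_traits(trait_df: pd.DataFrame,
                     trait_cols: list[str] | None = None) -> dict:
    """Pearson correlations, PCA on standardized traits, spatial tables."""
    from sklearn.decomposition import PCA

    from .datatypes import TRAIT_NAMES
    cols = trait_cols or [c for c in TRAIT_NAMES if c in trait_df.columns]
    data = trait_df[cols].dropna()
    if len(data) < 3:
        raise ValueError("need >= 3 complete rows")
    constant = [c for c in cols if data[c].std(ddof=0) == 0]
    if constant:
        warnings.warn(f"constant traits (correlation undefined): {constant}")
    corr = data.corr()
    use = [c for c in cols if c not in constant]
    z = (data[use] - data[use].mean()) / data[use].std(ddof=1)
    pca = PCA()
    scores = pca.fit_transform(z.to_numpy())
    loadings = pd.DataFrame(pca.components_.T, index=use,
                            columns=[f"PC{i+1}" for i in range(len(use))])
    spatial = {}
    if {"x", "y"}.issubset(trait_df.columns):
        for c in cols:
            spatial[c] = trait_df[["x", "y", c]].dropna()
    return {"correlation": corr,
            "pca_variance_fraction": pca.explained_variance_ratio_,
            "pca_loadings": loadings,
            "pca_scores": scores,
            "constant_traits": constant,
            "spatial": spatial}
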