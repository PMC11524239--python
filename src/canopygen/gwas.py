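"""SNP QC, Yang kinship and the kinship-corrected GLS association scan.

The scan follows the population-parameters-previously-determined
(EMMAX/P3D) scheme: polygenic and residual variances are estimated once
per trait under the no-SNP null with V = sigma2_g K + sigma2_e I, then
every SNP is tested by generalized least squares with V held fixed.  One
eigendecomposition of K serves the whole scan.  Significance uses fixed
-log10 p thresholds (defaults 4 and 5 for the 0.05 and 0.01 classes).
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import eigh

from .datatypes import GenotypeMatrix
from .io import log_kv
from .quantgen import fit_reml_genomic

_P_FLOOR = 1e-300


@dataclass
class QcReport:
    n_input: int
    n_non_biallelic: int = 0
    n_low_call_rate: int = 0
    n_low_maf: int = 0
    n_imputed: int = 0
    n_retained: int = 0

    def conserves(self) -> bool:
        return (self.n_non_biallelic + self.n_low_call_rate
                + self.n_low_maf + self.n_retained) == self.n_input


def qc_filter(geno: GenotypeMatrix, maf_min: float = 0.05,
              call_rate_min: float = 0.9,
              n_non_biallelic: int = 0) -> tuple[GenotypeMatrix, QcReport]:
    """Call-rate then MAF filter; remaining missing calls mean-imputed.

    MAF is computed from non-missing calls.  SNP order is preserved.
    ``n_non_biallelic`` carries the count of multiallelic records already
    excluded at read time so the report still balances.
    """
    d = geno.dosage
    n, m = d.shape
    called = np.isfinite(d)
    call_rate = called.mean(axis=0)
    pass_cr = call_rate >= call_rate_min
    with np.errstate(invalid="ignore"):
        p_alt = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(p_alt, 1 - p_alt)
    pass_maf = pass_cr & (maf >= maf_min)
    report = QcReport(
        n_input=m + n_non_biallelic,
        n_non_biallelic=n_non_biallelic,
        n_low_call_rate=int((~pass_cr).sum()),
        n_low_maf=int((pass_cr & ~pass_maf).sum()),
        n_retained=int(pass_maf.sum()),
    )
    if report.n_retained == 0:
        raise ValueError("no SNPs retained after QC")
    out = geno.select_snps(pass_maf)
    missing = ~np.isfinite(out.dosage)
    report.n_imputed = int(missing.sum())
    if report.n_imputed:
        col_mean = np.nanmean(out.dosage, axis=0)
        idx = np.nonzero(missing)
        out.dosage[idx] = col_mean[idx[1]]
    log_kv("qc_filter", **report.__dict__)
    return out, report


def yang_kinship(geno: GenotypeMatrix) -> tuple[np.ndarray, int]:
    """GCTA 'Yang' genomic relationship matrix.

    Off-diagonal: A_jk = (1/m) sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2 p_i q_i).
    Diagonal:     A_jj = 1 + (1/m) sum_i (x_ij^2 - (1+2p_i) x_ij + 2 p_i^2)
                  / (2 p_i q_i).
    Monomorphic SNPs are skipped (count returned).  Requires imputed
    (missing-free) dosages.
    """
    d = geno.dosage
    if not np.all(np.isfinite(d)):
        raise ValueError("kinship requires imputed dosages (run qc_filter)")
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_skipped = int((~poly).sum())
    d = d[:, poly]
    p = p[poly]
    m = d.shape[1]
    if m == 0:
        raise ValueError("no polymorphic SNPs for kinship")
    denom = 2 * p * (1 - p)
    W = (d - 2 * p[None, :]) / np.sqrt(denom)[None, :]
    A = (W @ W.T) / m
    diag = 1.0 + ((d ** 2 - (1 + 2 * p)[None, :] * d + 2 * (p ** 2)[None, :])
                  / denom[None, :]).sum(axis=1) / m
    np.fill_diagonal(A, diag)
    log_kv("yang_kinship", n_individuals=A.shape[0], m_snps=m,
           skipped_monomorphic=n_skipped)
    return A, n_skipped


def gls_scan(y: np.ndarray, X: np.ndarray, geno: GenotypeMatrix,
             K: np.ndarray, sigma2_g: float | None = None,
             sigma2_e: float | None = None,
             eig: tuple[np.ndarray, np.ndarray] | None = None,
             ) -> pd.DataFrame:
    """Per-SNP GLS association test with fixed polygenic covariance.

    Null variance components are estimated once (unless supplied), then
    each SNP's dosage column augments X and the Wald statistic
    beta^2 / Var(beta) is referred to chi-square(1).  Everything is
    computed in the eigenbasis of K, one decomposition for the scan.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if len(y) != geno.n_individuals:
        raise ValueError("phenotype not aligned with genotype rows")
    if sigma2_g is None or sigma2_e is None:
        fit, eig = fit_reml_genomic(y, X, K, eig=eig)
        sigma2_g = fit.vc.components["g"]
        sigma2_e = fit.vc.sigma2_e
    if eig is None:
        d_eig, U = eigh(np.asarray(K, dtype=float))
        d_eig = np.clip(d_eig, 0.0, None)
    else:
        d_eig, U = eig
    w = 1.0 / (sigma2_g * d_eig + sigma2_e)

    yr = U.T @ y
    Xr = U.T @ X
    Gr = U.T @ geno.dosage
    # residualize y and every SNP against X under the GLS weights
    XtWX = (Xr * w[:, None]).T @ Xr
    XtWX_inv = np.linalg.inv(XtWX)
    proj = XtWX_inv @ (Xr * w[:, None]).T
    y_res = yr - Xr @ (proj @ yr)
    G_res = Gr - Xr @ (proj @ Gr)
    xWx = (w[:, None] * G_res ** 2).sum(axis=0)
    xWy = (w[:, None] * G_res * y_res[:, None]).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = xWy / xWx
        var_beta = 1.0 / xWx
    collinear = xWx <= 1e-10
    beta[collinear] = np.nan
    var_beta[collinear] = np.nan
    wald = beta ** 2 / var_beta
    p = stats.chi2.sf(wald, df=1)
    p = np.clip(p, _P_FLOOR, 1.0)
    p[collinear] = np.nan

    p_alt = geno.dosage.mean(axis=0) / 2.0
    maf = np.minimum(p_alt, 1 - p_alt)
    res = pd.DataFrame({
        "snp_id": geno.snps["snp_id"].to_numpy(),
        "scaffold_id": geno.snps["scaffold_id"].to_numpy(),
        "position": geno.snps["position"].to_numpy(),
        "maf": maf,
        "beta": beta,
        "se": np.sqrt(var_beta),
        "wald": wald,
        "p": p,
        "neglog10p": -np.log10(p),
        "flag": np.where(collinear, "collinear", ""),
    })
    log_kv("gls_scan", n_snps=len(res), sigma2_g=round(float(sigma2_g), 6),
           sigma2_e=round(float(sigma2_e), 6),
           n_collinear=int(collinear.sum()))
    return res


def classify_significance(results: pd.DataFrame, sig05: float = 4.0,
                          sig01: float = 5.0) -> pd.DataFrame:
    """Attach the significance class per the fixed -log10 p thresholds."""
    lp = results["neglog10p"]
    cls = np.where(lp > sig01, "sig01", np.where(lp > sig05, "sig05", "none"))
    cls = np.where(lp.isna(), "none", cls)
    out = results.copy()
    out["class"] = cls
    return out


def significant_sets(results_by_trait: dict[str, pd.DataFrame],
                     sig05: float = 4.0) -> tuple[dict[str, set], pd.DataFrame]:
    """Per-trait significant SNP sets and the cross-trait overlap counts
    (the input of an UpSet plot: one row per non-empty trait combination)."""
    sets = {t: set(df.loc[df["neglog10p"] > sig05, "snp_id"])
            for t, df in results_by_trait.items()}
    traits = sorted(sets)
    rows = []
    for r in range(1, len(traits) + 1):
        for combo in itertools.combinations(traits, r):
            inter = set.intersection(*(sets[t] for t in combo))
            outside = set.union(set(), *(sets[t] for t in traits
                                         if t not in combo))
            exclusive = inter - outside
            if exclusive:
                rows.append({"traits": "+".join(combo),
                             "n_traits": r, "n_snps": len(exclusive)})
    cols = ["traits", "n_traits", "n_snps"]
    return sets, (pd.DataFrame(rows, columns=cols) if rows
                  else pd.DataFrame(columns=cols))


def export_manhattan_table(results: pd.DataFrame, path=None,
                           scaffold_lengths: dict[str, float] | None = None,
                           ) -> pd.DataFrame:
    """Cumulative genome coordinates (scaffolds in input order) + classes.

    The output is sufficient to draw a Manhattan plot externally.
    """
    out = results.copy()
    order = list(dict.fromkeys(out["scaffold_id"]))
    if scaffold_lengths is None:
        scaffold_lengths = {sc: float(out.loc[out["scaffold_id"] == sc,
                                              "position"].max())
                            for sc in order}
    offset, offsets = 0.0, {}
    for sc in order:
        offsets[sc] = offset
        offset += scaffold_lengths.get(sc, 0.0)
    out["cumulative_position"] = (out["scaffold_id"].map(offsets)
                                  + out["position"])
    if "class" not in out.columns:
        out = classify_significance(out)
    cols = ["snp_id", "scaffold_id", "position", "cumulative_position",
            "neglog10p", "class"]
    table = out[cols]
    if path is not None:
        table.to_csv(path, index=False)
        log_kv("export_manhattan_table", path=path, n_snps=len(table))
    return table
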