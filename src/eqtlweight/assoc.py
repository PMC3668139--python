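"""Genotype QC and the per-SNP case-control association scan.

QC removes SNPs with excessive missingness (>= 5% by default), low minor
allele frequency (< 5%) or Hardy-Weinberg disequilibrium (1-df chi-square
p < 1e-5), mirroring standard GWAS marker filters.

The scan fits, for every SNP, an additive-dosage logistic regression of the
binary phenotype on genotype plus covariates and reports the two-sided Wald
p-value for the genotype coefficient.  Fitting is a *batched* iteratively
reweighted least squares across all SNPs simultaneously (the covariate block
is shared; only the genotype column differs), which is what makes
genome-scale permutation studies tractable.  Missing genotypes drop
individuals for that SNP only (zero IRLS weight).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AssocTable, GenotypeMatrix

__all__ = ["QcThresholds", "qc_filter", "hwe_test", "logistic_scan"]


@dataclass(frozen=True)
class QcThresholds:
    max_missing: float = 0.05
    min_maf: float = 0.05
    hwe_min_p: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("max_missing", "min_maf", "hwe_min_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def hwe_test(dosages: np.ndarray) -> np.ndarray:
    """Per-SNP 1-df chi-square Hardy-Weinberg test p-values.

    ``dosages`` is individuals x SNPs; monomorphic columns return p = 1.
    """
    d = np.asarray(dosages, dtype=float)
    obs = np.stack([(d == g).sum(axis=0) for g in (0.0, 1.0, 2.0)]).astype(float)
    n = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = (2 * obs[2] + obs[1]) / (2 * n)
        exp = np.stack([n * (1 - p_alt) ** 2, 2 * n * p_alt * (1 - p_alt), n * p_alt**2])
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0).sum(axis=0)
    pvals = stats.chi2.sf(chi2, df=1)
    mono = (p_alt <= 0) | (p_alt >= 1)
    return np.where(mono | (n == 0), 1.0, pvals)


def qc_filter(
    G: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop SNP columns violating any marker QC rule; log which rule(s) fired."""
    t = thresholds or QcThresholds()
    miss = G.missing_rate()
    maf = G.maf()
    hwe_p = hwe_test(G.dosages)
    rows = []
    keep = np.ones(G.n_snps, dtype=bool)
    for j, snp in enumerate(G.snps):
        reasons = []
        if miss[j] >= t.max_missing:
            reasons.append(f"missing >= {t.max_missing:g}")
        if np.isnan(maf[j]) or maf[j] < t.min_maf:
            reasons.append(f"MAF < {t.min_maf:g}")
        if hwe_p[j] < t.hwe_min_p:
            reasons.append(f"HWE p < {t.hwe_min_p:g}")
        if reasons:
            keep[j] = False
            rows.append({"snp_id": snp.snp_id, "reason": "; ".join(reasons)})
    log = pd.DataFrame(rows, columns=["snp_id", "reason"])
    return G.subset_snps(keep), log


def _expit(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def logistic_scan(
    G: GenotypeMatrix,
    y: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> AssocTable:
    """Additive logistic regression Wald scan across all SNPs.

    Returns an AssocTable with columns ``beta, se, z, p, converged``.  A SNP
    where the fit fails (separation, non-convergence, monomorphic column)
    carries a missing p flagged ``converged = False`` -- never a silent 0 or
    1.  An exactly collinear genotype/covariate pair raises.
    """
    if y is None:
        y = G.phenotype
    if y is None:
        raise ValueError("no phenotype supplied")
    y = np.asarray(y, dtype=float)
    uniq = np.unique(y[~np.isnan(y)])
    if not np.isin(uniq, (0.0, 1.0)).all() or len(uniq) != 2:
        raise ValueError("phenotype must be binary with both classes present")
    if covariates is None and G.covariates is not None:
        covariates = G.covariates
    n, m = G.dosages.shape
    C = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)]
    )
    c = C.shape[1]
    if np.linalg.matrix_rank(C) < c:
        raise ValueError("covariate matrix (with intercept) is rank deficient")

    g_raw = G.dosages
    mask = ~np.isnan(g_raw)
    g = np.where(mask, g_raw, 0.0)
    maskf = mask.astype(float)

    # structural checks before fitting
    n_used = maskf.sum(axis=0)
    var_g = np.full(m, np.nan)
    ok_n = n_used > c + 1
    with np.errstate(invalid="ignore"):
        mean_g = np.where(ok_n, (g * maskf).sum(axis=0) / np.maximum(n_used, 1), np.nan)
        var_g = ((g - mean_g[None, :]) ** 2 * maskf).sum(axis=0) / np.maximum(n_used, 1)
    monomorphic = ~ok_n | (var_g < 1e-12)
    # exact collinearity of genotype with the covariate block (complete rows)
    coef, *_ = np.linalg.lstsq(C, g, rcond=None)
    resid = g - C @ coef
    resid_norm = (resid**2 * maskf).sum(axis=0)
    collinear = (~monomorphic) & (resid_norm / np.maximum(var_g * n_used, 1e-300) < 1e-10)
    if collinear.any():
        j = int(np.flatnonzero(collinear)[0])
        raise ValueError(
            f"genotype column {G.snps[j].snp_id!r} is collinear with the covariates "
            "(rank deficiency)"
        )

    k = c + 1  # genotype coefficient is last
    beta = np.zeros((m, k))
    ybar = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    beta[:, 0] = np.log(ybar / (1 - ybar))
    active = ~monomorphic
    converged = np.zeros(m, dtype=bool)

    XtWX = np.zeros((m, k, k))
    rhs = np.zeros((m, k))
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if len(idx) == 0:
            break
        eta = C @ beta[idx, :c].T + g[:, idx] * beta[idx, c]
        mu = _expit(eta)
        w = mu * (1 - mu) * maskf[:, idx]
        w = np.maximum(w, 0.0)
        r = w * eta + (y[:, None] - mu) * maskf[:, idx]  # = W z
        gi = g[:, idx]
        A_cc = np.einsum("na,nm,nb->mab", C, w, C, optimize=True)
        A_cg = np.einsum("na,nm->ma", C, w * gi, optimize=True)
        A_gg = np.einsum("nm,nm->m", gi * w, gi, optimize=True)
        b_c = np.einsum("na,nm->ma", C, r, optimize=True)
        b_g = np.einsum("nm,nm->m", gi, r, optimize=True)
        XtWX_i = np.zeros((len(idx), k, k))
        XtWX_i[:, :c, :c] = A_cc
        XtWX_i[:, :c, c] = A_cg
        XtWX_i[:, c, :c] = A_cg
        XtWX_i[:, c, c] = A_gg
        rhs_i = np.concatenate([b_c, b_g[:, None]], axis=1)
        try:
            new = np.linalg.solve(XtWX_i, rhs_i[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new = np.full_like(rhs_i, np.nan)
            for t_i in range(len(idx)):
                try:
                    new[t_i] = np.linalg.solve(XtWX_i[t_i], rhs_i[t_i])
                except np.linalg.LinAlgError:
                    pass
        delta = np.nanmax(np.abs(new - beta[idx]), axis=1)
        bad = ~np.isfinite(new).all(axis=1) | (np.abs(new[:, c]) > 30)
        beta[idx] = np.where(np.isfinite(new), new, beta[idx])
        XtWX[idx] = XtWX_i
        rhs[idx] = rhs_i
        done = (delta < tol) & ~bad
        converged[idx[done]] = True
        active[idx[done]] = False
        active[idx[bad]] = False

    se = np.full(m, np.nan)
    fit_idx = np.flatnonzero(converged)
    if len(fit_idx):
        try:
            cov = np.linalg.inv(XtWX[fit_idx])
            se_g = np.sqrt(np.maximum(cov[:, k - 1, k - 1], 0.0))
        except np.linalg.LinAlgError:
            se_g = np.full(len(fit_idx), np.nan)
        se[fit_idx] = se_g
    huge_se = converged & (~np.isfinite(se) | (se > 100))
    converged = converged & ~huge_se

    z = np.where(converged, beta[:, c] / se, np.nan)
    p = np.where(converged, 2 * stats.norm.sf(np.abs(z)), np.nan)
    p = np.where(converged, np.clip(p, np.finfo(float).tiny, 1.0), np.nan)

    df = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in G.snps],
            "chrom": [s.chrom for s in G.snps],
            "pos": [s.pos for s in G.snps],
            "p": p,
            "beta": np.where(converged, beta[:, c], np.nan),
            "se": se,
            "z": z,
            "converged": converged,
        }
    )
    return AssocTable(df, validate=False)
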