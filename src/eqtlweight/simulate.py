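"""Synthetic GWAS data generation and the permutation FWER size study.

Genotypes are drawn in LD blocks: within a block every SNP shares the block
MAF and the block's haplotype alleles are thresholded equicorrelated
Gaussians, with the latent correlation calibrated (per block, by root
finding on the bivariate-normal orthant probability) so the *realized*
allele-level correlation matches the requested ``rho``.  Two independent
haplotypes per individual give Hardy-Weinberg genotypes marginally and
pairwise genotype correlation ``rho`` (hence haplotype r2 of about
``rho**2``) within blocks, independence across blocks.

Phenotypes follow a logistic model over the causal SNPs (a fair coin under
the complete null).  eQTL flags hit a target overall fraction while causal
SNPs' flag probability is multiplied by a configurable enrichment factor --
the informative-prior scenario weighting is designed for.

The size study permutes the phenotype among individuals (covariates stay
with their individuals, so the covariate-phenotype link is deliberately
broken), refits the scan, and counts replicates with at least one rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .assoc import logistic_scan
from .io import EqtlTable, GenotypeMatrix, SnpKey
from .multitest import bh_mask, bonferroni_mask, holm_mask
from .weights import WeightVector

__all__ = [
    "SimConfig",
    "SimulatedStudy",
    "simulate_study",
    "FwerEstimate",
    "fwer_permutation_study",
]


@dataclass
class SimConfig:
    """Study-generator settings (desk-scale defaults).

    ``rho`` is the target *allele-level* pairwise correlation within a block;
    ``eqtl_log10p_range`` draws eQTL p-values as ``10**(-U(lo, hi))``;
    ``causal_eqtl_enrichment`` multiplies a causal SNP's probability of being
    flagged as an eQTL.
    """

    n_individuals: int = 500
    n_snps: int = 2000
    block_size_range: tuple[int, int] = (5, 25)
    rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    eqtl_fraction: float = 0.106
    eqtl_log10p_range: tuple[float, float] = (4.0, 16.0)
    n_causal: int = 0
    effect_log_odds: float = 0.4
    causal_eqtl_enrichment: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.eqtl_fraction <= 1:
            raise ValueError("eqtl_fraction must lie in [0, 1]")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not 0 < lo <= hi < 1:
            raise ValueError("maf_range must satisfy 0 < lo <= hi < 1")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")


@dataclass
class SimulatedStudy:
    genotypes: GenotypeMatrix
    eqtl: EqtlTable | None
    eqtl_flags: np.ndarray
    causal_idx: np.ndarray
    config: SimConfig


def _latent_rho_for(target_r: float, maf: float) -> float:
    """Latent Gaussian correlation giving allele-level correlation ``target_r``
    for two equally-frequent thresholded alleles."""
    if target_r <= 0:
        return 0.0
    t = stats.norm.ppf(maf)
    q = maf

    def realized(rho_lat: float) -> float:
        if rho_lat >= 1.0:
            return 1.0
        p11 = stats.multivariate_normal(
            mean=[0, 0], cov=[[1, rho_lat], [rho_lat, 1]]
        ).cdf([t, t])
        return (p11 - q * q) / (q * (1 - q))

    hi = 1.0 - 1e-9
    if realized(hi) < target_r:
        raise ValueError(
            f"infeasible rho/MAF combination: target r={target_r} at MAF {maf:.3f}"
        )
    return float(optimize.brentq(lambda x: realized(x) - target_r, target_r * 0.5, hi,
                                 xtol=1e-6))


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Draw genotypes, phenotype, eQTL annotation and truth labels from ``cfg``.

    Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_individuals, cfg.n_snps

    # block structure
    sizes = []
    total = 0
    lo, hi = cfg.block_size_range
    while total < m:
        s = int(rng.integers(lo, hi + 1))
        sizes.append(min(s, m - total))
        total += sizes[-1]

    dosages = np.empty((n, m), dtype=float)
    mafs = np.empty(m)
    col = 0
    for s in sizes:
        maf = float(rng.uniform(*cfg.maf_range))
        rho_lat = _latent_rho_for(cfg.rho, maf) if s > 1 else 0.0
        t = stats.norm.ppf(maf)
        block = np.zeros((n, s))
        for _hap in range(2):
            shared = rng.standard_normal((n, 1))
            noise = rng.standard_normal((n, s))
            z = np.sqrt(rho_lat) * shared + np.sqrt(1 - rho_lat) * noise
            block += (z < t).astype(float)
        dosages[:, col : col + s] = block
        mafs[col : col + s] = maf
        col += s

    snps = [SnpKey(f"snp{j + 1}", chrom="1", pos=(j + 1) * 1000) for j in range(m)]

    # phenotype
    causal_idx = (
        np.sort(rng.choice(m, size=cfg.n_causal, replace=False))
        if cfg.n_causal
        else np.array([], dtype=int)
    )
    if cfg.n_causal:
        eta = (
            (dosages[:, causal_idx] - 2 * mafs[causal_idx][None, :])
            @ np.full(cfg.n_causal, cfg.effect_log_odds)
        )
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    else:
        y = (rng.random(n) < 0.5).astype(float)

    # eQTL flags with causal enrichment, preserving the overall target fraction
    p_causal = min(1.0, cfg.causal_eqtl_enrichment * cfg.eqtl_fraction)
    n_noncausal = m - cfg.n_causal
    if n_noncausal > 0:
        p_noncausal = (cfg.eqtl_fraction * m - p_causal * cfg.n_causal) / n_noncausal
        p_noncausal = float(np.clip(p_noncausal, 0.0, 1.0))
    else:
        p_noncausal = 0.0
    p_flag = np.full(m, p_noncausal)
    p_flag[causal_idx] = p_causal
    flags = rng.random(m) < p_flag

    eqtl = None
    if flags.any():
        loglo, loghi = cfg.eqtl_log10p_range
        log10p = rng.uniform(loglo, loghi, size=int(flags.sum()))
        p_eqtl = 10.0 ** (-log10p)
        chi2 = stats.chi2.isf(p_eqtl, df=1)
        lod = chi2 / (2 * np.log(10))
        eqtl = EqtlTable(
            pd.DataFrame(
                {
                    "snp_id": [snps[j].snp_id for j in np.flatnonzero(flags)],
                    "p_eqtl": p_eqtl,
                    "lod": lod,
                    "gene": [f"GENE{j + 1}" for j in np.flatnonzero(flags)],
                }
            ),
            collapsed=True,
        )

    G = GenotypeMatrix(dosages, snps, phenotype=y)
    return SimulatedStudy(
        genotypes=G, eqtl=eqtl, eqtl_flags=flags, causal_idx=causal_idx, config=cfg
    )


@dataclass
class FwerEstimate:
    """Monte-Carlo FWER estimate for one (weight scheme, procedure) pair."""

    scheme: str
    procedure: str
    alpha: float
    n_perm: int
    n_rejecting: int
    per_replicate: np.ndarray = field(repr=False)  # rejection count per permutation

    @property
    def fwer_hat(self) -> float:
        return self.n_rejecting / self.n_perm

    @property
    def mc_se(self) -> float:
        f = self.fwer_hat
        return float(np.sqrt(f * (1 - f) / self.n_perm))


def fwer_permutation_study(
    G: GenotypeMatrix,
    weights: dict[str, WeightVector],
    alpha: float = 0.05,
    n_perm: int = 500,
    seed: int = 0,
    procedures: tuple[str, ...] = ("bonferroni", "holm"),
    effective_ratio: float | None = None,
    covariates: np.ndarray | None = None,
    y: np.ndarray | None = None,
) -> list[FwerEstimate]:
    """Estimate the realized FWER of weighted procedures by phenotype permutation.

    Each permutation shuffles the phenotype among individuals, refits the
    logistic scan for every SNP, forms Q = p / w for every weight scheme, and
    applies each procedure at level ``alpha``; a replicate counts toward the
    FWER when at least one hypothesis is rejected (every rejection under
    permutation is a false positive).  Non-converged SNPs in a replicate
    cannot be rejected.
    """
    if y is None:
        y = G.phenotype
    if y is None:
        raise ValueError("no phenotype to permute")
    y = np.asarray(y, dtype=float)
    if not np.isin(np.unique(y), (0.0, 1.0)).all():
        raise ValueError("phenotype must be binary")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    for name, wv in weights.items():
        if not wv.normalized:
            raise ValueError(f"weight scheme {name!r} is not normalized")
        if wv.m != G.n_snps:
            raise ValueError(f"weight scheme {name!r} is not aligned with the genotypes")

    m = G.n_snps
    count = m * effective_ratio if effective_ratio is not None else float(m)
    rng = np.random.default_rng(seed)
    tallies = {
        (name, proc): np.zeros(n_perm, dtype=int)
        for name in weights
        for proc in procedures
    }
    for b in range(n_perm):
        y_perm = rng.permutation(y)
        scan = logistic_scan(G, y=y_perm, covariates=covariates)
        p = scan.p
        for name, wv in weights.items():
            with np.errstate(invalid="ignore"):
                q = np.where(np.isnan(p), np.inf, p / wv.w)
            for proc in procedures:
                if proc == "bonferroni":
                    mask = bonferroni_mask(q, alpha, count)
                elif proc == "holm":
                    mask = holm_mask(q, wv.w, alpha, count if effective_ratio else None)
                elif proc == "bh":
                    mask = bh_mask(q, alpha, count)
                else:
                    raise ValueError(f"unknown procedure {proc!r}")
                tallies[(name, proc)][b] = int(mask.sum())

    return [
        FwerEstimate(
            scheme=name,
            procedure=proc,
            alpha=alpha,
            n_perm=n_perm,
            n_rejecting=int((cnt > 0).sum()),
            per_replicate=cnt,
        )
        for (name, proc), cnt in tallies.items()
    ]
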