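"""Linkage disequilibrium: pairwise r2/D' from unphased genotypes, window
pruning, proxy extension and LD-aware novelty filtering.

Pairwise LD uses maximum-likelihood haplotype frequency estimation by EM over
the double-heterozygote phase ambiguity (the standard estimator for unphased
diploid data): initialize at linkage equilibrium, iterate expected haplotype
counts until the largest frequency change falls below ``tol`` (default 1e-8)
or 1000 iterations.  Individuals with a missing genotype at either SNP of a
pair are excluded pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, LdTable, SnpKey

__all__ = [
    "LdEstimate",
    "pairwise_ld",
    "ld_prune",
    "extend_with_proxies",
    "novel_hits",
    "NovelHitReport",
]


@dataclass
class LdEstimate:
    """Two-locus LD summary: r2, D' and the estimated haplotype frequencies
    (order AB, Ab, aB, ab where A/B are the dosage-counted alleles)."""

    r2: float
    dprime: float
    hap_freqs: np.ndarray
    n_used: int
    loglik_trace: list[float] = field(default_factory=list, repr=False)


def _hap_stats(freqs: np.ndarray) -> tuple[float, float]:
    pAB, pAb, paB, pab = freqs
    pA = pAB + pAb
    pB = pAB + paB
    D = pAB - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = 0.0 if denom <= 0 else D * D / denom
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = 0.0 if dmax <= 0 else abs(D) / dmax
    return float(min(r2, 1.0)), float(min(dprime, 1.0))


def _counts_3x3(g1: np.ndarray, g2: np.ndarray) -> tuple[np.ndarray, int]:
    mask = ~np.isnan(g1) & ~np.isnan(g2)
    a = g1[mask].astype(int)
    b = g2[mask].astype(int)
    c = np.zeros((3, 3), dtype=float)
    np.add.at(c, (a, b), 1.0)
    return c, int(mask.sum())


def em_haplotype_freqs(
    counts: np.ndarray, tol: float = 1e-8, max_iter: int = 1000
) -> tuple[np.ndarray, list[float]]:
    """EM haplotype frequencies from a 3x3 genotype-pair count table.

    ``counts[i, j]`` is the number of individuals with dosage ``i`` at the
    first SNP and ``j`` at the second.  Returns (frequencies, log-likelihood
    trace); the trace is non-decreasing.
    """
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    if n < 2:
        raise ValueError("need at least 2 individuals with complete data for the pair")
    # fixed haplotype contributions from unambiguous genotype pairs: outside
    # the double heterozygote, the two haplotypes are determined (any pairing
    # of alleles yields the same multiset)
    base = np.zeros(4)  # AB, Ab, aB, ab
    for i in range(3):
        for j in range(3):
            if i == 1 and j == 1:
                continue
            cnt = c[i, j]
            if cnt == 0:
                continue
            a_alleles = [1] * i + [0] * (2 - i)
            b_alleles = [1] * j + [0] * (2 - j)
            for a, b in zip(a_alleles, b_alleles):
                idx = (1 - a) * 2 + (1 - b)  # AB, Ab, aB, ab
                base[idx] += cnt
    n_dh = c[1, 1]  # double heterozygotes: AB/ab (cis) or Ab/aB (trans)
    pA = (2 * c[2, :].sum() + c[1, :].sum()) / (2 * n)
    pB = (2 * c[:, 2].sum() + c[:, 1].sum()) / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic SNP in the complete-data subsample; r2 undefined")
    freqs = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    trace: list[float] = []

    def loglik(f: np.ndarray) -> float:
        geno_prob = np.zeros((3, 3))
        fAB, fAb, faB, fab = f
        hap = {(1, 1): fAB, (1, 0): fAb, (0, 1): faB, (0, 0): fab}
        for (a1, b1), f1 in hap.items():
            for (a2, b2), f2 in hap.items():
                geno_prob[a1 + a2, b1 + b2] += f1 * f2
        with np.errstate(divide="ignore"):
            lg = np.where(c > 0, np.log(np.maximum(geno_prob, 1e-300)), 0.0)
        return float((c * lg).sum())

    for _ in range(max_iter):
        trace.append(loglik(freqs))
        fAB, fAb, faB, fab = freqs
        denom = fAB * fab + fAb * faB
        cis = 0.5 if denom == 0 else fAB * fab / denom
        counts_new = base + n_dh * np.array([cis, 1 - cis, 1 - cis, cis])
        new = counts_new / (2 * n)
        if np.max(np.abs(new - freqs)) < tol:
            freqs = new
            break
        freqs = new
    trace.append(loglik(freqs))
    return freqs, trace


def pairwise_ld(g1: np.ndarray, g2: np.ndarray, tol: float = 1e-8,
                max_iter: int = 1000) -> LdEstimate:
    """EM estimate of r2 and D' between two unphased genotype columns."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    counts, n_used = _counts_3x3(g1, g2)
    if n_used < 2:
        raise ValueError("fewer than 2 individuals with complete data for both SNPs")
    freqs, trace = em_haplotype_freqs(counts, tol=tol, max_iter=max_iter)
    r2, dprime = _hap_stats(freqs)
    return LdEstimate(r2=r2, dprime=dprime, hap_freqs=freqs, n_used=n_used,
                      loglik_trace=trace)


def _safe_r2(G: GenotypeMatrix, i: int, j: int, cache: dict) -> float:
    key = (i, j) if i < j else (j, i)
    if key in cache:
        return cache[key]
    try:
        r2 = pairwise_ld(G.dosages[:, key[0]], G.dosages[:, key[1]]).r2
    except ValueError:
        r2 = 0.0  # monomorphic / no data: cannot exceed any pruning threshold
    cache[key] = r2
    return r2


def ld_prune(
    G: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2max: float = 0.8,
) -> list[SnpKey]:
    """Greedy sliding-window pruning (PLINK ``--indep-pairwise`` style).

    Within each window placement every retained pair must satisfy
    ``r2 <= r2max``; offending pairs drop the member with the lower MAF
    (tie: the later position).  Windows advance by ``step`` SNPs; removed
    SNPs are never reconsidered.  Requires SNPs ordered by (chrom, pos).
    """
    m = G.n_snps
    pos = [s.pos for s in G.snps]
    chrom = [s.chrom for s in G.snps]
    if all(p is not None for p in pos):
        key = list(zip([str(c) for c in chrom], pos))
        if any(key[i][0] == key[i + 1][0] and key[i][1] > key[i + 1][1] for i in range(m - 1)):
            raise ValueError("SNPs must be ordered by (chrom, pos) before pruning")
    maf = G.maf()
    removed = np.zeros(m, dtype=bool)
    cache: dict = {}
    for start in range(0, max(1, m), step):
        idx = [i for i in range(start, min(start + window, m)) if not removed[i]]
        for a_pos in range(len(idx)):
            i = idx[a_pos]
            if removed[i]:
                continue
            for b_pos in range(a_pos + 1, len(idx)):
                j = idx[b_pos]
                if removed[i]:
                    break
                if removed[j]:
                    continue
                if _safe_r2(G, i, j, cache) > r2max:
                    # drop the lower-MAF member; tie -> the later position
                    if maf[i] < maf[j]:
                        drop = i
                    else:
                        drop = j
                    removed[drop] = True
        if start + window >= m:
            break
    return [G.snps[i] for i in range(m) if not removed[i]]


def extend_with_proxies(
    snps: set[str],
    ld: LdTable,
    r2min: float = 0.8,
    max_distance: float | None = 500_000,
) -> set[str]:
    """One-hop proxy extension: the input set plus every SNP with
    ``r2 >= r2min`` against some input SNP (no transitive closure).

    When the LD table records pair distances, proxies beyond ``max_distance``
    base pairs are not added; pairs with unknown distance are kept.
    """
    out = set(snps)
    for a in snps:
        for b, (r2, _dp, dist) in ld.partners(a).items():
            if r2 >= r2min and (
                max_distance is None or np.isnan(dist) or dist <= max_distance
            ):
                out.add(b)
    return out


@dataclass
class NovelHitReport:
    """Weighted-only hits screened for LD against the unweighted hit list."""

    table: pd.DataFrame  # snp_id, max_r2, has_ld_data, novel

    @property
    def novel(self) -> set[str]:
        return set(self.table.loc[self.table["novel"], "snp_id"])


def novel_hits(
    weighted_hits: set[str],
    unweighted_hits: set[str],
    ld: LdTable,
    r2: float = 0.4,
) -> NovelHitReport:
    """SNPs found only by the weighted procedure and not in LD (r2 < threshold,
    or no LD data) with any unweighted hit.

    Pairs absent from the LD table are treated as not-in-LD; such SNPs are
    reported as novel with ``has_ld_data = False`` so the missing-data caveat
    is visible.
    """
    rows = []
    for s in sorted(weighted_hits - set(unweighted_hits)):
        r2s = []
        for u in unweighted_hits:
            hit = ld.lookup(s, u)
            if hit is not None:
                r2s.append(hit[0])
        max_r2 = max(r2s) if r2s else np.nan
        rows.append(
            {
                "snp_id": s,
                "max_r2": max_r2,
                "has_ld_data": bool(r2s),
                "novel": (not r2s) or max_r2 < r2,
            }
        )
    table = pd.DataFrame(rows, columns=["snp_id", "max_r2", "has_ld_data", "novel"])
    return NovelHitReport(table=table)
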