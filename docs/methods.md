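# Methods

## Weighted hypothesis testing

Given m hypotheses with p-values P_1, …, P_m and positive weights
W_1, …, W_m satisfying ∑ W_i = m, the weighted p-value is Q_i = P_i / W_i.
Q_i is not a p-value (it may exceed 1; reports flag such rows but never clip
them). The procedures:

* **Bonferroni** rejects where Q_j ≤ α/m. Since
  P(∃ j: P_j ≤ W_j α/m) ≤ ∑ W_j α/m = α, mean-one weighting preserves the
  FWER bound for any weights.
* **Holm** sorts Q ascending and steps down with thresholds
  α / ∑_{k≥i} W_(k), stopping at the first failure. With unit weights the
  denominators are m, m−1, …, 1, the classical Holm schedule.
* **Benjamini–Hochberg** steps up on sorted Q with thresholds α·j/m.

Ties in Q are broken by stable sort on (q, input order); this affects only
the reported ordering, never the rejection sets, because thresholds are
compared per sorted position.

### Effective test count

Correlated SNPs make m an overcount of independent tests. An effective
count m_eff = m × ratio (the ratio is a supplied parameter, e.g. 0.791 for
a 300k-SNP array panel or 0.30 for imputed meta-analysis SNPs) may replace
m in all thresholds. For Holm, the published step-down rule is written in
terms of weight sums, not m, so there is a genuine interpretation question;
we rescale the weight-sum denominators by m_eff/m so that the first step
reproduces α/m_eff, matching Bonferroni's adjusted threshold. The same flag
applies the ratio to BH (α·j/m_eff). Both behaviors (with/without the
ratio) are available; the ratio is applied uniformly or not at all.

## eQTL weights

**General weight.** w_g = sqrt(−log10 p_eQTL) for SNPs present in the eQTL
reference, 1 otherwise. The square root deliberately tempers the strongest
eQTLs (a p_eQTL of 1e-16 gets weight 4, not 16). Raw general weights for
eQTL SNPs are floored at 1.0: a LOD-thresholded reference cannot contain
p_eQTL > 0.1, but synthetic inputs can, and an "eQTL" should never be
down-weighted relative to an unannotated SNP before normalization. Both
schemes are normalized to mean one (two-pass division, final mean within
1e-12 of 1).

**Binary weight.** Up-weight B for the flagged fraction ε, down-weight
b = (1 − εB)/(1 − ε) from the mean-one identity εB + (1−ε)b = 1. When the
realized flag fraction differs from ε the vector is renormalized (with a
warning); constant flags renormalize to unit weights.

**Choosing B.** Under a one-sided normal power model, a test with weight w
rejects when its z-statistic exceeds Φ̄⁻¹(αw/m). Fix the reference effect
size ξ = Φ̄⁻¹(α/m) — the effect detected with 50% power at the unweighted
Bonferroni threshold. The smallest up-weight giving the favored ε-fraction
power 1−β at ξ is

    B = (m/α) · Φ̄(ξ + Φ⁻¹(β)),

capped below at 1 and constrained by feasibility εB < 1. With ε = 0.106,
α = 0.05, β = 0.4: m = 300 821 gives B = 3.70 (b = 0.68) and
m = 2 473 850 gives B = 4.07 — the two reference configurations. The
effect-size convention is exposed (`xi` may be overridden); maximizing the
down-weighted group's power instead is degenerate under this model (it
always returns B = 1, since raising B both lowers ξ and tightens the
down-group threshold), which is why the solver fixes ξ and treats the
up-group power requirement as the binding constraint.

## Enrichment test

For N background SNPs with K eQTLs and a query of n SNPs with k eQTLs, the
enrichment p-value is the hypergeometric upper tail P(X ≥ k) — the
one-sided Fisher tail of the 2×2 table — computed by
`scipy.stats.hypergeom.sf` (log-stable, exact). Two variants are provided:
the EASE jackknife (k replaced by k−1), a conservative screen popular in
annotation-enrichment tools, and the Poisson upper tail at rate λ = nK/N,
the classical rare-annotation approximation. On the reference asthma counts
(N = 251 826, K = 22 922, n = 38, k = 13) the exact tail is 1.77e-5, the
Poisson tail 6.76e-5, and EASE 9.09e-5; published analyses of these counts
report the Poisson-style value. The default is the exact tail.

## Association scan

Additive-dosage logistic regression per SNP with shared covariates plus
intercept, fitted by batched IRLS: the per-SNP normal equations are
assembled with einsum over the shared covariate block and the genotype
column, and solved as a stacked batch. Convergence is declared per SNP when
the max coefficient change falls below 1e-8 (max 50 iterations). The
reported p-value is the two-sided Wald test of the genotype coefficient.
Separation or non-convergence (|log-OR| > 30, exploding SE, singular
normal equations) yields a missing p flagged `converged = False` — never a
silent 0 or 1. Exact collinearity of a genotype column with the covariates
raises, as does a rank-deficient covariate block. Missing genotypes zero
out that individual's IRLS weight for that SNP only. The scan agrees with a
per-SNP reference implementation (statsmodels Logit) to ~1e-5 relative on
fixtures, and the Wald χ² tracks the likelihood-ratio statistic at large n.

QC before scanning: drop SNPs with missing rate ≥ 0.05, MAF < 0.05, or
1-df chi-square Hardy–Weinberg p < 1e-5 (an exact HWE test is a possible
refinement; at the MAFs retained by the MAF filter the chi-square
approximation is adequate).

## LD

Pairwise r² and D′ come from maximum-likelihood haplotype frequencies
estimated by EM over the double-heterozygote ambiguity (initialized at
linkage equilibrium; stops when the largest frequency change < 1e-8 or at
1000 iterations; the observed-data log-likelihood is monitored and is
non-decreasing). Individuals are dropped pairwise-complete. Monomorphic
SNPs raise (r² undefined).

Pruning follows the sliding-window convention (window 50 SNPs, step 5,
drop pairs with r² > 0.8): within each placement, offending pairs drop the
lower-MAF member (tie: the later position); removed SNPs are never
reconsidered. The exact drop rule of the original PLINK implementation is
not published, so the rule here is documented and tested against the window
invariant (no retained pair exceeds the threshold), not against PLINK
output.

Proxy extension adds, one hop only, every SNP with r² ≥ 0.8 against an
input SNP (500 kb distance cap when the LD table records distances).
Novelty screening reports weighted-only hits whose r² against every
unweighted hit is below 0.4; pairs absent from the LD table are treated as
not-in-LD and the report carries a `has_ld_data = False` annotation so the
missing-data caveat stays visible.

## Synthetic data generator

The generator emulates a case-control GWAS at desk scale: genotypes in LD
blocks (block sizes uniform on 5–25 SNPs; one MAF per block drawn uniform
on 0.05–0.5), phenotype from a logistic model, and an eQTL annotation
covering fraction ε = 0.106 of SNPs with eQTL p-values 10^(−U(4, 16))
(LOD scores derived from the corresponding 1-df χ²). Haplotype alleles are
thresholded equicorrelated Gaussians; the latent correlation is calibrated
per block by root finding on the bivariate-normal orthant probability so
the realized allele-level correlation matches the requested ρ (default
0.8, so within-block genotype r ≈ ρ and haplotype r² ≈ ρ²). Two
independent haplotypes per individual guarantee Hardy–Weinberg marginally.
Causal SNPs (n_causal, additive log-odds effect each, centered) can be
enriched among eQTL flags by a multiplicative factor while preserving the
overall flag fraction.

What the generator does **not** emulate: realistic allele-frequency
spectra, recombination-driven LD decay within blocks, cross-block LD,
population structure, genotyping error, or case-control ascertainment.
Passing error-control tests on these fixtures shows the procedures behave
correctly under clean block-correlated nulls; it does not certify
performance under stratification or differential genotyping artifacts.

## Permutation size study

The complete-null FWER of each (weight scheme, procedure) pair is
estimated by permuting the phenotype among individuals — covariates stay
attached to their individuals, deliberately breaking any
covariate-phenotype link — refitting the whole scan per permutation, and
counting replicates with at least one rejection (under permutation every
rejection is false). Default desk-scale study: 500 individuals × 2 000
SNPs × 500 permutations (~2 minutes). Monte-Carlo SE is
sqrt(f(1−f)/n_perm). Non-converged SNPs in a replicate are treated as
non-rejections (q = ∞).

The power experiments use 500 individuals × 1 000 SNPs with 10 causal SNPs
of log-odds 0.55 — chosen by an a-priori power calculation to put the
per-SNP Wald statistic near the Bonferroni detection boundary (z ≈ 4),
where weighting has the most leverage — and 200 replicates per arm, with
causal SNPs 5× enriched among eQTL flags in the informative arm and
unenriched in the uninformative arm.

## Numerical and interface choices

* Randomness: numpy `default_rng` (PCG64) seeded explicitly everywhere; a
  configuration plus seed reproduces outputs byte-for-byte.
* Machine-readable TSVs carry floats as `%.6e`; coordinates are 1-based.
* `AssocTable` rejects p ∉ (0, 1], duplicate ids, and unparseable rows with
  the offending row/id named; eQTL tables collapse multiple probe rows per
  SNP to the minimum p (idempotent).
* The effective count is used un-rounded as a divisor.
* Degenerate inputs: constant eQTL flags renormalize to unit weights with a
  warning; empty rejection sets are valid outputs; missing LD pairs are
  "unknown", not zero.

## Known limitations

* Weighted procedures assume the weights were chosen independently of the
  association p-values; data-dependent weights void the error-control
  guarantee.
* The binary-weight solver's power model is one-sided normal with a single
  common effect size; other conventions change B (which is why all its
  inputs are parameters).
* LD estimation assumes biallelic diploid variants; no phasing, no
  multi-allelic support.
* The scan offers no Firth or exact logistic fallback for separated SNPs;
  such SNPs are reported as failed fits.
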