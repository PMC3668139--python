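"""LD estimation, pruning, proxy extension and novelty screening.

Simulates a small genotype panel with LD blocks, estimates pairwise r2 by
EM, prunes the panel at r2 > 0.8, extends a SNP set with one-hop proxies,
and screens a weighted-only hit list for novelty at r2 < 0.4.
"""

import numpy as np

from eqtlweight import (
    LdTable,
    SimConfig,
    extend_with_proxies,
    ld_prune,
    novel_hits,
    pairwise_ld,
    simulate_study,
)

cfg = SimConfig(n_individuals=800, n_snps=30, rho=0.9,
                block_size_range=(5, 5), maf_range=(0.2, 0.4), seed=4)
G = simulate_study(cfg).genotypes

est = pairwise_ld(G.dosages[:, 0], G.dosages[:, 1])
print(f"within-block pair: r2 = {est.r2:.3f}, D' = {est.dprime:.3f} "
      f"(n = {est.n_used})")
est = pairwise_ld(G.dosages[:, 0], G.dosages[:, 10])
print(f"cross-block pair:  r2 = {est.r2:.3f}, D' = {est.dprime:.3f}")

kept = ld_prune(G, window=50, step=5, r2max=0.8)
print(f"pruning at r2 > 0.8 kept {len(kept)} of {G.n_snps} SNPs")

ld = LdTable.from_pairs([
    ("rs10", "rs11", 0.92, 0.98, 1200),
    ("rs10", "rs12", 0.55, 0.80, 3000),
    ("rs20", "rs11", 0.30, 0.60, 9000),
])
extended = extend_with_proxies({"rs10", "rs20"}, ld, r2min=0.8)
print(f"proxy extension of {{rs10, rs20}}: {sorted(extended)}")

report = novel_hits({"rs12", "rs20"}, {"rs11"}, ld, r2=0.4)
print(report.table.to_string(index=False))
# rs12 (r2 0.55 with nothing in the unweighted list) is novel; rs20 is in
# weak LD (0.30 < 0.4) with rs11 and also counts as novel.
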