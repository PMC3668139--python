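import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eqtlweight import (
    GenotypeMatrix,
    LdTable,
    SnpKey,
    extend_with_proxies,
    ld_prune,
    novel_hits,
    pairwise_ld,
)
from eqtlweight.ld import em_haplotype_freqs


def direct_hap_freqs(counts):
    """Closed-form haplotype counting, valid only without double heterozygotes."""
    counts = np.asarray(counts, dtype=float)
    assert counts[1, 1] == 0
    n = counts.sum()
    hap = np.zeros(4)  # AB, Ab, aB, ab
    for i in range(3):
        for j in range(3):
            c = counts[i, j]
            if c == 0:
                continue
            a_all = [1] * i + [0] * (2 - i)
            b_all = [1] * j + [0] * (2 - j)
            for a, b in zip(a_all, b_all):
                hap[(1 - a) * 2 + (1 - b)] += c
    return hap / (2 * n)


def random_table(rng, n_max=30, allow_dh=True):
    while True:
        c = rng.multinomial(int(rng.integers(4, n_max + 1)), np.full(9, 1 / 9)).reshape(3, 3)
        if not allow_dh:
            c[1, 1] = 0
        n = c.sum()
        if n < 2:
            continue
        pA = (2 * c[2].sum() + c[1].sum()) / (2 * n)
        pB = (2 * c[:, 2].sum() + c[:, 1].sum()) / (2 * n)
        if 0 < pA < 1 and 0 < pB < 1:
            return c


class TestPairwiseLd:
    def test_identical_columns_give_perfect_ld(self):
        g = np.array([0, 1, 2, 1, 0, 2, 1, 1], dtype=float)
        est = pairwise_ld(g, g)
        assert est.r2 == pytest.approx(1.0, abs=1e-6)
        assert est.dprime == pytest.approx(1.0, abs=1e-6)

    def test_em_equals_direct_counting_without_double_hets(self, rng):
        for _ in range(200):
            c = random_table(rng, allow_dh=False)
            freqs, _ = em_haplotype_freqs(c)
            np.testing.assert_allclose(freqs, direct_hap_freqs(c), atol=1e-10)

    def test_independent_snps_have_near_zero_r2(self, rng):
        n = 10_000
        g1 = rng.binomial(2, 0.3, size=n).astype(float)
        g2 = rng.binomial(2, 0.3, size=n).astype(float)
        assert pairwise_ld(g1, g2).r2 < 0.01

    def test_loglik_never_decreases(self, rng):
        for _ in range(50):
            c = random_table(rng, allow_dh=True)
            _, trace = em_haplotype_freqs(c)
            assert (np.diff(trace) >= -1e-9).all()

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            pairwise_ld(np.zeros(10), np.array([0, 1, 2] * 3 + [1], dtype=float))

    def test_missing_dropped_pairwise(self):
        g1 = np.array([0, 1, 2, np.nan, 1, 0, 2, 1])
        g2 = np.array([0, 1, 2, 1, np.nan, 0, 2, 1])
        est = pairwise_ld(g1, g2)
        assert est.n_used == 6
        assert est.r2 == pytest.approx(1.0, abs=1e-6)


def _matrix(cols, start_pos=1):
    cols = [np.asarray(c, dtype=float) for c in cols]
    snps = [SnpKey(f"s{i+1}", "1", (start_pos + i) * 1000) for i in range(len(cols))]
    return GenotypeMatrix(np.column_stack(cols), snps)


class TestPrune:
    def test_high_ld_pair_drops_one(self, rng):
        base = rng.binomial(2, 0.4, size=200).astype(float)
        other = rng.binomial(2, 0.4, size=200).astype(float)
        G = _matrix([base, base.copy(), other])
        kept = [s.snp_id for s in ld_prune(G, window=50, step=5, r2max=0.8)]
        # identical pair: equal MAF tie drops the later member
        assert kept == ["s1", "s3"]

    def test_lower_maf_member_dropped(self, rng):
        hap = rng.random(400) < 0.4
        g1 = (hap[:200].astype(float) + hap[200:].astype(float))
        g2 = g1.copy()
        # remove a few alt alleles from g2: lowers its MAF, keeps r2 high
        carriers = np.flatnonzero(g2 > 0)[:3]
        g2[carriers] -= 1
        est = pairwise_ld(g1, g2)
        assert est.r2 > 0.8
        kept = [s.snp_id for s in ld_prune(_matrix([g1, g2]), r2max=0.8)]
        assert kept == ["s1"]

    def test_independent_snps_all_kept(self, rng):
        G = _matrix([rng.binomial(2, 0.3, 300).astype(float) for _ in range(6)])
        kept = ld_prune(G)
        assert [s.snp_id for s in kept] == [s.snp_id for s in G.snps]

    def test_idempotent(self, rng):
        cols = [rng.binomial(2, 0.4, 150).astype(float) for _ in range(5)]
        cols[1] = cols[0].copy()
        cols[4] = cols[3].copy()
        G = _matrix(cols)
        kept1 = ld_prune(G)
        idx = [i for i, s in enumerate(G.snps) if s in kept1]
        kept2 = ld_prune(G.subset_snps(np.array(idx)))
        assert [s.snp_id for s in kept1] == [s.snp_id for s in kept2]

    def test_unordered_positions_rejected(self, rng):
        g = rng.binomial(2, 0.3, 50).astype(float)
        G = GenotypeMatrix(
            np.column_stack([g, g]),
            [SnpKey("a", "1", 2000), SnpKey("b", "1", 1000)],
        )
        with pytest.raises(ValueError, match="ordered"):
            ld_prune(G)


class TestProxies:
    def test_empty_table_is_identity(self):
        assert extend_with_proxies({"a"}, LdTable.from_pairs([])) == {"a"}

    def test_single_hop_no_transitivity(self):
        ld = LdTable.from_pairs([("a", "b", 0.9), ("b", "c", 0.9)])
        assert extend_with_proxies({"a"}, ld) == {"a", "b"}

    def test_threshold_is_inclusive(self):
        ld = LdTable.from_pairs([("a", "b", 0.79), ("a", "c", 0.8)])
        assert extend_with_proxies({"a"}, ld, r2min=0.8) == {"a", "c"}

    def test_distance_cap(self):
        ld = LdTable.from_pairs([("a", "b", 0.95, 1.0, 600_000), ("a", "c", 0.95, 1.0, 100)])
        assert extend_with_proxies({"a"}, ld, max_distance=500_000) == {"a", "c"}

    @settings(derandomize=True, max_examples=30)
    @given(extra=st.sets(st.sampled_from(["a", "b", "c", "d", "e"])))
    def test_monotone_in_input_set(self, extra):
        ld = LdTable.from_pairs([("a", "b", 0.9), ("c", "d", 0.85), ("d", "e", 0.7)])
        small = extend_with_proxies({"a"}, ld)
        big = extend_with_proxies({"a"} | extra, ld)
        assert small <= big


class TestNovelHits:
    def test_subset_gives_empty(self):
        ld = LdTable.from_pairs([])
        rep = novel_hits({"a"}, {"a", "b"}, ld)
        assert rep.novel == set()

    def test_definition_example(self):
        ld = LdTable.from_pairs([("x", "u", 0.7), ("y", "u", 0.1)])
        rep = novel_hits({"x", "y"}, {"u"}, ld, r2=0.4)
        assert rep.novel == {"y"}

    def test_missing_ld_annotated_but_novel(self):
        rep = novel_hits({"x"}, {"u"}, LdTable.from_pairs([]), r2=0.4)
        assert rep.novel == {"x"}
        assert not rep.table["has_ld_data"].iloc[0]
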