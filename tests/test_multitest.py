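import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from eqtlweight import (
    AssocTable,
    WeightVector,
    effective_test_count,
    rank_shift_table,
    weighted_bh,
    weighted_bonferroni,
    weighted_holm,
    weighted_pvalues,
)
from eqtlweight.multitest import bh_mask, bonferroni_mask, holm_mask
from conftest import make_assoc


def unit_weights(assoc):
    return WeightVector(assoc.snp_ids.copy(), np.ones(assoc.m), normalized=True)


def wv_for(assoc, w):
    return WeightVector(assoc.snp_ids.copy(), np.asarray(w, dtype=float),
                        normalized=abs(np.mean(w) - 1) < 1e-9)


class TestWeightedPvalues:
    def test_unit_weight_identity(self, small_assoc):
        qt = weighted_pvalues(small_assoc, unit_weights(small_assoc))
        np.testing.assert_array_equal(qt.q, small_assoc.p)

    def test_q_may_exceed_one_and_is_flagged(self):
        assoc = make_assoc([0.9, 0.1])
        qt = weighted_pvalues(assoc, wv_for(assoc, [0.5, 1.5]))
        assert qt.q[0] == pytest.approx(1.8)
        assert bool(qt.df["q_exceeds_one"].iloc[0])

    def test_misalignment_reported_with_id(self, small_assoc):
        wv = WeightVector(np.array(["x"] * 5), np.ones(5), normalized=True)
        with pytest.raises(ValueError, match="rs1"):
            weighted_pvalues(small_assoc, wv)

    def test_unnormalized_weights_rejected(self, small_assoc):
        wv = WeightVector(small_assoc.snp_ids.copy(), np.full(5, 2.0))
        with pytest.raises(ValueError, match="normalized"):
            weighted_pvalues(small_assoc, wv)


class TestEffectiveCount:
    def test_printed_products(self):
        assert effective_test_count(300_821, 0.791) == pytest.approx(237_949.411)
        assert effective_test_count(2_473_850, 0.30) == pytest.approx(742_155.0)

    def test_ratio_one_is_identity(self):
        assert effective_test_count(123, 1.0) == 123

    def test_ratio_above_one_rejected(self):
        with pytest.raises(ValueError):
            effective_test_count(10, 1.2)


class TestBonferroni:
    def test_effective_count_threshold(self):
        assoc = make_assoc([2.0e-7, 1.0e-3])
        qt = weighted_pvalues(assoc, unit_weights(assoc))
        rep = weighted_bonferroni(qt, 0.05, count=300_821 * 0.791)
        assert rep.rejected == ["rs1"]
        assert rep.table["threshold"].iloc[0] == pytest.approx(0.05 / 237949.411)

    def test_empty_when_nothing_passes(self):
        assoc = make_assoc([0.2, 0.9])
        rep = weighted_bonferroni(weighted_pvalues(assoc, unit_weights(assoc)), 0.05)
        assert rep.n_rejected == 0


class TestHolm:
    def test_classical_stepdown_by_hand(self):
        assoc = make_assoc([0.01, 0.02, 0.9])
        rep = weighted_holm(assoc, unit_weights(assoc), 0.05)
        # thresholds 0.05/3, 0.05/2, 0.05: first two pass
        assert rep.rejected == ["rs1", "rs2"]

    def test_first_step_blocks_everything(self):
        assoc = make_assoc([0.02, 0.03, 0.04])
        rep = weighted_holm(assoc, unit_weights(assoc), 0.05)
        assert rep.n_rejected == 0  # Q_(1) = 0.02 >= 0.05/3

    def test_weighted_stepdown_by_hand(self):
        assoc = make_assoc([0.03, 0.012, 0.5, 0.9])
        wv = wv_for(assoc, [2.0, 2 / 3, 2 / 3, 2 / 3])
        rep = weighted_holm(assoc, wv, 0.05)
        # q = (0.015, 0.018, 0.75, 1.35); suffix weight sums (4, 2, 4/3, 2/3)
        # q_(1) = 0.015 > 0.05/4 = 0.0125 -> nothing rejected
        assert rep.n_rejected == 0


class TestBH:
    def test_stepup_by_hand(self):
        assoc = make_assoc([0.001, 0.010, 0.030, 0.500])
        rep = weighted_bh(weighted_pvalues(assoc, unit_weights(assoc)), 0.05)
        assert rep.rejected == ["rs1", "rs2", "rs3"]

    def test_empty_when_all_large(self):
        assoc = make_assoc([0.9, 0.8])
        rep = weighted_bh(weighted_pvalues(assoc, unit_weights(assoc)), 0.05)
        assert rep.n_rejected == 0


@pytest.mark.parametrize("seed", range(25))
def test_unit_weight_reduction_matches_classical(seed):
    """With all weights 1 each weighted procedure equals its classical form."""
    r = np.random.default_rng(seed)
    m = int(r.integers(3, 40))
    p = r.uniform(1e-8, 1, size=m)
    assoc = make_assoc(p)
    wv = unit_weights(assoc)
    qt = weighted_pvalues(assoc, wv)
    alpha = float(r.uniform(0.01, 0.2))
    ours = {
        "bonferroni": weighted_bonferroni(qt, alpha).table["reject"].to_numpy(),
        "holm": weighted_holm(assoc, wv, alpha).table["reject"].to_numpy(),
        "fdr_bh": weighted_bh(qt, alpha).table["reject"].to_numpy(),
    }
    for method, mask in ours.items():
        ref = multipletests(p, alpha=alpha, method=method)[0]
        np.testing.assert_array_equal(mask, ref, err_msg=method)


@pytest.mark.parametrize("seed", range(25))
def test_nesting_and_monotonicity(seed):
    """Holm and BH each reject at least what Bonferroni does; lowering a
    p-value never shrinks any rejection set."""
    r = np.random.default_rng(1000 + seed)
    m = int(r.integers(4, 30))
    p = r.uniform(1e-8, 1, size=m)
    w = r.uniform(0.2, 3, size=m)
    w = w / w.mean()
    alpha = 0.05
    q = p / w
    bonf = bonferroni_mask(q, alpha, m)
    holm = holm_mask(q, w, alpha)
    bh = bh_mask(q, alpha, m)
    assert (holm | ~bonf).all() and (bh | ~bonf).all()
    # monotonicity under improving a single p-value
    j = int(r.integers(m))
    p2 = p.copy()
    p2[j] = p2[j] / 10
    q2 = p2 / w
    assert (bonferroni_mask(q2, alpha, m) | ~bonf).all()
    assert (holm_mask(q2, w, alpha) | ~holm).all()
    assert (bh_mask(q2, alpha, m) | ~bh).all()


class TestErrorRateControl:
    def test_fwer_on_complete_null(self):
        """Weighted Bonferroni and Holm keep FWER <= alpha + 3 MC-SE on
        independent uniform p-values with fixed mean-one weights."""
        r = np.random.default_rng(42)
        m, reps, alpha = 200, 2000, 0.05
        w = r.uniform(0.3, 3, size=m)
        w = w / w.mean()
        p = r.uniform(size=(reps, m))
        q = p / w
        bonf_any = (q.min(axis=1) <= alpha / m)
        holm_any = np.array([holm_mask(q[i], w, alpha).any() for i in range(reps)])
        for any_rej in (bonf_any, holm_any):
            fwer = any_rej.mean()
            se = np.sqrt(max(fwer, 1e-12) * (1 - fwer) / reps)
            assert fwer <= alpha + 3 * se

    def test_fdr_on_complete_null(self):
        r = np.random.default_rng(43)
        m, reps, alpha = 200, 2000, 0.05
        w = r.uniform(0.3, 3, size=m)
        w = w / w.mean()
        p = r.uniform(size=(reps, m))
        fdp = np.array([bh_mask(p[i] / w, alpha, m).any() for i in range(reps)])
        # under the complete null FDR equals the probability of any rejection
        fdr = fdp.mean()
        se = np.sqrt(max(fdr, 1e-12) * (1 - fdr) / reps)
        assert fdr <= alpha + 3 * se


class TestRankShift:
    def test_unit_weights_preserve_ranks(self, small_assoc):
        qt = weighted_pvalues(small_assoc, unit_weights(small_assoc))
        t = rank_shift_table(small_assoc, qt)
        np.testing.assert_array_equal(t["rank_p"], t["rank_q"])

    def test_upweighted_group_improves_on_average(self):
        r = np.random.default_rng(5)
        m = 2000
        p = r.uniform(size=m)
        flags = r.random(m) < 0.10
        w = np.where(flags, 3.70, 0.68)
        w = w / w.mean()
        assoc = make_assoc(p)
        qt = weighted_pvalues(assoc, wv_for(assoc, w))
        t = rank_shift_table(assoc, qt, flags)
        assert t.loc[t["is_eqtl"], "rank_shift"].mean() > 0
        assert t.loc[~t["is_eqtl"], "rank_shift"].mean() < 0
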