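"""Count table, three-hypothesis bootstrap and Fisher presence test."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import fisher_exact as scipy_fisher

import promotif as pm
from promotif.stats import fisher_exact_two_tailed

from _oracles import bootstrap_enum, fisher_enum


def make_meta(n_active=14, n_inactive=14):
    return ([pm.SpeciesMeta(f"a{i}", pm.ACTIVE) for i in range(n_active)]
            + [pm.SpeciesMeta(f"i{i}", pm.INACTIVE) for i in range(n_inactive)])


class TestCountTable:
    def test_no_hits_gives_zero_filled_rows(self):
        table = pm.count_table([], make_meta(), matrix_ids=["M"])
        assert table.counts.shape == (28, 1)
        assert (table.counts == 0).all().all()
        assert not table.presence.any().any()

    def test_multiple_hits_accumulate(self):
        hits = [pm.MotifHit("M", "a0", -100 - k, "+", 0.95) for k in range(3)]
        table = pm.count_table(hits, make_meta())
        assert table.counts.loc["a0", "M"] == 3
        assert bool(table.presence.loc["a0", "M"])
        assert table.counts.to_numpy().sum() == 3  # conservation

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        hits = [pm.MotifHit(f"M{rng.integers(2)}", f"a{rng.integers(14)}",
                            -int(rng.integers(20, 900)), "+", 0.95)
                for _ in range(50)]
        t1 = pm.count_table(hits, make_meta())
        perm = [hits[i] for i in rng.permutation(len(hits))]
        t2 = pm.count_table(perm, make_meta())
        assert t1.counts.equals(t2.counts)

    def test_unknown_species_rejected(self):
        with pytest.raises(pm.StudyError, match="ghost"):
            pm.count_table([pm.MotifHit("M", "ghost", -5, "+", 1.0)], make_meta())


class TestBootstrap:
    def test_identical_constant_counts_all_equal(self):
        counts = [2] * 6
        labels = [pm.ACTIVE] * 3 + [pm.INACTIVE] * 3
        for seed in (0, 1, 999):
            r = pm.bootstrap_three_way(counts, labels, B=500, seed=seed)
            assert (r.p_greater, r.p_equal, r.p_less) == (0.0, 1.0, 0.0)

    @given(st.lists(st.integers(0, 5), min_size=4, max_size=10),
           st.integers(0, 2**31 - 1))
    def test_tallies_partition_replicates(self, counts, seed):
        half = len(counts) // 2
        labels = [pm.ACTIVE] * half + [pm.INACTIVE] * (len(counts) - half)
        r = pm.bootstrap_three_way(counts, labels, B=97, seed=seed)
        assert r.n_greater + r.n_equal + r.n_less == r.B == 97
        assert sum(r.fractions()) == Fraction(1)

    def test_bit_reproducible(self):
        counts = [0, 1, 3, 0, 2, 2]
        labels = [pm.ACTIVE] * 3 + [pm.INACTIVE] * 3
        a = pm.bootstrap_three_way(counts, labels, B=1000, seed=7)
        b = pm.bootstrap_three_way(counts, labels, B=1000, seed=7)
        assert (a.n_greater, a.n_equal, a.n_less) == (b.n_greater, b.n_equal, b.n_less)

    def test_converges_to_enumeration_oracle(self):
        active, inactive = [0, 2], [1, 2]
        pg, pe, pl = bootstrap_enum(active, inactive)
        counts = active + inactive
        labels = [pm.ACTIVE] * 2 + [pm.INACTIVE] * 2
        B = 20_000
        r = pm.bootstrap_three_way(counts, labels, B=B, seed=13)
        for est, exact in ((r.p_greater, pg), (r.p_equal, pe), (r.p_less, pl)):
            se = math.sqrt(float(exact) * (1 - float(exact)) / B)
            assert abs(est - float(exact)) <= 3 * se + 1e-12

    def test_label_swap_symmetry_in_enumeration(self):
        # swapping groups swaps greater/less and preserves equal
        pg, pe, pl = bootstrap_enum([0, 1, 3], [2, 2])
        qg, qe, ql = bootstrap_enum([2, 2], [0, 1, 3])
        assert (pg, pe, pl) == (ql, qe, qg)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            pm.bootstrap_three_way([1, 2], [pm.ACTIVE, pm.ACTIVE], B=10, seed=0)
        with pytest.raises(ValueError, match="B"):
            pm.bootstrap_three_way([1, 2], [pm.ACTIVE, pm.INACTIVE], B=0, seed=0)


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_exact_two_tailed(((7, 7), (7, 7))) == 1

    def test_two_by_two_enumeration(self):
        # margins (2,2,2,2): table probabilities (1,4,1)/6; two-tailed = 2/6
        assert fisher_exact_two_tailed(((2, 0), (0, 2))) == Fraction(1, 3)

    def test_perfect_separation_14_14(self):
        assert fisher_exact_two_tailed(((14, 0), (0, 14))) == \
            Fraction(2, math.comb(28, 14))

    @given(st.integers(0, 10), st.integers(0, 10), st.integers(0, 10),
           st.integers(0, 10))
    def test_matches_scipy_oracle(self, a, b, c, d):
        if (a + b) == 0 or (c + d) == 0:
            return
        mine = float(fisher_exact_two_tailed(((a, b), (c, d))))
        _, ref = scipy_fisher([[a, b], [c, d]], alternative="two-sided")
        assert mine == pytest.approx(ref, rel=1e-7, abs=1e-12)

    def test_presence_wrapper_builds_table(self):
        presence = [True] * 10 + [False] * 4 + [True] * 2 + [False] * 12
        labels = [pm.ACTIVE] * 14 + [pm.INACTIVE] * 14
        r = pm.fisher_presence(presence, labels, matrix_id="M")
        assert r.table == ((10, 4), (2, 12))
        assert r.p_exact == fisher_enum(10, 4, 2, 12)

    def test_degenerate_margins_give_p_one(self):
        r = pm.fisher_presence([True] * 6, [pm.ACTIVE] * 3 + [pm.INACTIVE] * 3)
        assert r.p_two_tailed == 1.0
        assert r.note == "degenerate margins"


class TestEnrichmentReport:
    def test_planted_effect_recovered(self, matrices, effect_study):
        hits = pm.scan_study(matrices[:1], effect_study.promoters,
                             pm.ScanProfile(mode="match"))
        table = pm.count_table(hits, effect_study.meta,
                               matrix_ids=["GABPA_SYN"])
        report = pm.enrichment_report(table, B=2000, seed=1)
        row = report.iloc[0]
        # sites favour active promoters: H0 "inactive > active" fails
        assert row.p_greater < 0.05
        assert row.fisher_p < 0.05
        assert bool(row.significant)
        assert row.p_greater + row.p_equal + row.p_less == pytest.approx(1.0)

    def test_empty_column_noted_not_flagged(self):
        table = pm.count_table([], make_meta(), matrix_ids=["M"])
        report = pm.enrichment_report(table, B=100, seed=0)
        assert report.iloc[0].note == "no hits"
        assert not bool(report.iloc[0].significant)

    def test_deterministic_given_seed(self, matrices, effect_study):
        hits = pm.scan_study(matrices, effect_study.promoters,
                             pm.ScanProfile(mode="match"))
        table = pm.count_table(hits, effect_study.meta)
        a = pm.enrichment_report(table, B=500, seed=3)
        b = pm.enrichment_report(table, B=500, seed=3)
        assert a.equals(b)

    def test_seed_required(self, matrices, effect_study):
        hits = pm.scan_study(matrices, effect_study.promoters,
                             pm.ScanProfile(mode="match"))
        table = pm.count_table(hits, effect_study.meta)
        with pytest.raises(ValueError, match="seed"):
            pm.enrichment_report(table, B=100)
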