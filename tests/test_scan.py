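"""Match-style scoring kernel and both-strand scanning."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import promotif as pm
from promotif.scan import unscorable_window_count

from _oracles import brute_scan, window_score
from conftest import random_matrix, random_seq


def hit_tuples(hits):
    return [(h.matrix_id, h.species_id, h.offset, h.strand) for h in hits]


class TestInformationVector:
    def test_conserved_uniform_and_half(self):
        m = pm.read_matrix("ID T\n01 10 0 0 0\n02 1 1 1 1\n03 5 5 0 0\n//\n")
        iv = pm.information_vector(m)
        assert iv[0] == pytest.approx(math.log(4), abs=1e-12)
        assert iv[1] == pytest.approx(0.0, abs=1e-12)
        assert iv[2] == pytest.approx(math.log(2), abs=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            iv = pm.information_vector(random_matrix(rng))
            assert np.all(iv >= -1e-12) and np.all(iv <= math.log(4) + 1e-12)


class TestSimilarityScores:
    def test_consensus_is_exactly_one(self, matrices):
        for m in matrices:
            assert pm.matrix_similarity(m, m.consensus) == 1.0
            assert pm.core_similarity(m, m.consensus) == 1.0

    def test_anticonsensus_is_exactly_zero(self, matrices):
        for m in matrices:
            anti = "".join("ACGT"[i] for i in np.argmin(m.frequencies, axis=1))
            assert pm.matrix_similarity(m, anti) == 0.0
            assert pm.core_similarity(m, anti) == 0.0

    def test_matches_hand_evaluated_formula(self):
        m = pm.read_matrix("ID T\n01 10 0 0 0\n02 5 5 0 0\n//\n")
        for w in ("AC", "AA", "CA", "GT", "AG"):
            assert pm.matrix_similarity(m, w) == pytest.approx(
                window_score(m.counts.tolist(), w), abs=1e-12)

    def test_scores_in_unit_interval(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            m = random_matrix(rng)
            for _ in range(50):
                w = random_seq(rng, len(m))
                assert 0.0 <= pm.matrix_similarity(m, w) <= 1.0
                assert 0.0 <= pm.core_similarity(m, w) <= 1.0

    def test_window_with_n_is_unscorable(self, gabpa):
        with pytest.raises(pm.UnscorableWindowError):
            pm.matrix_similarity(gabpa, "N" * len(gabpa))

    def test_wrong_length_rejected(self, gabpa):
        with pytest.raises(ValueError, match="length"):
            pm.matrix_similarity(gabpa, "ACGT")


class TestCore:
    def test_short_matrix_core_is_whole_matrix(self):
        m = pm.read_matrix("ID T\n01 9 1 0 0\n02 0 9 1 0\n03 0 0 9 1\n04 1 0 0 9\n//\n")
        assert m.core_slice == slice(0, 4)

    def test_core_ignores_uninformative_tail(self):
        # informative 5-run at the start, uniform tail: CSS must not react
        # to tail edits
        text = ("ID T\n" + "\n".join(
            f"{i + 1:02d} {' '.join(str(c) for c in row)}"
            for i, row in enumerate(
                [[10, 0, 0, 0]] * 5 + [[1, 1, 1, 1]] * 3)) + "\n//\n")
        m = pm.read_matrix(text)
        assert m.core_slice == slice(0, 5)
        assert pm.core_similarity(m, "AAAAACCC") == pm.core_similarity(m, "AAAAAGGG") == 1.0

    def test_leftmost_tie_break(self):
        m = pm.read_matrix(
            "ID T\n01 10 0 0 0\n02 10 0 0 0\n03 10 0 0 0\n04 10 0 0 0\n"
            "05 10 0 0 0\n06 10 0 0 0\n//\n")
        assert m.core_start == 0


class TestScanSequence:
    def test_planted_consensus_single_hit(self, gabpa):
        # hit-free background: poly-T scores 0 on both strands for this matrix
        bases = list("T" * 1000)
        start = -175 + 1000
        bases[start:start + len(gabpa)] = gabpa.consensus
        prom = pm.PromoterSequence("sp1", "".join(bases))
        hits = pm.scan_sequence(gabpa, prom, pm.ScanProfile(mode="match"))
        assert hit_tuples(hits) == [("GABPA_SYN", "sp1", -175, "+")]
        assert hits[0].mss == 1.0 and hits[0].css == 1.0

    def test_weak_site_rescued_by_two_base_change(self, gabpa):
        # a core-mutated site scores below cut-off; restoring two bases
        # creates a hit at the same offset
        weak = list(gabpa.consensus)
        core = gabpa.core_slice
        weak[core.start], weak[core.start + 1] = "T", "T"
        for variant, expect in (("".join(weak), 0), (gabpa.consensus, 1)):
            bases = list("T" * 500)
            bases[300:300 + len(gabpa)] = variant
            prom = pm.PromoterSequence("sp", "".join(bases))
            hits = pm.scan_sequence(gabpa, prom, pm.ScanProfile(mode="match"))
            assert len(hits) == expect
            if hits:
                assert hits[0].offset == 300 - 500

    def test_short_promoter_yields_empty(self, gabpa):
        prom = pm.PromoterSequence("s", "ACGT")
        assert pm.scan_sequence(gabpa, prom, pm.ScanProfile()) == []

    def test_n_windows_skipped_and_counted(self, gabpa):
        bases = list(gabpa.consensus + "T" * 100)
        bases[50] = "N"
        prom = pm.PromoterSequence("s", "".join(bases))
        hits = pm.scan_sequence(gabpa, prom, pm.ScanProfile(mode="match"))
        assert len(hits) == 1  # the consensus at the 5' end
        assert unscorable_window_count(gabpa, prom) == 2 * len(gabpa)

    @given(st.integers(0, 2**31 - 1))
    def test_strand_symmetry(self, seed):
        # scanning the reverse complement = strand-swapped, mirrored scan
        rng = np.random.default_rng(seed)
        m = random_matrix(rng)
        n = int(rng.integers(len(m), 200))
        seq = random_seq(rng, n)
        profile = pm.ScanProfile(mode="tfbind", mss_cutoff=0.6)
        fwd = pm.scan_sequence(m, pm.PromoterSequence("s", seq), profile)
        rev = pm.scan_sequence(m, pm.PromoterSequence("s", pm.revcomp(seq)), profile)
        mirrored = sorted(
            (-(h.offset + n) - len(m), "-" if h.strand == "+" else "+",
             round(h.mss, 12))
            for h in rev)
        original = sorted((h.offset, h.strand, round(h.mss, 12)) for h in fwd)
        assert original == mirrored

    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 1.0))
    def test_cutoff_monotonicity(self, seed, cutoff):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng)
        seq = random_seq(rng, 100)
        prom = pm.PromoterSequence("s", seq)
        lo = pm.scan_sequence(m, prom, pm.ScanProfile(mode="tfbind", mss_cutoff=0.0))
        hi = pm.scan_sequence(m, prom, pm.ScanProfile(mode="tfbind", mss_cutoff=cutoff))
        assert set(hit_tuples(hi)) <= set(hit_tuples(lo))
        assert all(h.mss >= cutoff for h in hi)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(5):
            m = random_matrix(rng)
            prom = pm.PromoterSequence("s", random_seq(rng, 300))
            for mode, cut in (("match", 0.8), ("tfbind", 0.7)):
                profile = pm.ScanProfile(mode=mode, mss_cutoff=cut,
                                         core_cutoff=0.9)
                mine = pm.scan_sequence(m, prom, profile)
                oracle = brute_scan(m.counts.tolist(), m.matrix_id, "s",
                                    prom.bases, mode, cut, core_cutoff=0.9)
                assert hit_tuples(mine) == [t[:4] for t in oracle]
                for h, o in zip(mine, oracle):
                    assert h.mss == pytest.approx(o[4], abs=1e-12)


class TestScanStudy:
    def test_empty_matrix_list(self, effect_study):
        assert pm.scan_study([], effect_study.promoters, pm.ScanProfile()) == []

    def test_total_is_sum_of_per_promoter_scans(self, matrices, effect_study):
        profile = pm.ScanProfile(mode="match")
        total = pm.scan_study(matrices[:1], effect_study.promoters, profile)
        per = sum(len(pm.scan_sequence(matrices[0], p, profile))
                  for p in effect_study.promoters)
        assert len(total) == per

    def test_deterministic_and_sorted(self, matrices, effect_study):
        profile = pm.ScanProfile(mode="match")
        a = pm.scan_study(matrices, effect_study.promoters, profile)
        b = pm.scan_study(matrices, effect_study.promoters, profile)
        assert pm.write_hits(a) == pm.write_hits(b)
        keys = [h.sort_key() for h in a]
        assert keys == sorted(keys)


class TestHitSerialisation:
    def test_tsv_round_trip(self, matrices, effect_study):
        hits = pm.scan_study(matrices, effect_study.promoters,
                             pm.ScanProfile(mode="match"))
        assert pm.read_hits(pm.write_hits(hits)) == hits

    def test_bed_export(self, gabpa):
        hits = [pm.MotifHit("GABPA_SYN", "sp", -175, "+", 0.97, 1.0)]
        bed = pm.hits_to_bed(hits, [gabpa], {"sp": 1000})
        assert bed == "sp\t825\t837\tGABPA_SYN\t970\t+\n"
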