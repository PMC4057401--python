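"""MFE folding: model evaluation, DP optimality, loop enumeration/selection."""

import numpy as np
import pytest

import _oracles
from aptaclass import folding
from aptaclass.folding import LoopRegion, SecondaryStructure

REVCOMP = str.maketrans("ACGT", "TGCA")


class TestFoldMfe:
    def test_unpairable_homopolymer_is_open_chain(self):
        st = folding.fold_mfe("A" * 20)
        assert st.pairs == frozenset()
        assert st.energy_E == 0.0

    def test_designed_stem_energy_hand_summed(self):
        # GCGC stem (4 bp) + 5-nt hairpin: stacks GC/CG, CG/GC, GC/CG
        p = folding.default_parameters()
        expected = (
            p.stack_energy("G", "C", "C", "G")
            + p.stack_energy("C", "G", "G", "C")
            + p.stack_energy("G", "C", "C", "G")
            + p.hairpin_energy(5)
        )
        st = folding.fold_mfe("GCGCAAAAAGCGC")
        assert st.pairs == frozenset({(0, 12), (1, 11), (2, 10), (3, 9)})
        assert st.energy_E == pytest.approx(expected)

    def test_short_sequence_returns_open_chain(self):
        st = folding.fold_mfe("ACG")
        assert st.pairs == frozenset() and st.energy_E == 0.0

    def test_reported_energy_matches_model_evaluation(self, rng):
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 41))))
            st = folding.fold_mfe(seq)
            if st.pairs:
                assert folding.evaluate_energy(seq, st.pairs) == pytest.approx(st.energy_E)
            assert st.energy_E <= 0.0

    def test_optimality_vs_enumeration_small(self, rng):
        for _ in range(15):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 16))))
            assert folding.fold_mfe(seq).energy_E == pytest.approx(_oracles.mfe_oracle(seq), abs=1e-9)

    def test_reverse_complement_stability_on_designed_stems(self):
        # Watson-Crick stacks are palindromic-symmetric; wobble pairing is
        # not (G:T maps to C:A under reverse complement), so it is disabled.
        for seq in ("GCGCAAAAAGCGC", "GGGCCTTTTTTAGGCCC", "ATATGCGCACACACGCGCATAT"):
            rc = seq.translate(REVCOMP)[::-1]
            e_fwd = folding.fold_mfe(seq, wobble=False).energy_E
            e_rc = folding.fold_mfe(rc, wobble=False).energy_E
            assert e_fwd == pytest.approx(e_rc)

    def test_rejects_bad_input(self):
        with pytest.raises(folding.FoldingError):
            folding.fold_mfe("")
        with pytest.raises(folding.FoldingError):
            folding.fold_mfe("ACGTN")

    def test_wobble_toggle(self):
        # G:T-only stem folds with wobble enabled, not without
        seq = "GTGTGTAAAAAGTGTGT"
        with_w = folding.fold_mfe(seq, wobble=True)
        without = folding.fold_mfe(seq, wobble=False)
        assert without.energy_E >= with_w.energy_E


class TestDotBracket:
    def test_roundtrip(self):
        st = folding.fold_mfe("GCGCAAAAAGCGC")
        again = SecondaryStructure.from_dot_bracket(st.sequence, st.dot_bracket(), st.energy_E)
        assert again.pairs == st.pairs


class TestEnumerateLoops:
    def test_single_hairpin(self):
        st = folding.fold_mfe("GCGCAAAAAGCGC")
        loops = folding.enumerate_loops(st)
        assert len(loops) == 1
        assert loops[0].kind == "hairpin"
        assert loops[0].n_nucleotides == 5
        assert loops[0].positions == (4, 5, 6, 7, 8)

    def test_open_chain_has_no_loops(self):
        st = SecondaryStructure("A" * 10, frozenset(), 0.0)
        assert folding.enumerate_loops(st) == []

    def test_bulge_plus_hairpin_hand_constructed(self):
        #  stem with 2-nt bulge on the 5' strand plus terminal hairpin
        #  pairs: (0,13),(1,12),(4,11),(5,10) -> bulge {2,3}, hairpin {6..9}
        seq = "GCAAGCAAAAGCGC"
        pairs = frozenset({(0, 13), (1, 12), (4, 11), (5, 10)})
        st = SecondaryStructure(seq, pairs, -1.0)
        loops = folding.enumerate_loops(st)
        kinds = {lp.kind: lp for lp in loops}
        assert set(kinds) == {"bulge", "hairpin"}
        assert kinds["bulge"].positions == (2, 3)
        assert kinds["hairpin"].positions == (6, 7, 8, 9)

    def test_unpaired_partition(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=40))
            st = folding.fold_mfe(seq)
            partner = st.partner_map()
            loops = folding.enumerate_loops(st)
            in_loops = sum(lp.n_nucleotides for lp in loops)
            exterior = sum(
                1
                for kind, _, _, pos in folding.decompose(seq, st.pairs)
                if kind == "exterior"
                for _ in pos
            )
            assert in_loops + exterior == len(seq) - len(partner)


class TestSelectLoop:
    def hp(self, start, n):
        return LoopRegion("hairpin", tuple(range(start, start + n)))

    def test_size_priority_window(self):
        loops = [self.hp(0, 4), self.hp(10, 6), self.hp(20, 9)]
        assert folding.select_loop(loops).n_nucleotides == 6

    def test_single_out_of_range_loop_is_fallback(self):
        only = self.hp(0, 12)
        assert folding.select_loop([only]) is only

    def test_five_prime_tiebreak_in_window(self):
        first, second = self.hp(3, 5), self.hp(20, 7)
        assert folding.select_loop([second, first]) is first

    def test_hairpin_preferred_over_bulge_in_window(self):
        bulge = LoopRegion("bulge", tuple(range(2, 7)))
        hairpin = self.hp(15, 6)
        assert folding.select_loop([bulge, hairpin]) is hairpin

    def test_fallback_nearest_six_smaller_wins(self):
        assert folding.select_loop([self.hp(0, 4), self.hp(10, 8)]).n_nucleotides == 4

    def test_empty_is_error(self):
        with pytest.raises(folding.FoldingError, match="no pair structure"):
            folding.select_loop([])


class TestParameters:
    def test_table_roundtrip(self, tmp_path):
        p = folding.default_parameters()
        assert p.stack_energy("A", "A", "T", "T") == pytest.approx(-1.00)
        # symmetric context resolves to the same entry
        assert p.stack_energy("T", "T", "A", "A") == pytest.approx(-1.00)
        assert p.hairpin_energy(30) > p.hairpin_energy(10)

    def test_loop_sequence_extraction(self):
        st = folding.fold_mfe("GCGCAACTAGCGC")
        lp = folding.select_loop(folding.enumerate_loops(st))
        assert folding.loop_sequence(st, lp) == "AACTA"
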