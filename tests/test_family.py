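import itertools
import math

import dendropy
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from synthcn.errors import FrameError, InvalidInputError, SaturationError
from synthcn.family import (
    CodingSequence,
    DistanceMatrix,
    codon_path_diffs,
    codon_site_fractions,
    detect_premature_stop,
    distance_matrix,
    dnds_table,
    jukes_cantor,
    nei_gojobori,
    nj_tree,
    p_distance,
    truncation_table,
)

from .oracles import all_nonstop_codons, path_counts_oracle, site_fractions_oracle


def seq(nt, name="s", frame=0):
    return CodingSequence(name=name, nucleotides=nt, frame=frame)


class TestPDistance:
    def test_identical(self):
        assert p_distance(seq("ACGTACGT"), seq("ACGTACGT", "t")) == 0.0

    def test_one_of_four(self):
        assert p_distance(seq("AAAA"), seq("AAAT", "t")) == 0.25

    def test_matches_site_by_site_oracle(self):
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(list("ACGT"), 300))
        b = "".join(rng.choice(list("ACGT"), 300))
        oracle = sum(x != y for x, y in zip(a, b)) / 300
        assert p_distance(seq(a), seq(b, "t")) == pytest.approx(oracle, abs=1e-15)

    def test_gaps_and_ns_removed_pairwise(self):
        # comparable sites: positions 3 and 4 only -> one mismatch of two
        assert p_distance(seq("A-GT"), seq("NCGA", "t")) == 0.5

    def test_no_comparable_sites(self):
        with pytest.raises(InvalidInputError):
            p_distance(seq("NN--"), seq("ACGT", "t"))

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            p_distance(seq("ACGT"), seq("ACG", "t"))


class TestJukesCantor:
    def test_zero(self):
        assert jukes_cantor(0.0) == 0.0

    def test_closed_form(self):
        # independent evaluation: -(3/4) ln(1 - 0.4)
        assert jukes_cantor(0.3) == pytest.approx(-0.75 * math.log(0.6), rel=1e-12)
        assert jukes_cantor(0.3) == pytest.approx(0.38311921782449304, rel=1e-12)

    def test_saturation_boundary(self):
        with pytest.raises(SaturationError):
            jukes_cantor(0.75)

    @given(p=st.floats(1e-6, 0.74))
    def test_exceeds_p_and_increases(self, p):
        d = jukes_cantor(p)
        assert d >= p
        assert jukes_cantor(p * 0.5) < d


class TestSiteFractions:
    def test_phenylalanine_codon(self):
        s, n = codon_site_fractions("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    @pytest.mark.parametrize("count_stops", [False, True])
    def test_sites_sum_to_three_for_every_codon(self, count_stops):
        for codon in all_nonstop_codons():
            s, n = codon_site_fractions(codon, count_stops)
            assert s + n == pytest.approx(3.0, abs=1e-12)

    def test_matches_independent_oracle(self):
        for codon in all_nonstop_codons():
            assert codon_site_fractions(codon) == pytest.approx(
                site_fractions_oracle(codon), abs=1e-12
            )

    def test_fourfold_degenerate_third_position(self):
        s, _ = codon_site_fractions("GGG")  # glycine: third position fully synonymous
        assert s == pytest.approx(1.0)


class TestPathwayCounts:
    def test_two_difference_worked_example(self):
        # TTT<->GTA: pathway via GTT is N+S, via TTA is N+N; averaged
        assert codon_path_diffs("TTT", "GTA") == pytest.approx((0.5, 1.5))

    def test_all_pairs_up_to_two_differences_match_oracle(self):
        codons = all_nonstop_codons()
        for a, b in itertools.product(codons, repeat=2):
            if sum(x != y for x, y in zip(a, b)) <= 2:
                got = codon_path_diffs(a, b)
                want = path_counts_oracle(a, b)
                assert got == pytest.approx(want, abs=1e-12), (a, b)

    def test_difference_count_preserved(self):
        rng = np.random.default_rng(8)
        codons = all_nonstop_codons()
        for _ in range(200):
            a, b = rng.choice(codons, 2)
            s, n = codon_path_diffs(a, b)
            assert s + n == pytest.approx(sum(x != y for x, y in zip(a, b)))


class TestNeiGojobori:
    def test_identical_sequences(self):
        a = seq("ATGGCTTTT" * 10, "a")
        res = nei_gojobori(a, seq(a.nucleotides, "b"))
        assert res.syn_diffs == res.nonsyn_diffs == 0.0
        assert res.ds == res.dn == 0.0
        assert res.ratio is None

    def test_symmetry_in_sequence_order(self):
        rng = np.random.default_rng(13)
        codons = all_nonstop_codons()
        a = seq("".join(rng.choice(codons, 50)), "a")
        b = seq("".join(rng.choice(codons, 50)), "b")
        r1, r2 = nei_gojobori(a, b), nei_gojobori(b, a)
        for field in ("syn_sites", "nonsyn_sites", "syn_diffs", "nonsyn_diffs",
                      "ps", "pn", "ds", "dn", "ratio"):
            assert getattr(r1, field) == getattr(r2, field)

    def test_sites_sum_to_three_per_codon(self):
        rng = np.random.default_rng(14)
        codons = all_nonstop_codons()
        a = seq("".join(rng.choice(codons, 40)), "a")
        b = seq("".join(rng.choice(codons, 40)), "b")
        res = nei_gojobori(a, b)
        assert res.syn_sites + res.nonsyn_sites == pytest.approx(
            3 * res.codons_compared
        )

    def test_pure_synonymous_divergence_gives_zero_dn(self):
        from synthcn.simulate import CodonModel, SyntheticScenario, simulate_codon_pair

        sc = SyntheticScenario(seed=2, codon_model=CodonModel(omega=0.0))
        a, b, log = simulate_codon_pair(sc)
        assert set(log["class"]) == {"synonymous"}
        res = nei_gojobori(a, b)
        assert res.dn == 0.0
        assert res.ds > 0.0

    def test_pure_nonsynonymous_divergence_gives_zero_ds(self):
        from synthcn.simulate import CodonModel, SyntheticScenario, simulate_codon_pair

        sc = SyntheticScenario(seed=2, codon_model=CodonModel(omega=float("inf")))
        a, b, log = simulate_codon_pair(sc)
        assert set(log["class"]) == {"nonsynonymous"}
        res = nei_gojobori(a, b)
        assert res.ds == 0.0
        assert res.dn > 0.0
        assert res.ratio is None

    def test_codons_with_ambiguity_dropped_pairwise(self):
        a = seq("ATGGCTTTTGGAGGCGGT", "a")
        b = seq("ATGGC-TTCGGAGGCGGT", "b")  # GCT/GC- dropped; TTT->TTC synonymous
        res = nei_gojobori(a, b)
        assert res.codons_compared == 5
        assert res.syn_diffs == 1.0
        assert res.nonsyn_diffs == 0.0

    def test_saturated_divergence_reported_undefined(self):
        rng = np.random.default_rng(4)
        codons = all_nonstop_codons()
        a = seq("".join(rng.choice(codons, 40)), "a")
        b = seq("".join(rng.choice(codons, 40)), "b")
        res = nei_gojobori(a, b)  # unrelated sequences: pN near random ~0.75+
        if res.pn >= 0.75 or res.ps >= 0.75:
            assert res.ratio is None

    def test_out_of_frame_alignment_rejected(self):
        with pytest.raises(FrameError):
            nei_gojobori(seq("ATGGCTTT", "a"), seq("ATGGCTTC", "b"))

    def test_all_codons_dropped_rejected(self):
        with pytest.raises(InvalidInputError):
            nei_gojobori(seq("NNNNNN", "a"), seq("ATGGCT", "b"))


class TestTruncationDetection:
    def test_internal_stop_flags_truncation(self):
        rep = detect_premature_stop(seq("ATGTAAGGG"))
        assert rep.in_frame_stop_positions == (2,)
        assert rep.is_truncated

    def test_terminal_stop_is_not_truncation(self):
        rep = detect_premature_stop(seq("ATGGGGTAA"))
        assert rep.in_frame_stop_positions == (3,)
        assert not rep.is_truncated

    def test_frame_offset_shifts_codon_grid(self):
        # with frame 1 the scan reads TGT AAG GG -> no stop
        rep = detect_premature_stop(seq("ATGTAAGGG", frame=1))
        assert not rep.is_truncated

    def test_planted_stop_positions_recovered_exactly(self):
        from synthcn.simulate import CodonModel, SyntheticScenario, simulate_codon_pair

        for s in range(10):
            pos = 10 + s * 13
            sc = SyntheticScenario(
                seed=s,
                codon_model=CodonModel(ancestor_codons=300, planted_stop_codons=(pos,)),
            )
            _, derived, _ = simulate_codon_pair(sc)
            rep = detect_premature_stop(derived)
            assert pos in rep.in_frame_stop_positions
            assert rep.is_truncated

    def test_short_tail_ignored(self):
        rep = detect_premature_stop(seq("ATGGGGTA"))  # trailing TA is no codon
        assert rep.n_codons == 2
        assert not rep.is_truncated


class TestNjTree:
    @staticmethod
    def tip_path_lengths(tree):
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        return lambda a, b: pdm.patristic_distance(taxa[a], taxa[b])

    def test_three_taxa_closed_form(self):
        # d(A,B)=4, d(A,C)=6, d(B,C)=8 -> branches a=1, b=3, c=5
        d = DistanceMatrix(["A", "B", "C"], np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float))
        tree = nj_tree(d)
        dist = self.tip_path_lengths(tree)
        assert dist("A", "B") == pytest.approx(4.0)
        assert dist("A", "C") == pytest.approx(6.0)
        assert dist("B", "C") == pytest.approx(8.0)

    def test_four_taxon_additive_matrix_recovered(self):
        # tree ((A:2,B:3):1,(C:4,D:5):1) -> additive distances
        values = np.array(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 9, 0],
            ],
            float,
        )
        tree = nj_tree(DistanceMatrix(["A", "B", "C", "D"], values))
        dist = self.tip_path_lengths(tree)
        for (i, a), (j, b) in itertools.combinations(enumerate("ABCD"), 2):
            assert dist(a, b) == pytest.approx(values[i, j])

    def test_deterministic_under_ties(self):
        values = np.ones((4, 4)) - np.eye(4)  # fully tied joins
        d = DistanceMatrix(["A", "B", "C", "D"], values)
        n1 = nj_tree(d).as_string(schema="newick")
        n2 = nj_tree(d).as_string(schema="newick")
        assert n1 == n2

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(InvalidInputError):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float)))


class TestDistanceMatrixContainer:
    def test_asymmetric_rejected(self):
        with pytest.raises(InvalidInputError):
            DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0]], float))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(InvalidInputError):
            DistanceMatrix(["A", "B"], np.array([[1, 1], [1, 0]], float))

    def test_jc_option_applies_correction(self):
        a, b = seq("AAAAAAAAACCC", "a"), seq("AAAAAAAAACCG", "b")
        dm_p = distance_matrix([a, b], "p")
        dm_jc = distance_matrix([a, b], "jc")
        p = dm_p.values[0, 1]
        assert dm_jc.values[0, 1] == pytest.approx(jukes_cantor(p))


class TestFamilyTables:
    def test_distance_upper_dnds_lower_layout(self):
        from synthcn.simulate import SyntheticScenario, simulate_family_alignment

        seqs, _ = simulate_family_alignment(SyntheticScenario(seed=17), n_sequences=3)
        seqs = [seq(s.nucleotides, f"m{i}") for i, s in enumerate(seqs)]
        table = dnds_table(seqs)
        d01 = p_distance(seqs[0], seqs[1])
        assert table.loc["m0", "m1"] == pytest.approx(d01)
        res = nei_gojobori(seqs[0], seqs[1])
        assert table.loc["m1", "m0"] == pytest.approx(res.ratio)

    def test_truncation_table_flags(self):
        seqs = [seq("ATGTAAGGG", "trunc"), seq("ATGGGGTAA", "full")]
        table = truncation_table(seqs).set_index("name")
        assert bool(table.loc["trunc", "is_truncated"])
        assert not bool(table.loc["full", "is_truncated"])
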