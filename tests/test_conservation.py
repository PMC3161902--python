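"""Global alignment, identity/similarity, logo matrices, NJ trees, signals."""

import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trz.catalog import AA20
from trz.conservation import (
    AlignmentError,
    TargetingSignal,
    global_align,
    load_signal_table,
    logo_matrix,
    nj_tree,
    p_distance_matrix,
    percent_identity_similarity,
    validate_signal,
)
from trz.synthetic import random_additive_tree


def exhaustive_best_score(a, b, match=1.0, mismatch=0.0, gap=-1.0):
    """Plain recursion over every global alignment path (no memoisation)."""

    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, rec(i + 1, j + 1) + s)
        if i < len(a):
            best = max(best, rec(i + 1, j) + gap)
        if j < len(b):
            best = max(best, rec(i, j + 1) + gap)
        return best

    return rec(0, 0)


def unrooted_rf(newick_a, newick_b):
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    return dendropy.calculate.treecompare.symmetric_difference(ta, tb)


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = global_align("ACDE", "ACDE")
        assert aln.n_identical == aln.n_aligned_columns == 4
        assert "-" not in aln.aligned_a + aln.aligned_b

    def test_terminal_gap(self):
        aln = global_align("ACDE", "ACD")
        assert aln.aligned_b.count("-") == 1
        assert aln.n_identical == 3
        assert aln.aligned_a.replace("-", "") == "ACDE"
        assert aln.aligned_b.replace("-", "") == "ACD"

    def test_single_mismatch(self):
        aln = global_align("KLK", "KMK")
        assert (aln.n_identical, aln.n_aligned_columns) == (2, 3)

    def test_empty_input_rejected(self):
        with pytest.raises(AlignmentError):
            global_align("", "ACD")

    @given(st.data())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_dp_score_equals_exhaustive_enumeration(self, data):
        a = data.draw(st.text(alphabet="ACDE", min_size=1, max_size=7))
        b = data.draw(st.text(alphabet="ACDE", min_size=1, max_size=7))
        assert global_align(a, b).score == exhaustive_best_score(a, b)

    @given(st.data())
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_dp_score_matches_biopython(self, data):
        from Bio import Align

        a = data.draw(st.text(alphabet=AA20, min_size=1, max_size=30))
        b = data.draw(st.text(alphabet=AA20, min_size=1, max_size=30))
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = 0
        aligner.gap_score = -1
        assert global_align(a, b).score == aligner.score(a, b)


class TestIdentitySimilarity:
    def test_identical_pair_is_100_100(self):
        aln = global_align("M" * 100, "M" * 100)
        assert percent_identity_similarity(aln) == (100.0, 100.0)

    def test_e_and_f_share_no_group(self):
        aln = global_align("ACDE", "ACDF")
        assert percent_identity_similarity(aln) == (75.0, 75.0)

    def test_serine_threonine_conservation_group(self):
        aln = global_align("ST", "TS")
        assert percent_identity_similarity(aln) == (0.0, 100.0)

    def test_symmetry(self):
        a, b = "KLKAAYHHL", "KMKAAWHHI"
        fwd = percent_identity_similarity(global_align(a, b))
        rev = percent_identity_similarity(global_align(b, a))
        assert fwd == rev


class TestLogo:
    def test_single_instance_has_maximal_information(self):
        logo = logo_matrix(["KLK"])
        assert np.allclose(logo.information, math.log2(20))

    def test_uniform_column_has_zero_information(self):
        logo = logo_matrix(list(AA20))
        assert np.allclose(logo.information, 0.0)

    def test_binary_split_loses_one_bit(self):
        logo = logo_matrix(["K", "K", "L", "L"])
        assert np.allclose(logo.information, math.log2(20) - 1.0)

    def test_ragged_instances_rejected(self):
        with pytest.raises(ValueError):
            logo_matrix(["KL", "KLK"])

    @given(st.data())
    @settings(max_examples=100, derandomize=True)
    def test_frequencies_normalized_and_ic_bounded(self, data):
        length = data.draw(st.integers(1, 6))
        instances = data.draw(
            st.lists(
                st.text(alphabet=AA20, min_size=length, max_size=length),
                min_size=1,
                max_size=12,
            )
        )
        logo = logo_matrix(instances)
        assert np.allclose(logo.frequencies.sum(axis=1), 1.0)
        assert np.all(logo.information >= 0.0)
        assert np.all(logo.information <= math.log2(20) + 1e-12)


class TestNeighborJoining:
    def test_three_taxa_three_point_formulas(self):
        d = [[0, 5, 9], [5, 0, 10], [9, 10, 0]]
        newick = nj_tree(d, ["A", "B", "C"])
        # lA = (5+9-10)/2 = 2, lB = (5+10-9)/2 = 3, lC = (9+10-5)/2 = 7
        assert newick == "(A:2,B:3,C:7);"

    def test_four_taxon_additive_round_trip(self):
        # tree ((A:1,B:2):1,C:3,D:4) gives these path distances
        d = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        newick = nj_tree(d, ["A", "B", "C", "D"])
        assert unrooted_rf(newick, "((A:1,B:2):1,C:3,D:4);") == 0
        assert newick == "((A:1,B:2):1,C:3,D:4);"

    @pytest.mark.parametrize("seed", range(12))
    def test_random_additive_trees_recovered_exactly(self, seed):
        labels, d, true_newick = random_additive_tree(8, seed=seed)
        assert unrooted_rf(nj_tree(d, labels), true_newick) == 0

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            nj_tree([[0, 1], [1, 0]], ["A", "B"])
        with pytest.raises(ValueError):
            nj_tree([[0, 1, 2], [9, 0, 3], [2, 3, 0]], ["A", "B", "C"])
        with pytest.raises(ValueError):
            nj_tree([[1, 1, 2], [1, 0, 3], [2, 3, 0]], ["A", "B", "C"])


class TestSignals:
    def test_packaged_table_lengths_all_consistent(self):
        table = load_signal_table()
        assert len(table) == 46
        for record in table:
            n, consistent = validate_signal(record)
            assert consistent, record.protein_id
            assert n == record.declared_length

    def test_undeclared_length_returns_count(self):
        n, consistent = validate_signal(TargetingSignal("x", "C", "M"))
        assert (n, consistent) == (1, True)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            validate_signal(TargetingSignal("x", "C", ""))


def test_p_distance_of_identical_sequences_is_zero():
    d = p_distance_matrix(["KLKAY", "KLKAY", "KLKAW"], ["a", "b", "c"])
    assert d[0, 1] == 0.0
    assert d[0, 2] == pytest.approx(0.2)
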