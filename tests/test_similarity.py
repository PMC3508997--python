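import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tandemdup.genome_io import PeptideRecord
from tandemdup.similarity import (
    AlignmentResult,
    align_local,
    best_alignment_per_pair,
    is_duplicate_pair,
    parse_alignment_tabular,
    rost_threshold,
    weighted_identity,
)

from conftest import pep
from oracles import sw_affine_score

AA = "ACDEFGHIKLMNPQRSTVWY"


def aln(identities, L, n_q, n_s, L_q, L_s, evalue=None, score=0.0):
    return AlignmentResult(
        query_id="gA", subject_id="gB", L=L, identities=identities,
        n_query=n_q, n_subject=n_s, L_query=L_q, L_subject=L_s,
        score=score, e_value=evalue,
    )


class TestAlignLocal:
    def test_identical_sequences_fully_aligned(self):
        result = align_local(pep("gA", "MKVLA"), pep("gB", "MKVLA"))
        assert (result.L, result.identities) == (5, 5)
        assert result.n_query == result.n_subject == 5

    def test_single_substitution(self):
        result = align_local(pep("gA", "MKVLA"), pep("gB", "MKILA"))
        assert (result.L, result.identities) == (5, 4)

    def test_unrelatable_sequences_give_empty_alignment(self):
        result = align_local(pep("gA", "AAAA"), pep("gB", "WWWW"))
        assert result.L == 0 and result.score == 0.0
        decision = is_duplicate_pair(result)
        assert not decision.passes

    def test_empty_sequence_rejected(self):
        with pytest.raises(Exception):
            align_local(pep("gA", ""), pep("gB", "MKV"))

    def test_scores_match_exhaustive_dp_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            s1 = "".join(rng.choice(list(AA), size=rng.integers(1, 13)))
            s2 = "".join(rng.choice(list(AA), size=rng.integers(1, 13)))
            got = align_local(pep("gA", s1), pep("gB", s2)).score
            assert got == sw_affine_score(s1, s2), (s1, s2)

    def test_x_residues_are_neutral(self):
        plain = align_local(pep("gA", "MKVLAMKVLA"), pep("gB", "MKVLAMKVLA"))
        with_x = align_local(pep("gA", "MKVLAXMKVLA"), pep("gB", "MKVLAXMKVLA"))
        # the X column contributes 0 score but no penalty either
        assert with_x.score == plain.score


class TestWeightedIdentity:
    def test_full_length_identity(self):
        decision = weighted_identity(aln(100, 100, 100, 100, 100, 100))
        assert decision.I == 1.0 and decision.I_prime == 1.0

    def test_direct_formula(self):
        # I=0.5, coverage fractions 0.8 and 0.6 -> I' = 0.5 * 0.6 = 0.30
        decision = weighted_identity(aln(50, 100, 80, 60, 100, 100))
        assert decision.I == 0.5
        assert decision.I_prime == pytest.approx(0.30)

    def test_short_domain_of_long_protein_is_penalised(self):
        # 50-aa protein perfectly matching a 50-aa domain of a 500-aa protein
        decision = weighted_identity(aln(50, 50, 50, 50, 500, 50))
        assert decision.I == 1.0
        assert decision.I_prime == pytest.approx(0.1)

    def test_symmetric_under_query_subject_swap(self):
        a = weighted_identity(aln(40, 80, 70, 60, 90, 100))
        b = weighted_identity(aln(40, 80, 60, 70, 100, 90))
        assert a.I == b.I and a.I_prime == b.I_prime

    @given(
        L=st.integers(1, 400),
        frac_id=st.floats(0, 1),
        nq=st.integers(1, 400),
        ns=st.integers(1, 400),
        extra_q=st.integers(0, 200),
        extra_s=st.integers(0, 200),
    )
    @settings(max_examples=200, deadline=None)
    def test_i_prime_never_exceeds_i(self, L, frac_id, nq, ns, extra_q, extra_s):
        nq, ns = min(nq, L), min(ns, L)
        identities = min(int(frac_id * L), nq, ns)
        a = aln(identities, L, nq, ns, nq + extra_q, ns + extra_s)
        decision = weighted_identity(a)
        assert decision.I_prime <= decision.I + 1e-12


class TestRostThreshold:
    def test_continuous_with_long_branch_at_150(self):
        assert rost_threshold(150, 6) == pytest.approx(0.30, abs=0.005)

    def test_value_at_50(self):
        assert rost_threshold(50, 6) == pytest.approx(0.477, abs=0.001)

    def test_strictly_decreasing_over_the_short_branch_range(self):
        # the curve is only consulted for L < 150; there it falls strictly,
        # and numerically it keeps falling until a shallow minimum near L~417
        values = [rost_threshold(L, 6) for L in range(10, 418)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_closed_form(self):
        for L, n in [(25, 6), (100, 6), (149, 3)]:
            expected = 0.01 * n + 4.8 * L ** (-0.32 * (1 + math.exp(-L / 1000)))
            assert rost_threshold(L, n) == expected


class TestIsDuplicatePair:
    def test_identical_long_peptides_pass_on_long_branch(self):
        decision = is_duplicate_pair(aln(200, 200, 200, 200, 200, 200, evalue=1e-100))
        assert decision.passes and decision.branch == "long"
        assert decision.threshold_used == 0.30

    def test_high_evalue_fails_criterion_i(self):
        decision = is_duplicate_pair(aln(200, 200, 200, 200, 200, 200, evalue=5.0))
        assert not decision.passes

    def test_missing_evalue_skips_criterion_i(self):
        decision = is_duplicate_pair(aln(200, 200, 200, 200, 200, 200, evalue=None))
        assert decision.passes

    def test_short_branch_uses_rost_curve(self):
        # I' = 0.40 vs rost_threshold(100, 6) ~ 0.354
        decision = is_duplicate_pair(aln(40, 100, 100, 100, 100, 100))
        assert decision.branch == "short"
        assert decision.threshold_used == pytest.approx(rost_threshold(100, 6))
        assert decision.passes

    def test_short_branch_threshold_is_applied_to_i_prime(self):
        # raw I passes the curve but coverage-weighted I' does not
        decision = is_duplicate_pair(aln(60, 100, 100, 100, 400, 100))
        assert decision.I >= decision.threshold_used
        assert decision.I_prime < decision.threshold_used
        assert not decision.passes

    def test_decision_same_for_internal_and_tabular_route(self, tmp_path):
        a, b = pep("gA", "MKVLAWQERTYIPASDFGHKLCVNM" * 8), None
        b = PeptideRecord("pep_gB", "gB", a.sequence)
        internal = align_local(a, b)
        row = (
            f"gA\tgB\t100.000\t{internal.L}\t0\t0\t1\t{internal.n_query}\t1\t"
            f"{internal.n_subject}\t1e-100\t500\t{internal.L_query}\t{internal.L_subject}\n"
        )
        path = tmp_path / "hits.tsv"
        path.write_text(row)
        (parsed,) = parse_alignment_tabular(path)
        d_int = is_duplicate_pair(internal)
        d_tab = is_duplicate_pair(parsed)
        assert d_int.passes == d_tab.passes
        assert d_int.I_prime == pytest.approx(d_tab.I_prime)


class TestParseAlignmentTabular:
    ROW12 = "gA\tgB\t50.000\t100\t50\t0\t1\t100\t1\t100\t1e-20\t120\n"

    def test_identities_reconstructed_from_pident(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(self.ROW12)
        (r,) = parse_alignment_tabular(path, lengths={"gA": 150, "gB": 150})
        assert r.identities == 50 and r.L == 100
        assert weighted_identity(r).I == pytest.approx(0.5)

    def test_full_identity_row(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("gA\tgB\t100.000\t200\t0\t0\t1\t200\t1\t200\t1e-50\t400\t200\t200\n")
        (r,) = parse_alignment_tabular(path)
        assert weighted_identity(r).I == 1.0

    def test_self_hits_dropped(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("gA\tgA\t100.0\t100\t0\t0\t1\t100\t1\t100\t0.0\t200\t100\t100\n")
        assert parse_alignment_tabular(path) == []

    def test_missing_lengths_is_an_error(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(self.ROW12)
        with pytest.raises(ValueError, match="length"):
            parse_alignment_tabular(path)

    def test_best_alignment_per_pair_prefers_score_then_length(self):
        low = aln(10, 50, 50, 50, 100, 100, score=100.0)
        high = aln(40, 50, 50, 50, 100, 100, score=200.0)
        longer = aln(40, 60, 60, 60, 100, 100, score=200.0)
        best = best_alignment_per_pair([low, high])
        assert best[("gA", "gB")] is high
        best = best_alignment_per_pair([high, longer])
        assert best[("gA", "gB")] is longer
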