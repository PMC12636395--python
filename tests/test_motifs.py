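"""Candidate selection, pattern counting, enrichment, FDR and merging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promotif import errors
from promotif import motifs as M
from promotif.windows import TokenSpan


def spans_from_lengths(lengths):
    spans, start = [], 0
    for L in lengths:
        spans.append(TokenSpan(token="A" * L, start=start, end=start + L))
        start += L
    return spans


class TestCandidateTokens:
    def test_three_predicate_hand_example(self):
        spans = spans_from_lengths([4, 3, 6, 5])
        s_hat = np.array([0.1, 0.2, 1.0, 0.9])
        # mu = 0.55, 2*min = 0.2: only the last two tokens pass all tests
        picked = M.candidate_tokens(spans, s_hat)
        assert [c.span.start for c in picked] == [spans[2].start, spans[3].start]

    def test_constant_attention_selects_nothing(self):
        spans = spans_from_lengths([5, 5, 5])
        assert M.candidate_tokens(spans, np.ones(3)) == []

    def test_single_token_strict_mean(self):
        spans = spans_from_lengths([8])
        assert M.candidate_tokens(spans, np.array([1.0])) == []

    def test_empty_spans_rejected(self):
        with pytest.raises(errors.ShapeError):
            M.candidate_tokens([], np.array([]))

    def test_corpus_wide_override(self):
        spans = spans_from_lengths([6, 6])
        s_hat = np.array([0.2, 1.0])
        # per-sequence (mu=0.6, 2*min=0.4): only the 1.0 token passes;
        # with lower corpus-wide statistics both do
        assert len(M.candidate_tokens(spans, s_hat)) == 1
        assert len(M.candidate_tokens(spans, s_hat, mu=0.1, s_min=0.05)) == 2


class TestCountOccurrences:
    SEQS = [("s1", 1, "ACGTACGT"), ("s2", 0, "TTTT")]

    def test_overlapping_occurrences_counted(self):
        counts = M.count_occurrences(["ACGT", "TTT"], self.SEQS)
        acgt, ttt = counts["ACGT"], counts["TTT"]
        assert (acgt.n, acgt.k, acgt.instances) == (1, 1, 2)
        assert (ttt.n, ttt.k, ttt.instances) == (1, 0, 2)
        assert ttt.locations == [("s2", 0), ("s2", 1)]

    def test_absent_motif_zero(self):
        c = M.count_occurrences(["GGGG"], self.SEQS)["GGGG"]
        assert (c.n, c.k, c.instances) == (0, 0, 0)

    def test_softmasked_sequence_still_matches(self):
        c = M.count_occurrences(["ACGT"], [("s", 1, "acgtacgt")])["ACGT"]
        assert c.instances == 2

    def test_bad_alphabet(self):
        with pytest.raises(errors.AlphabetError):
            M.count_occurrences(["ACXT"], self.SEQS)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_automaton_matches_naive_scan(self, seed):
        rng = np.random.default_rng(seed)
        seqs = [
            (f"s{i}", int(rng.integers(0, 2)), "".join(rng.choice(list("ACGT"), size=60)))
            for i in range(20)
        ]
        motifs = ["".join(rng.choice(list("ACGT"), size=int(rng.integers(3, 7)))) for _ in range(15)]
        fast = M.count_occurrences(motifs, seqs)
        slow = M.naive_count_occurrences(motifs, seqs)
        for m in fast:
            assert (fast[m].n, fast[m].k, fast[m].instances) == (slow[m].n, slow[m].k, slow[m].instances)
            assert sorted(fast[m].locations) == sorted(slow[m].locations)


class TestHypergeometricEnrichment:
    def test_maximal_k_equals_pmf(self):
        assert M.hypergeometric_enrichment(10, 5, 4, 4) == pytest.approx(5 / 210)
        assert M.hypergeometric_pmf(10, 5, 4, 4) == pytest.approx(5 / 210)

    def test_minimal_feasible_k_gives_one(self):
        assert M.hypergeometric_enrichment(10, 5, 4, 0) == pytest.approx(1.0)
        assert M.hypergeometric_enrichment(10, 8, 5, 3) == pytest.approx(1.0)  # lo = 5-2

    def test_small_hand_example(self):
        assert M.hypergeometric_enrichment(6, 3, 2, 2) == pytest.approx(3 / 15)

    def test_infeasible_combination(self):
        with pytest.raises(errors.DomainError):
            M.hypergeometric_enrichment(10, 5, 4, 5)
        with pytest.raises(errors.DomainError):
            M.hypergeometric_enrichment(10, 12, 4, 2)

    def test_upper_tail_matches_exhaustive_pmf_sum(self):
        """Exact-fraction summation oracle on a spread of parameter sets."""
        for N in (5, 9, 16):
            for K in range(N + 1):
                for n in range(N + 1):
                    lo, hi = max(0, n - (N - K)), min(K, n)
                    for k in range(lo, hi + 1):
                        exact = sum(
                            math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, hi + 1)
                        ) / math.comb(N, n)
                        assert M.hypergeometric_enrichment(N, K, n, k) == pytest.approx(
                            exact, abs=1e-12
                        )


class TestFdrCorrect:
    def test_hand_worked_bh_example(self):
        q, sig = M.fdr_correct([0.002, 0.004, 0.03], alpha=0.01)
        assert np.allclose(q, [0.006, 0.006, 0.03])
        assert list(sig) == [True, True, False]

    def test_all_ones_no_rejection(self):
        q, sig = M.fdr_correct([1.0, 1.0, 1.0])
        assert np.allclose(q, 1.0) and not sig.any()

    def test_single_p_identity(self):
        q, sig = M.fdr_correct([0.005], alpha=0.01)
        assert q[0] == pytest.approx(0.005) and sig[0]

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, size=12)
        perm = rng.permutation(12)
        q, sig = M.fdr_correct(p)
        q2, sig2 = M.fdr_correct(p[perm])
        assert np.allclose(q[perm], q2)
        assert (sig[perm] == sig2).all()

    def test_rejections_form_a_prefix_of_sorted_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, size=40) ** 3
        q, sig = M.fdr_correct(p, alpha=0.05)
        rejected = sorted(p[sig])
        kept = sorted(p[~sig])
        if rejected and kept:
            assert max(rejected) <= min(kept)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            M.fdr_correct([0.5, 1.5])


class TestFilterMinInstances:
    def make(self, instances):
        return [
            M.MotifEnrichment(motif=f"m{i}", N=10, K=5, n=3, k=2, instances=v, p=0.5)
            for i, v in enumerate(instances)
        ]

    def test_threshold_semantics(self):
        kept = M.filter_min_instances(self.make([2, 3, 10]))
        assert [r.instances for r in kept] == [3, 10]

    def test_min_zero_is_identity(self):
        results = self.make([0, 1, 2])
        assert M.filter_min_instances(results, min_instances=0) == results

    def test_all_filtered_warns(self):
        with pytest.warns(UserWarning):
            assert M.filter_min_instances(self.make([1, 2])) == []


class TestMergeRedundant:
    def test_suffix_prefix_overlap(self):
        merged = M.merge_redundant(["ACGTACG", "TACGTT"], min_overlap=4)
        assert [m.consensus for m in merged] == ["ACGTACGTT"]
        assert merged[0].members == ["ACGTACG", "TACGTT"]

    def test_containment_absorbs(self):
        merged = M.merge_redundant(["ACGT", "ACGTAA"])
        assert [m.consensus for m in merged] == ["ACGTAA"]

    def test_no_overlap_retained(self):
        merged = M.merge_redundant(["AAAA", "CCCC"])
        assert sorted(m.consensus for m in merged) == ["AAAA", "CCCC"]

    def test_chain_reconstructs_superstring(self):
        pieces = ["GATCAC", "ATCACG", "TCACGT", "CACGTT"]
        merged = M.merge_redundant(pieces, min_overlap=4)
        assert [m.consensus for m in merged] == ["GATCACGTT"]

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_merge_terminates_and_is_deterministic(self, seed):
        rng = np.random.default_rng(seed)
        motifs = list(
            {"".join(rng.choice(list("ACGT"), size=int(rng.integers(4, 9)))) for _ in range(12)}
        )
        a = M.merge_redundant(motifs)
        b = M.merge_redundant(list(reversed(motifs)))
        assert [m.consensus for m in a] == [m.consensus for m in b]
        # every input survives as a substring of some consensus
        for mot in motifs:
            assert any(mot in m.consensus for m in a)


class TestInstanceWindows:
    def test_center_window_coordinates(self):
        seq = "A" * 200
        m = M.MergedMotif(consensus="GGGGCG", members=["GGGGCG"], instances=[("s", 100)])
        [(wid, win)] = M.extract_instance_windows(m, {"s": seq}, flank=12)
        # center = 100 + 3 = 103; window covers [91, 116)
        assert len(win) == 25 and wid.endswith("s:100")

    def test_left_clip_no_padding(self):
        m = M.MergedMotif(consensus="ACGT", members=["ACGT"], instances=[("s", 0)])
        [(_, win)] = M.extract_instance_windows(m, {"s": "ACGTACGTACGT" * 3}, flank=12)
        assert len(win) == 2 + 12 + 1  # center 2, clipped left

    def test_flank_zero_single_base(self):
        m = M.MergedMotif(consensus="ACGTA", members=["ACGTA"], instances=[("s", 10)])
        [(_, win)] = M.extract_instance_windows(m, {"s": "A" * 50}, flank=0)
        assert len(win) == 1


class TestModelContrast:
    def test_set_difference(self):
        assert M.model_contrast({"m1", "m2", "m3"}, {"m2"}) == {"m1", "m3"}

    def test_empty_a_returns_b(self):
        assert M.model_contrast({"m1"}, set()) == {"m1"}

    def test_b_subset_of_a_empty(self):
        assert M.model_contrast({"m1"}, {"m1", "m2"}) == set()

    def test_containment_aware_mode(self):
        assert M.model_contrast({"ACGTACGT"}, {"CGTA"}, containment_aware=True) == set()


def test_meme_minimal_export(tmp_path):
    merged = [M.MergedMotif(consensus="ACGN", members=["ACGN"], instances=[("s", 0)])]
    path = tmp_path / "motifs.meme"
    M.write_meme_minimal(merged, path)
    text = path.read_text()
    assert "MEME version 4" in text
    assert "MOTIF ACGN" in text
    assert "w= 4" in text
    assert "0.250 0.250 0.250 0.250" in text  # the N row
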