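"""Synthetic-fixture generators: determinism, truth bookkeeping, null/signal
behaviour of the emulated attention and attributions."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu, spearmanr

from promotif import errors
from promotif import fixtures as F
from promotif.attention import layer_specificity


class TestGenerateSequences:
    def test_certain_insertion_plants_everywhere(self):
        spec = F.FixtureSpec(n_pos=10, n_neg=0, length=300,
                             planted_motifs=(F.PlantedMotif("GATCACGT", 1.0),), seed=1)
        pos, _, truth = F.generate_sequences(spec)
        for sid, _, seq in pos:
            [(motif, off)] = truth.planted[sid]
            assert seq[off : off + len(motif)] == motif

    def test_zero_insertion_probability_empty_truth(self):
        spec = F.FixtureSpec(n_pos=5, n_neg=0, length=200,
                             planted_motifs=(F.PlantedMotif("GATCACGT", 0.0),), seed=1)
        _, _, truth = F.generate_sequences(spec)
        assert all(not v for v in truth.planted.values())

    def test_background_gc_concentrates(self):
        spec = F.FixtureSpec(n_pos=0, n_neg=50, length=10_000, planted_motifs=(), seed=2)
        _, neg, _ = F.generate_sequences(spec)
        gc = np.mean([(s.count("G") + s.count("C")) / len(s) for _, _, s in neg])
        assert abs(gc - 0.5) < 0.02

    def test_bit_reproducible(self):
        spec = F.preset_spec("smoke", seed=9)
        assert F.generate_sequences(spec) == F.generate_sequences(spec)

    def test_truth_offsets_scan_back(self):
        spec = F.preset_spec("smoke", seed=4)
        pos, _, truth = F.generate_sequences(spec)
        for sid, _, seq in pos:
            for motif, off in truth.planted[sid]:
                assert seq[off : off + len(motif)] == motif

    def test_motif_longer_than_sequence(self):
        with pytest.raises(errors.ConfigError):
            F.FixtureSpec(length=5, planted_motifs=(F.PlantedMotif("GATCACGT"),))


class TestMockTokenize:
    def test_fixed_length_exact_tiling(self):
        spans = F.mock_tokenize("ACGTACGTACGT", (4, 4), seed=0)
        assert [(s.start, s.end) for s in spans] == [(0, 4), (4, 8), (8, 12)]

    @pytest.mark.parametrize("seed", [0, 5, 17])
    def test_spans_tile_sequence(self, seed):
        seq = "ACGT" * 100
        spans = F.mock_tokenize(seq, (3, 7), seed=seed)
        assert "".join(s.token for s in spans) == seq
        assert spans[0].start == 0 and spans[-1].end == len(seq)
        for a, b in zip(spans, spans[1:]):
            assert a.end == b.start

    def test_deterministic(self):
        seq = "ACGT" * 50
        assert F.mock_tokenize(seq, (3, 7), seed=11) == F.mock_tokenize(seq, (3, 7), seed=11)

    def test_invalid_range(self):
        with pytest.raises(errors.ConfigError):
            F.mock_tokenize("ACGT", (0, 3))


class TestGenerateAttention:
    def spans_and_planted(self, seed=0):
        seq = "".join(np.random.default_rng(seed).choice(list("ACGT"), size=400))
        spans = F.mock_tokenize(seq, (4, 8), seed=seed)
        planted = [("XXXXXXXX", 100)]  # flag tokens overlapping [100, 108)
        return spans, planted

    def test_alpha_sums_to_heads(self):
        spans, planted = self.spans_and_planted()
        for rec in F.generate_attention(spans, planted, heads=12, seed=1):
            assert rec.alpha.sum() == pytest.approx(12.0)
            assert rec.s_hat.max() == pytest.approx(1.0)

    def test_boosted_tokens_are_argmax_in_informative_layers(self):
        hits = 0
        for seed in range(40):
            spans, planted = self.spans_and_planted(seed)
            flags = np.zeros(len(spans), bool)
            for i, sp in enumerate(spans):
                if sp.start < 108 and sp.end > 100:
                    flags[i] = True
            recs = F.generate_attention(spans, planted, boost=10, noise_sd=0.1, seed=seed)
            rec = next(r for r in recs if r.layer == 6)
            hits += flags[int(np.argmax(rec.s_hat))]
        assert hits >= 38  # boosted span wins in >= 95% of sequences

    def test_null_boost_indistinguishable(self):
        spans, planted = self.spans_and_planted()
        flags = np.array([sp.start < 108 and sp.end > 100 for sp in spans])
        pooled_flagged, pooled_bg = [], []
        for seed in range(20):
            recs = F.generate_attention(spans, planted, boost=1.0, noise_sd=0.1, seed=seed)
            rec = next(r for r in recs if r.layer == 6)
            pooled_flagged.extend(rec.s_hat[flags])
            pooled_bg.extend(rec.s_hat[~flags])
        _, p = mannwhitneyu(pooled_flagged, pooled_bg)
        assert p > 0.01

    def test_uninformative_layers_have_noise_specificity(self):
        """Sp in non-boosted layers matches a fully unplanted run."""
        spans, planted = self.spans_and_planted()
        sp_uninformative, sp_unplanted = [], []
        for seed in range(30):
            recs = F.generate_attention(spans, planted, boost=10, noise_sd=0.1, seed=seed)
            sp_uninformative.append(layer_specificity(next(r.s_hat for r in recs if r.layer == 3)))
            null = F.generate_attention(spans, [], boost=10, noise_sd=0.1, seed=seed + 1000)
            sp_unplanted.append(layer_specificity(next(r.s_hat for r in null if r.layer == 6)))
        _, p = mannwhitneyu(sp_uninformative, sp_unplanted)
        assert p > 0.01


class TestGenerateAttributions:
    def setup_corpus(self, effect, seed=0):
        spec = F.FixtureSpec(n_pos=30, n_neg=0, length=500, seed=seed)
        pos, _, truth = F.generate_sequences(spec)
        spans = {sid: F.mock_tokenize(s, (4, 8), seed=i) for i, (sid, _, s) in enumerate(pos)}
        attrs = F.generate_attributions(spans, truth, effect=effect, noise_sd=0.1, seed=seed)
        return spans, truth, attrs

    def test_null_effect_uncorrelated_with_truth(self):
        spans, truth, attrs = self.setup_corpus(effect=0.0)
        flags, values = [], []
        i = 0
        for sid in spans:
            fl = truth.token_flags(sid, spans[sid])
            for f in fl:
                flags.append(float(f))
                values.append(attrs[i].value)
                i += 1
        rho, _ = spearmanr(flags, values)
        assert abs(rho) < 0.2

    def test_strong_effect_separates_planted(self):
        spans, truth, attrs = self.setup_corpus(effect=1.0)
        i, flagged, bg = 0, [], []
        for sid in spans:
            for f in truth.token_flags(sid, spans[sid]):
                (flagged if f else bg).append(attrs[i].value)
                i += 1
        assert min(flagged) > max(bg) - 0.5
        assert np.mean(flagged) > np.mean(bg) + 0.9

    def test_empty_truth_pure_noise(self):
        spec = F.FixtureSpec(n_pos=5, n_neg=0, length=200, planted_motifs=(), seed=3)
        pos, _, truth = F.generate_sequences(spec)
        spans = {sid: F.mock_tokenize(s, (4, 8), seed=1) for sid, _, s in pos}
        attrs = F.generate_attributions(spans, truth, effect=5.0, noise_sd=0.1, seed=3)
        assert max(abs(a.value) for a in attrs) < 1.0


class TestGenomeFixture:
    def test_reproducible(self):
        a = F.generate_genome_fixture(seed=5)
        b = F.generate_genome_fixture(seed=5)
        assert a[0] == b[0] and a[2] == b[2]

    def test_has_both_strands_and_softmask(self):
        genome, records, _ = F.generate_genome_fixture(n_promoters=6, seed=1)
        assert {r.strand for r in records} == {"+", "-"}
        assert any(c.islower() for c in genome["chr1"])


def test_make_fixture_emits_complete_set(tmp_path):
    from promotif import io as pio

    F.make_fixture("smoke", tmp_path, seed=3)
    seqs = pio.read_fasta_sequences(tmp_path / "sequences.fasta")
    spans = pio.read_token_spans(tmp_path / "tokens.tsv")
    recs = pio.read_attention_h5(tmp_path / "attention.h5")
    assert len(seqs) == 20 and len(spans) == 20
    assert len(recs) == 20 * 12
    assert (tmp_path / "truth.json").exists()
    assert (tmp_path / "attributions.tsv").exists()
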