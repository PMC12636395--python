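import numpy as np
import pytest

from promotif import fixtures as F


@pytest.fixture
def toy_genome():
    return {"chr1": "ACGTACGTACGT"}


@pytest.fixture
def random_genome():
    rng = np.random.default_rng(42)
    return {"chr1": "".join(rng.choice(list("ACGT"), size=10_000))}


def run_discovery(preset: str, seed: int):
    """One full pipeline run on a fixture preset; returns everything a test
    might want to inspect."""
    from promotif import motifs as M

    spec = F.preset_spec(preset, seed=seed)
    pos, neg, truth = F.generate_sequences(spec)
    sequences = pos + neg
    rng = np.random.default_rng(spec.seed + 1)
    spans = {
        sid: F.mock_tokenize(s, spec.token_len_range, seed=int(rng.integers(0, 2**31 - 1)))
        for sid, _, s in sequences
    }
    records = F.generate_attention_dataset(sequences, spans, truth, spec)
    results, merged = M.discover_motifs(
        sequences, spans, records, layers=list(spec.informative_layers)
    )
    return spec, sequences, spans, truth, records, results, merged


def planted_recovered(spec, results, merged) -> bool:
    """Did the planted motif (or a merged superstring of it) reach
    FDR significance?"""
    motif = spec.planted_motifs[0].motif
    if any(r.motif == motif and r.significant for r in results):
        return True
    return any(motif in m.consensus for m in merged)
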