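"""Synthetic fixtures with planted motifs and controlled signal/noise.

Everything the discovery pipeline consumes — sequences, a mock byte-pair
tokenization, per-layer attention, attribution tables, even a toy genome
with strand-resolved promoters — can be generated here with exact ground
truth, so the full pipeline is testable without any download or model run.

The background model is i.i.d. bases with a GC dial only; no Markov
structure, nucleosome or CpG modelling. That is deliberate: chance-hit
rates of a w-mer are then analytically (3/8 or 1/8 per strand-position at
GC 0.5) predictable, which is what planted-recovery tests need. Attention
is emulated at the alpha level: baseline ``|N(1, noise_sd^2)|`` per token,
multiplied by ``attention_boost`` on tokens overlapping a planted motif in
the designated informative layers, then renormalised to sum to H. A boost
of 1 is the exact null. A separate query/key generator exercises the raw
scaled-dot-product route.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .attention import AttentionRecord, normalize_attention
from .attribution import TokenAttribution
from .errors import ConfigError
from .windows import TSSRecord, TokenSpan

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedMotif:
    """One motif to insert into positive sequences.

    ``position`` is either ``("uniform",)`` over all valid offsets or
    ``("normal", mu_bp, sigma_bp)`` on the TSS-relative axis (TSS at the
    sequence's ``tss_offset``).
    """

    motif: str
    insertion_probability: float = 1.0
    position: tuple = ("uniform",)

    def __post_init__(self) -> None:
        if not 0.0 <= self.insertion_probability <= 1.0:
            raise ConfigError("insertion probability must lie in [0, 1]")
        if self.position[0] not in {"uniform", "normal"}:
            raise ConfigError(f"unknown position distribution {self.position[0]!r}")


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic dataset."""

    n_pos: int = 100
    n_neg: int = 100
    length: int = 2000
    planted_motifs: tuple[PlantedMotif, ...] = (PlantedMotif("GATCACGT", 0.9),)
    gc: float = 0.5
    attention_boost: float = 10.0
    noise_sd: float = 0.1
    token_len_range: tuple[int, int] = (4, 8)
    seed: int = 0
    tss_offset: int | None = None  # default: length // 2
    n_layers: int = 12
    informative_layers: tuple[int, ...] = (5, 6, 7, 12)
    heads: int = 12

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ConfigError("sequence counts must be >= 0")
        if self.attention_boost < 1:
            raise ConfigError("attention_boost must be >= 1")
        if not 0 < self.gc < 1:
            raise ConfigError("background GC must lie in (0, 1)")
        for pm in self.planted_motifs:
            if len(pm.motif) > self.length:
                raise ConfigError(f"motif {pm.motif} longer than sequence length")


@dataclass
class FixtureTruth:
    """Exact bookkeeping of what was planted where."""

    planted: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def token_flags(self, sequence_id: str, spans: Sequence[TokenSpan]) -> np.ndarray:
        """True for tokens overlapping any planted span of the sequence."""
        flags = np.zeros(len(spans), dtype=bool)
        for motif, offset in self.planted.get(sequence_id, []):
            lo, hi = offset, offset + len(motif)
            for i, sp in enumerate(spans):
                if sp.start < hi and sp.end > lo:
                    flags[i] = True
        return flags


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p)


def generate_sequences(
    spec: FixtureSpec,
) -> tuple[list[tuple[str, int, str]], list[tuple[str, int, str]], FixtureTruth]:
    """i.i.d.-background positives/negatives with motifs planted in positives
    only; bit-reproducible under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    tss = spec.tss_offset if spec.tss_offset is not None else spec.length // 2
    truth = FixtureTruth()
    positives, negatives = [], []
    for i in range(spec.n_pos):
        seq = _random_bases(rng, spec.length, spec.gc)
        sid = f"pos{i}"
        truth.planted[sid] = []
        for pm in spec.planted_motifs:
            if rng.random() >= pm.insertion_probability:
                continue
            max_off = spec.length - len(pm.motif)
            if pm.position[0] == "uniform":
                off = int(rng.integers(0, max_off + 1))
            else:
                _, mu, sigma = pm.position
                off = int(np.clip(round(tss + rng.normal(mu, sigma)), 0, max_off))
            seq[off : off + len(pm.motif)] = list(pm.motif)
            truth.planted[sid].append((pm.motif, off))
        positives.append((sid, 1, "".join(seq)))
    for i in range(spec.n_neg):
        negatives.append((f"neg{i}", 0, "".join(_random_bases(rng, spec.length, spec.gc))))
    return positives, negatives, truth


def mock_tokenize(
    sequence: str, token_len_range: tuple[int, int] = (4, 8), seed: int = 0
) -> list[TokenSpan]:
    """Random-length contiguous tiling of the sequence (a stand-in for BPE).

    Token lengths are uniform over the range; the final token is clipped to
    the sequence end and may be shorter than the range minimum.
    """
    lo, hi = token_len_range
    if lo < 1 or hi < lo:
        raise ConfigError(f"invalid token length range {token_len_range}")
    rng = np.random.default_rng(seed)
    spans, start = [], 0
    n = len(sequence)
    while start < n:
        length = int(rng.integers(lo, hi + 1))
        end = min(start + length, n)
        spans.append(TokenSpan(token=sequence[start:end].upper(), start=start, end=end))
        start = end
    return spans


def generate_attention(
    spans: Sequence[TokenSpan],
    planted: Sequence[tuple[str, int]],
    boost: float = 10.0,
    noise_sd: float = 0.1,
    layers: Sequence[int] = tuple(range(1, 13)),
    informative_layers: Sequence[int] = (5, 6, 7, 12),
    heads: int = 12,
    seed: int = 0,
    sequence_id: str = "seq",
) -> list[AttentionRecord]:
    """Per-layer attention for one sequence: folded-normal baseline, boosted
    on planted-overlap tokens in informative layers, alpha renormalised to
    sum to ``heads``."""
    if boost < 1:
        raise ConfigError("boost must be >= 1")
    rng = np.random.default_rng(seed)
    J = len(spans)
    flags = np.zeros(J, dtype=bool)
    for motif, offset in planted:
        lo, hi = offset, offset + len(motif)
        for i, sp in enumerate(spans):
            if sp.start < hi and sp.end > lo:
                flags[i] = True
    informative = set(informative_layers)
    records = []
    for layer in layers:
        alpha = np.abs(rng.normal(1.0, noise_sd, size=J))
        if layer in informative:
            alpha = np.where(flags, alpha * boost, alpha)
        alpha = alpha * (heads / alpha.sum())
        records.append(
            AttentionRecord(
                sequence_id=sequence_id,
                layer=int(layer),
                alpha=alpha,
                s_hat=normalize_attention(alpha),
                heads=heads,
                correct_prediction=True,
            )
        )
    return records


def generate_attention_dataset(
    sequences: Sequence[tuple[str, int, str]],
    spans_by_sequence: Mapping[str, Sequence[TokenSpan]],
    truth: FixtureTruth,
    spec: FixtureSpec,
    seed: int | None = None,
) -> list[AttentionRecord]:
    """Attention for every sequence; negatives carry no planted spans, so
    their attention is pure baseline noise in every layer."""
    root = np.random.default_rng(spec.seed if seed is None else seed)
    records = []
    for sid, _, _ in sequences:
        records.extend(
            generate_attention(
                spans_by_sequence[sid],
                truth.planted.get(sid, []),
                boost=spec.attention_boost,
                noise_sd=spec.noise_sd,
                layers=range(1, spec.n_layers + 1),
                informative_layers=spec.informative_layers,
                heads=spec.heads,
                seed=int(root.integers(0, 2**31 - 1)),
                sequence_id=sid,
            )
        )
    return records


def generate_attributions(
    spans_by_sequence: Mapping[str, Sequence[TokenSpan]],
    truth: FixtureTruth,
    effect: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> list[TokenAttribution]:
    """Occurrence-level attribution scores: N(0, noise_sd^2) background plus
    ``effect`` on tokens overlapping a planted span."""
    if effect < 0:
        raise ConfigError("effect must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for sid in spans_by_sequence:
        spans = spans_by_sequence[sid]
        flags = truth.token_flags(sid, spans)
        values = rng.normal(0.0, noise_sd, size=len(spans))
        for sp, flag, v in zip(spans, flags, values):
            out.append(TokenAttribution(sid, sp.token, float(v + (effect if flag else 0.0))))
    return out


def generate_qk(
    J: int, heads: int = 4, d: int = 16, seed: int = 0, scale: float = 1.0
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Random per-head CLS query vectors and (J, d) key matrices for testing
    the raw attention route."""
    rng = np.random.default_rng(seed)
    q = [rng.normal(0, scale, size=d) for _ in range(heads)]
    k = [rng.normal(0, scale, size=(J, d)) for _ in range(heads)]
    return q, k


# ---------------------------------------------------------------------------
# toy genome with strand-resolved promoters
# ---------------------------------------------------------------------------

def generate_genome_fixture(
    n_promoters: int = 10,
    upstream: int = 300,
    downstream: int = 100,
    motif: str = "GATCACGT",
    gap: int = 200,
    gc: float = 0.5,
    softmask_prob: float = 0.1,
    seed: int = 0,
) -> tuple[dict[str, str], list[TSSRecord], dict[str, list[tuple[str, int]]]]:
    """A single-chromosome genome with alternating-strand promoters, one
    planted motif per promoter at a recorded window offset, and random
    soft-masked (lowercase) stretches.

    Returns ``(genome, tss_records, planted)`` where ``planted`` maps
    transcript ids to (motif, window_offset) with the offset expressed in
    the 5'->3' window string (so minus-strand plants are written into the
    reference as the motif's reverse complement).
    """
    rng = np.random.default_rng(seed)
    wlen = upstream + downstream
    total = gap + n_promoters * (wlen + gap)
    seq = _random_bases(rng, total, gc)
    # soft-mask random 20-50 bp stretches to emulate repeat annotation
    n_masked = int(softmask_prob * total / 35)
    for _ in range(n_masked):
        start = int(rng.integers(0, total - 50))
        length = int(rng.integers(20, 51))
        seq[start : start + length] = np.char.lower(seq[start : start + length])
    records, planted = [], {}
    comp = str.maketrans("ACGTacgt", "TGCAtgca")
    for i in range(n_promoters):
        win_start = gap + i * (wlen + gap)
        strand = "+" if i % 2 == 0 else "-"
        tid = f"tx{i}"
        offset = int(rng.integers(0, wlen - len(motif) + 1))
        if strand == "+":
            pos = win_start + upstream  # interval [pos-U, pos+D) == window
            g = win_start + offset
            seq[g : g + len(motif)] = list(motif)
        else:
            pos = win_start + downstream  # interval [pos-D, pos+U) == window
            g_end = win_start + wlen - offset
            rc = motif.translate(comp)[::-1]
            seq[g_end - len(motif) : g_end] = list(rc)
        records.append(TSSRecord(chrom="chr1", pos=pos, strand=strand, transcript_id=tid, group="TSp"))
        planted[tid] = [(motif, offset)]
    return {"chr1": "".join(seq)}, records, planted


# ---------------------------------------------------------------------------
# presets and on-disk emission
# ---------------------------------------------------------------------------

PRESETS: dict[str, FixtureSpec] = {
    "smoke": FixtureSpec(
        n_pos=10, n_neg=10, length=400,
        planted_motifs=(PlantedMotif("GATCACGT", 1.0),),
    ),
    "recovery": FixtureSpec(
        n_pos=100, n_neg=100, length=2000,
        planted_motifs=(PlantedMotif("GATCACGT", 0.9),),
        attention_boost=10.0, noise_sd=0.1,
    ),
    "null": FixtureSpec(
        n_pos=100, n_neg=100, length=2000,
        planted_motifs=(PlantedMotif("GATCACGT", 0.9),),
        attention_boost=1.0, noise_sd=0.1,
    ),
}


def preset_spec(name: str, seed: int | None = None) -> FixtureSpec:
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    spec = PRESETS[name]
    return replace(spec, seed=seed) if seed is not None else spec


def make_fixture(preset: str, out_dir, seed: int | None = None) -> FixtureSpec:
    """Emit a complete fixture (FASTA, token TSV, attention HDF5,
    attribution TSV, truth JSON) for one preset."""
    from . import io as pio

    spec = preset_spec(preset, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    positives, negatives, truth = generate_sequences(spec)
    sequences = positives + negatives
    rng = np.random.default_rng(spec.seed + 1)
    spans = {
        sid: mock_tokenize(s, spec.token_len_range, seed=int(rng.integers(0, 2**31 - 1)))
        for sid, _, s in sequences
    }
    records = generate_attention_dataset(sequences, spans, truth, spec)
    attrs = generate_attributions(spans, truth, effect=1.0, noise_sd=spec.noise_sd, seed=spec.seed + 2)
    with open(out / "sequences.fasta", "w") as fh:
        for sid, label, s in sequences:
            fh.write(f">{sid}:{label}\n{s}\n")
    pio.write_token_spans(spans, out / "tokens.tsv")
    pio.write_attention_h5(records, out / "attention.h5")
    with open(out / "attributions.tsv", "w") as fh:
        fh.write("sequence_id\ttoken\tvalue\n")
        for a in attrs:
            fh.write(f"{a.sequence_id}\t{a.token}\t{a.value:.6g}\n")
    with open(out / "truth.json", "w") as fh:
        json.dump({sid: lst for sid, lst in truth.planted.items()}, fh, indent=1)
    return spec
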