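"""Attention-guided motif discovery: candidate selection, occurrence
counting, hypergeometric enrichment, FDR, merging, and the model contrast.

A token j of a sequence becomes a candidate motif when its normalised
attention stands out from the rest of that sequence:

    s_hat_j > mean(s_hat)  and  s_hat_j > 2 * min(s_hat)  and  len >= 4 bp

(strict inequalities; mean and min over the sequence's genomic tokens).
Candidate strings are then counted across all sequences with an Aho-Corasick
automaton — every occurrence, overlapping ones included — and tested for
enrichment in the positive class with the hypergeometric upper tail:

    X ~ Hypergeom(N, K, n),  p = P(X >= k)

where N is the number of sequences, K the positives, n the sequences
containing the motif and k the positives containing it. Benjamini-Hochberg
FDR (alpha = 0.01) controls multiplicity; motifs with fewer than three total
occurrences are discarded; surviving motifs are merged by gapless overlap
into consensus strings. Comparing the significant sets of two classifiers
trained against different negative sets (the set difference B \\ A) isolates
motifs unique to the more specific task.
"""

from __future__ import annotations

import logging
import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import AlphabetError, ConfigError, DomainError, ShapeError
from .windows import TokenSpan

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class CandidateMotif:
    """A high-attention token selected as a motif candidate."""

    motif: str
    source_sequence: str
    span: TokenSpan
    s_hat: float


@dataclass
class MotifCounts:
    """Occurrence counts of one motif over a sequence collection."""

    motif: str
    n: int  # sequences (any label) containing >= 1 occurrence
    k: int  # label-1 sequences containing >= 1 occurrence
    instances: int  # total occurrences, overlaps included
    locations: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class MotifEnrichment:
    motif: str
    N: int
    K: int
    n: int
    k: int
    instances: int
    p: float
    q: float = float("nan")
    significant: bool = False
    locations: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class MergedMotif:
    """A consensus string absorbing redundant (overlapping/contained) motifs."""

    consensus: str
    members: list[str]
    instances: list[tuple[str, int]] = field(default_factory=list)
    best_s_hat: float = float("nan")


# ---------------------------------------------------------------------------
# candidate selection
# ---------------------------------------------------------------------------

def candidate_tokens(
    spans: Sequence[TokenSpan],
    s_hat: np.ndarray,
    sequence_id: str = "",
    min_len: int = 4,
    mu: float | None = None,
    s_min: float | None = None,
) -> list[CandidateMotif]:
    """Tokens whose attention exceeds both the sequence mean and twice the
    sequence minimum, and whose span is at least ``min_len`` bp.

    ``mu`` / ``s_min`` override the per-sequence statistics for corpus-wide
    thresholding.
    """
    if len(spans) == 0:
        raise ShapeError("candidate selection needs at least one token span")
    s = np.asarray(s_hat, dtype=float)
    if s.shape[0] != len(spans):
        raise ShapeError(f"{len(spans)} spans but {s.shape[0]} attention scores")
    mu = float(s.mean()) if mu is None else mu
    s_min = float(s.min()) if s_min is None else s_min
    out = []
    for span, sj in zip(spans, s):
        if sj > mu and sj > 2.0 * s_min and (span.end - span.start) >= min_len:
            out.append(
                CandidateMotif(
                    motif=span.token.upper(),
                    source_sequence=sequence_id,
                    span=span,
                    s_hat=float(sj),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Aho-Corasick multi-pattern matching
# ---------------------------------------------------------------------------

class AhoCorasick:
    """Multi-pattern string automaton reporting every (overlapping) match.

    Classic construction: a trie of the patterns, failure links computed by
    breadth-first search, and output sets propagated along failure links so
    each text position reports all patterns ending there in O(matches).
    """

    def __init__(self, patterns: Sequence[str]):
        if not patterns:
            raise ConfigError("automaton needs at least one pattern")
        self.patterns = list(patterns)
        for p in self.patterns:
            if not p:
                raise ConfigError("empty pattern")
            bad = set(p) - DNA_ALPHABET
            if bad:
                raise AlphabetError(f"pattern {p!r} contains non-DNA characters {bad}")
        self._goto: list[dict[str, int]] = [{}]
        self._fail: list[int] = [0]
        self._out: list[list[int]] = [[]]
        for idx, pat in enumerate(self.patterns):
            state = 0
            for ch in pat:
                nxt = self._goto[state].get(ch)
                if nxt is None:
                    nxt = len(self._goto)
                    self._goto[state][ch] = nxt
                    self._goto.append({})
                    self._fail.append(0)
                    self._out.append([])
                state = nxt
            self._out[state].append(idx)
        queue: deque[int] = deque()
        for child in self._goto[0].values():
            queue.append(child)
        while queue:
            state = queue.popleft()
            for ch, child in self._goto[state].items():
                queue.append(child)
                f = self._fail[state]
                while f and ch not in self._goto[f]:
                    f = self._fail[f]
                self._fail[child] = self._goto[f].get(ch, 0)
                if self._fail[child] == child:
                    self._fail[child] = 0
                self._out[child] = self._out[child] + self._out[self._fail[child]]

    def iter_matches(self, text: str):
        """Yield ``(start_offset, pattern_index)`` for every occurrence."""
        state = 0
        goto, fail, out = self._goto, self._fail, self._out
        lengths = [len(p) for p in self.patterns]
        for i, ch in enumerate(text):
            while state and ch not in goto[state]:
                state = fail[state]
            state = goto[state].get(ch, 0)
            for idx in out[state]:
                yield i - lengths[idx] + 1, idx


def count_occurrences(
    motifs: Sequence[str],
    sequences: Sequence[tuple[str, int, str]],
) -> dict[str, MotifCounts]:
    """Count motif occurrences over ``(id, label, sequence)`` triples.

    Duplicated motifs are collapsed first; sequences are scanned uppercased
    (soft-masking does not hide matches); all overlapping occurrences count
    toward ``instances``.
    """
    unique = list(dict.fromkeys(m.upper() for m in motifs))
    if not unique:
        raise ConfigError("no motifs to count")
    ac = AhoCorasick(unique)
    counts = {m: MotifCounts(motif=m, n=0, k=0, instances=0) for m in unique}
    for seq_id, label, seq in sequences:
        seen: set[int] = set()
        for offset, idx in ac.iter_matches(seq.upper()):
            m = counts[unique[idx]]
            m.instances += 1
            m.locations.append((seq_id, offset))
            seen.add(idx)
        for idx in seen:
            m = counts[unique[idx]]
            m.n += 1
            if label == 1:
                m.k += 1
    return counts


def naive_count_occurrences(
    motifs: Sequence[str], sequences: Sequence[tuple[str, int, str]]
) -> dict[str, MotifCounts]:
    """Brute-force substring scan with the same contract as
    :func:`count_occurrences`; quadratic, intended for verification only."""
    unique = list(dict.fromkeys(m.upper() for m in motifs))
    counts = {m: MotifCounts(motif=m, n=0, k=0, instances=0) for m in unique}
    for seq_id, label, seq in sequences:
        up = seq.upper()
        for m in unique:
            hits = [i for i in range(len(up) - len(m) + 1) if up[i : i + len(m)] == m]
            if hits:
                counts[m].n += 1
                if label == 1:
                    counts[m].k += 1
                counts[m].instances += len(hits)
                counts[m].locations.extend((seq_id, i) for i in hits)
    return counts


# ---------------------------------------------------------------------------
# enrichment statistics
# ---------------------------------------------------------------------------

def _check_hypergeom_domain(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise DomainError(f"need 0 <= K <= N and 0 <= n <= N, got N={N}, K={K}, n={n}")
    lo, hi = max(0, n - (N - K)), min(K, n)
    if not lo <= k <= hi:
        raise DomainError(f"k={k} outside feasible range [{lo}, {hi}] for N={N}, K={K}, n={n}")


def hypergeometric_enrichment(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail enrichment probability P(X >= k), X ~ Hypergeom(N, K, n).

    The upper tail is the enrichment-relevant quantity: the chance of drawing
    at least k positives among the n motif-containing sequences when the n
    are sampled without replacement from N sequences of which K are positive.
    """
    _check_hypergeom_domain(N, K, n, k)
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeometric_pmf(N: int, K: int, n: int, k: int) -> float:
    """Point probability P(X = k) for the same distribution."""
    _check_hypergeom_domain(N, K, n, k)
    return float(hypergeom.pmf(k, N, K, n))


def fdr_correct(
    pvalues: Sequence[float], alpha: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (q-values, significant mask).

    Significance is ``q <= alpha``; q-values are invariant to input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def enrich_motifs(
    counts: Mapping[str, MotifCounts],
    N: int,
    K: int,
    alpha: float = 0.01,
) -> list[MotifEnrichment]:
    """Hypergeometric upper-tail test per motif with BH-FDR across motifs."""
    motifs = list(counts)
    results = []
    for m in motifs:
        c = counts[m]
        p = hypergeometric_enrichment(N, K, c.n, c.k)
        results.append(
            MotifEnrichment(
                motif=m, N=N, K=K, n=c.n, k=c.k, instances=c.instances,
                p=p, locations=list(c.locations),
            )
        )
    q, sig = fdr_correct([r.p for r in results], alpha=alpha)
    for r, qi, si in zip(results, q, sig):
        r.q = float(qi)
        r.significant = bool(si)
    return results


def filter_min_instances(
    results: Sequence[MotifEnrichment], min_instances: int = 3
) -> list[MotifEnrichment]:
    """Discard motifs with fewer than ``min_instances`` total occurrences."""
    kept = [r for r in results if r.instances >= min_instances]
    if results and not kept:
        warnings.warn(
            f"all {len(results)} motifs fall below {min_instances} instances",
            stacklevel=2,
        )
    return kept


# ---------------------------------------------------------------------------
# gapless-overlap merging
# ---------------------------------------------------------------------------

def _best_overlap(a: str, b: str, min_overlap: int) -> int:
    """Longest suffix of ``a`` equal to a prefix of ``b`` with length >=
    ``min_overlap`` (0 when none)."""
    top = min(len(a), len(b))
    for o in range(top, min_overlap - 1, -1):
        if a[-o:] == b[:o]:
            return o
    return 0


def _pair_merge(a: str, b: str, min_overlap: int) -> str | None:
    """Gapless superstring of a mergeable pair, else None.

    Containment absorbs; otherwise both overlap directions are tried and the
    longer resulting superstring wins (lexicographic tie-break)."""
    if b in a:
        return a
    if a in b:
        return b
    cands = []
    o = _best_overlap(a, b, min_overlap)
    if o:
        cands.append(a + b[o:])
    o = _best_overlap(b, a, min_overlap)
    if o:
        cands.append(b + a[o:])
    if not cands:
        return None
    return max(cands, key=lambda s: (len(s), [-ord(c) for c in s]))


def merge_redundant(
    motifs: Sequence[str],
    min_overlap: int = 4,
    s_hat_by_motif: Mapping[str, float] | None = None,
) -> list[MergedMotif]:
    """Iteratively merge motifs related by containment or by suffix/prefix
    overlap of at least ``min_overlap`` bp into gapless superstrings.

    Pairs are examined in descending-length, then lexicographic order and
    merging repeats to a fixpoint, so the result is deterministic. Each
    returned consensus records the original member motifs it absorbed.
    """
    pool: dict[str, set[str]] = {}
    for m in dict.fromkeys(motifs):
        pool.setdefault(m, set()).add(m)
    changed = True
    while changed:
        changed = False
        ordered = sorted(pool, key=lambda s: (-len(s), s))
        for i in range(len(ordered)):
            for j in range(i + 1, len(ordered)):
                merged = _pair_merge(ordered[i], ordered[j], min_overlap)
                if merged is None:
                    continue
                members = pool.pop(ordered[i]) | pool.pop(ordered[j])
                pool.setdefault(merged, set()).update(members)
                changed = True
                break
            if changed:
                break
    out = []
    for consensus in sorted(pool, key=lambda s: (-len(s), s)):
        members = sorted(pool[consensus])
        best = float("nan")
        if s_hat_by_motif:
            scores = [s_hat_by_motif[m] for m in members if m in s_hat_by_motif]
            if scores:
                best = max(scores)
        out.append(MergedMotif(consensus=consensus, members=members, best_s_hat=best))
    return out


def locate_instances(
    merged: Sequence[MergedMotif], sequences: Sequence[tuple[str, int, str]]
) -> None:
    """Fill each merged motif's instance list with exact consensus matches."""
    if not merged:
        return
    counts = count_occurrences([m.consensus for m in merged], sequences)
    for m in merged:
        m.instances = counts[m.consensus].locations


def extract_instance_windows(
    merged: MergedMotif,
    sequences: Mapping[str, str],
    flank: int = 12,
) -> list[tuple[str, str]]:
    """Sequence windows of ``±flank`` bp around each instance's center base
    (clipped at sequence ends), for downstream de novo motif tools."""
    center_shift = len(merged.consensus) // 2
    out = []
    for seq_id, offset in merged.instances:
        seq = sequences[seq_id]
        center = offset + center_shift
        lo = max(0, center - flank)
        hi = min(len(seq), center + flank + 1)
        out.append((f"{merged.consensus}|{seq_id}:{offset}", seq[lo:hi]))
    return out


def model_contrast(
    motifs_b: Iterable[str], motifs_a: Iterable[str], containment_aware: bool = False
) -> set[str]:
    """Motifs unique to the specific model: B \\ A.

    With ``containment_aware=True`` a B motif is also removed when it
    contains, or is contained in, any A motif.
    """
    b, a = set(motifs_b), set(motifs_a)
    if not containment_aware:
        return b - a
    return {m for m in b if not any(m in x or x in m for x in a)}


# ---------------------------------------------------------------------------
# end-to-end discovery and exports
# ---------------------------------------------------------------------------

def discover_motifs(
    sequences: Sequence[tuple[str, int, str]],
    spans_by_sequence: Mapping[str, Sequence[TokenSpan]],
    records,  # Iterable[AttentionRecord]
    layers: Sequence[int] | None = None,
    alpha: float = 0.01,
    min_instances: int = 3,
    min_len: int = 4,
    min_overlap: int = 4,
    correct_only: bool = True,
) -> tuple[list[MotifEnrichment], list[MergedMotif]]:
    """Full pipeline: attention records -> candidates -> counting ->
    enrichment + FDR -> instance filter -> gapless merge of significant motifs.

    Candidate sets from the selected ``layers`` are pooled by union; the
    enrichment universe is all ``sequences`` passed in (restrict these to the
    correctly predicted evaluation set upstream).
    """
    wanted = set(layers) if layers is not None else None
    candidates: dict[str, float] = {}
    for rec in records:
        if correct_only and not rec.correct_prediction:
            continue
        if wanted is not None and rec.layer not in wanted:
            continue
        spans = spans_by_sequence.get(rec.sequence_id)
        if spans is None:
            continue
        for cand in candidate_tokens(spans, rec.s_hat, rec.sequence_id, min_len=min_len):
            prev = candidates.get(cand.motif)
            if prev is None or cand.s_hat > prev:
                candidates[cand.motif] = cand.s_hat
    if not candidates:
        logger.info("no candidate motifs passed the attention thresholds")
        return [], []
    counts = count_occurrences(list(candidates), sequences)
    N = len(sequences)
    K = sum(1 for _, label, _ in sequences if label == 1)
    results = enrich_motifs(counts, N=N, K=K, alpha=alpha)
    results = filter_min_instances(results, min_instances=min_instances)
    significant = [r.motif for r in results if r.significant]
    merged = merge_redundant(significant, min_overlap=min_overlap, s_hat_by_motif=candidates)
    locate_instances(merged, sequences)
    return results, merged


def enrichment_table(results: Sequence[MotifEnrichment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif": r.motif, "N": r.N, "K": r.K, "n": r.n, "k": r.k,
                "instances": r.instances, "p": r.p, "q": r.q,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=["motif", "N", "K", "n", "k", "instances", "p", "q", "significant"],
    )


def write_meme_minimal(
    merged: Sequence[MergedMotif], path, background: Mapping[str, float] | None = None
) -> None:
    """Write consensus motifs in MEME minimal format (TOMTOM input).

    Each consensus base becomes a one-hot probability row; N becomes uniform.
    """
    bg = background or {b: 0.25 for b in "ACGT"}
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {bg[b]:.3f}" for b in "ACGT") + "\n\n")
        for m in merged:
            nsites = max(len(m.instances), 1)
            fh.write(f"MOTIF {m.consensus}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(m.consensus)} "
                f"nsites= {nsites} E= 0\n"
            )
            for ch in m.consensus:
                if ch == "N":
                    row = [0.25, 0.25, 0.25, 0.25]
                else:
                    row = [1.0 if b == ch else 0.0 for b in "ACGT"]
                fh.write(" ".join(f"{v:.3f}" for v in row) + "\n")
            fh.write("\n")
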