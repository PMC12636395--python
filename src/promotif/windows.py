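"""Strand-aware promoter windows around transcription start sites.

Positive examples are genomic windows spanning ``[-upstream, +downstream)``
around a TSS, returned 5'->3' so the TSS always sits at string offset
``upstream`` regardless of strand. Two negative-set constructions mirror the
two classifier designs this toolkit serves: uniformly random genomic windows
outside an exclusion set (general promoter biology) and GC/repeat-matched
windows (tissue-specific logic, where composition must not give the label
away). Repeat content is proxied by the soft-masked (lowercase) fraction of
the genome FASTA.

Coordinates are 0-based, half-open throughout, matching BED.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement
from intervaltree import IntervalTree

from .errors import (
    ChromosomeNotFoundError,
    ConfigError,
    CoordinateError,
    HighNContentError,
    PlacementError,
)

VALID_STRANDS = frozenset({"+", "-"})

#: Windows with more than this fraction of ambiguous bases are rejected;
#: degenerate N-runs tokenize into meaningless repeats.
MAX_N_FRACTION = 0.5


@dataclass(frozen=True)
class TSSRecord:
    """One transcription start site with its expression-group label."""

    chrom: str
    pos: int  # 0-based genomic coordinate of the TSS base
    strand: str
    transcript_id: str
    group: str = ""
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise CoordinateError(f"TSS position must be >= 0, got {self.pos}")
        if self.strand not in VALID_STRANDS:
            raise ConfigError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class PromoterWindow:
    """A 5'->3' sequence window with its genomic interval and label.

    ``sequence[upstream]`` is the TSS base; on the minus strand the stored
    string is the reverse complement of the reference slice. ``gc`` and
    ``repeat_frac`` are computed on the stored (strand-resolved) sequence.
    """

    id: str
    chrom: str
    genomic_start: int
    genomic_end: int
    strand: str
    upstream: int
    downstream: int
    sequence: str
    label: int
    gc: float = field(default=float("nan"))
    repeat_frac: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if len(self.sequence) != self.genomic_end - self.genomic_start:
            raise CoordinateError(
                f"window {self.id}: sequence length {len(self.sequence)} != "
                f"interval span {self.genomic_end - self.genomic_start}"
            )
        if len(self.sequence) != self.upstream + self.downstream:
            raise CoordinateError(
                f"window {self.id}: upstream+downstream "
                f"{self.upstream + self.downstream} != sequence length"
            )

    @property
    def tss_offset(self) -> int:
        """Offset of the TSS within ``sequence`` (equals ``upstream``)."""
        return self.upstream

    @property
    def tss_genomic_pos(self) -> int:
        """Genomic coordinate of the TSS (``offset_to_genomic(upstream)``)."""
        return offset_to_genomic(self, self.upstream)


@dataclass(frozen=True)
class TokenSpan:
    """A tokenizer unit: an uppercased substring of a window sequence."""

    token: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise CoordinateError(f"invalid span [{self.start}, {self.end})")
        if len(self.token) != self.end - self.start:
            raise CoordinateError(
                f"token length {len(self.token)} != span width {self.end - self.start}"
            )


class GenomeIntervals:
    """A per-chromosome interval set used for exclusion/overlap queries."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    @classmethod
    def from_tuples(cls, intervals: Iterable[tuple[str, int, int]]) -> "GenomeIntervals":
        out = cls()
        for chrom, start, end in intervals:
            out.add(chrom, start, end)
        return out

    @classmethod
    def from_windows(cls, windows: Iterable[PromoterWindow]) -> "GenomeIntervals":
        out = cls()
        for w in windows:
            out.add(w.chrom, w.genomic_start, w.genomic_end)
        return out

    def add(self, chrom: str, start: int, end: int) -> None:
        if end <= start:
            raise ConfigError(f"empty interval [{start}, {end}) on {chrom}")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    def __bool__(self) -> bool:
        return any(len(t) for t in self._trees.values())


# ---------------------------------------------------------------------------
# genome access helpers: accept plain dict-of-strings or a pyfaidx.Fasta
# ---------------------------------------------------------------------------

def _chrom_names(genome) -> list[str]:
    if isinstance(genome, Mapping):
        return list(genome.keys())
    return list(genome.keys())  # pyfaidx.Fasta also exposes keys()


def _chrom_length(genome, chrom: str) -> int:
    seq = _get_chrom(genome, chrom)
    return len(seq)


def _get_chrom(genome, chrom: str):
    try:
        return genome[chrom]
    except KeyError as exc:
        raise ChromosomeNotFoundError(chrom) from exc


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    record = _get_chrom(genome, chrom)
    if isinstance(record, str):
        return record[start:end]
    piece = record[start:end]  # pyfaidx FastaRecord slice
    return str(piece)


def gc_fraction(sequence: str) -> float:
    """GC fraction over unambiguous bases, case-insensitive."""
    up = sequence.upper()
    acgt = sum(up.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (up.count("G") + up.count("C")) / acgt


def repeat_fraction(sequence: str) -> float:
    """Fraction of soft-masked (lowercase) bases."""
    if not sequence:
        return 0.0
    return sum(1 for c in sequence if c.islower()) / len(sequence)


def n_fraction(sequence: str) -> float:
    up = sequence.upper()
    return up.count("N") / len(sequence) if sequence else 0.0


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------

def extract_window(
    tss: TSSRecord,
    genome,
    upstream: int,
    downstream: int,
    label: int = 1,
    max_n_fraction: float = MAX_N_FRACTION,
) -> PromoterWindow:
    """Extract a promoter window of ``upstream + downstream`` bp around a TSS.

    On the plus strand the genomic interval is ``[pos - upstream,
    pos + downstream)`` and the sequence is taken as-is; on the minus strand
    the interval is ``[pos - downstream, pos + upstream)`` and the slice is
    reverse-complemented, so the returned string always reads 5'->3' with the
    TSS at offset ``upstream``.
    """
    if upstream <= 0 or downstream <= 0:
        raise ConfigError("upstream and downstream must be positive")
    chrom_len = _chrom_length(genome, tss.chrom)
    if tss.strand == "+":
        start, end = tss.pos - upstream, tss.pos + downstream
    else:
        start, end = tss.pos - downstream, tss.pos + upstream
    if start < 0 or end > chrom_len:
        raise CoordinateError(
            f"window [{start}, {end}) around {tss.transcript_id} falls outside "
            f"{tss.chrom} (length {chrom_len})"
        )
    seq = _fetch(genome, tss.chrom, start, end)
    if tss.strand == "-":
        seq = reverse_complement(seq)
    if n_fraction(seq) > max_n_fraction:
        raise HighNContentError(
            f"window around {tss.transcript_id} is {100 * n_fraction(seq):.0f}% N"
        )
    return PromoterWindow(
        id=f"{tss.transcript_id}|{tss.chrom}:{start}-{end}:{tss.strand}:{label}",
        chrom=tss.chrom,
        genomic_start=start,
        genomic_end=end,
        strand=tss.strand,
        upstream=upstream,
        downstream=downstream,
        sequence=seq,
        label=label,
        gc=gc_fraction(seq),
        repeat_frac=repeat_fraction(seq),
    )


def offset_to_genomic(window: PromoterWindow, offset: int) -> int:
    """Map a window-string offset back to a reference coordinate.

    Plus strand: ``genomic_start + offset`` (the coordinate of that base).
    Minus strand the window string runs against the reference, so the map
    returns the half-open boundary ``genomic_end - offset``; a feature of
    length m starting at window offset o then occupies reference interval
    ``[offset_to_genomic(o + m), offset_to_genomic(o))``. Under either
    strand, offset ``upstream`` maps exactly to the TSS position.
    """
    if not 0 <= offset <= len(window.sequence):
        raise CoordinateError(f"offset {offset} outside window of length {len(window.sequence)}")
    if window.strand == "+":
        return window.genomic_start + offset
    return window.genomic_end - offset


# ---------------------------------------------------------------------------
# negative sets
# ---------------------------------------------------------------------------

def _placeable_chroms(genome, length: int) -> tuple[list[str], np.ndarray]:
    names = [c for c in _chrom_names(genome) if _chrom_length(genome, c) >= length]
    if not names:
        raise PlacementError(f"no chromosome can hold a {length} bp window")
    weights = np.array([_chrom_length(genome, c) - length + 1 for c in names], float)
    return names, weights / weights.sum()


def _make_negative(genome, chrom: str, start: int, length: int, tag: str) -> PromoterWindow:
    seq = _fetch(genome, chrom, start, start + length)
    return PromoterWindow(
        id=f"{tag}|{chrom}:{start}-{start + length}:+:0",
        chrom=chrom,
        genomic_start=start,
        genomic_end=start + length,
        strand="+",
        upstream=length,
        downstream=0,
        sequence=seq,
        label=0,
        gc=gc_fraction(seq),
        repeat_frac=repeat_fraction(seq),
    )


def sample_random_negatives(
    genome,
    n: int,
    length: int,
    exclusion: GenomeIntervals | None = None,
    seed: int = 0,
    attempts_per_window: int = 1000,
    max_n_fraction: float = MAX_N_FRACTION,
) -> list[PromoterWindow]:
    """Sample ``n`` mutually disjoint random genomic windows outside
    ``exclusion`` (label 0). Deterministic under ``seed``."""
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    names, probs = _placeable_chroms(genome, length)
    exclusion = exclusion or GenomeIntervals()
    placed = GenomeIntervals()
    out: list[PromoterWindow] = []
    budget = attempts_per_window * n
    attempts = 0
    while len(out) < n and attempts < budget:
        attempts += 1
        chrom = names[rng.choice(len(names), p=probs)]
        start = int(rng.integers(0, _chrom_length(genome, chrom) - length + 1))
        end = start + length
        if exclusion.overlaps(chrom, start, end) or placed.overlaps(chrom, start, end):
            continue
        win = _make_negative(genome, chrom, start, length, f"rand{len(out)}")
        if n_fraction(win.sequence) > max_n_fraction:
            continue
        placed.add(chrom, start, end)
        out.append(win)
    if len(out) < n:
        raise PlacementError(
            f"placed only {len(out)}/{n} random negatives after {attempts} attempts"
        )
    return out


@dataclass
class MatchReport:
    """Per-positive outcome of GC/repeat-matched sampling."""

    matched: pd.DataFrame  # columns: positive_id, negative_id, d_gc, d_repeat
    unmatched: list[str]


def sample_matched_negatives(
    genome,
    positives: Sequence[PromoterWindow],
    gc_tol: float = 0.02,
    repeat_tol: float = 0.05,
    exclusion: GenomeIntervals | None = None,
    seed: int = 0,
    attempts_per_positive: int = 1000,
    max_n_fraction: float = MAX_N_FRACTION,
    on_unmatched: str = "warn",
) -> tuple[list[PromoterWindow], MatchReport]:
    """One GC- and repeat-matched negative per positive, by rejection sampling.

    Each candidate is a uniform random window of the positive's length; it is
    accepted when ``|gc - gc_pos| <= gc_tol`` and ``|repeat_frac -
    repeat_pos| <= repeat_tol`` and it avoids the exclusion set and previously
    placed negatives. Positives that exhaust the attempt budget are listed in
    the returned :class:`MatchReport`; ``on_unmatched`` selects ``"warn"``
    (default), ``"raise"`` or ``"ignore"``.
    """
    if on_unmatched not in {"warn", "raise", "ignore"}:
        raise ConfigError(f"on_unmatched must be warn/raise/ignore, got {on_unmatched!r}")
    rng = np.random.default_rng(seed)
    exclusion = exclusion or GenomeIntervals()
    placed = GenomeIntervals()
    negatives: list[PromoterWindow] = []
    rows = []
    unmatched: list[str] = []
    for pos in positives:
        length = len(pos.sequence)
        names, probs = _placeable_chroms(genome, length)
        found = None
        for _ in range(attempts_per_positive):
            chrom = names[rng.choice(len(names), p=probs)]
            start = int(rng.integers(0, _chrom_length(genome, chrom) - length + 1))
            end = start + length
            if exclusion.overlaps(chrom, start, end) or placed.overlaps(chrom, start, end):
                continue
            cand = _make_negative(genome, chrom, start, length, f"match{len(negatives)}")
            if n_fraction(cand.sequence) > max_n_fraction:
                continue
            if abs(cand.gc - pos.gc) <= gc_tol and abs(cand.repeat_frac - pos.repeat_frac) <= repeat_tol:
                found = cand
                break
        if found is None:
            unmatched.append(pos.id)
            continue
        placed.add(found.chrom, found.genomic_start, found.genomic_end)
        negatives.append(found)
        rows.append(
            {
                "positive_id": pos.id,
                "negative_id": found.id,
                "d_gc": abs(found.gc - pos.gc),
                "d_repeat": abs(found.repeat_frac - pos.repeat_frac),
            }
        )
    report = MatchReport(
        matched=pd.DataFrame(rows, columns=["positive_id", "negative_id", "d_gc", "d_repeat"]),
        unmatched=unmatched,
    )
    if unmatched:
        msg = f"{len(unmatched)} positives could not be GC/repeat-matched: {unmatched[:5]}"
        if on_unmatched == "raise":
            raise PlacementError(msg)
        if on_unmatched == "warn":
            warnings.warn(msg, stacklevel=2)
    return negatives, report


# ---------------------------------------------------------------------------
# dataset splitting
# ---------------------------------------------------------------------------

def split_dataset(
    windows: Sequence[PromoterWindow],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list[PromoterWindow], list[PromoterWindow], list[PromoterWindow]]:
    """Label-stratified train/validation/test partition.

    Within each label group the train and validation sizes are floored and the
    remainder goes to test, so each part's label ratio stays within one item
    of the global ratio. Deterministic under ``seed``.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError(f"split fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    train: list[PromoterWindow] = []
    val: list[PromoterWindow] = []
    test: list[PromoterWindow] = []
    for lab in sorted({w.label for w in windows}):
        group = [w for w in windows if w.label == lab]
        order = rng.permutation(len(group))
        m = len(group)
        n_train = math.floor(fractions[0] * m)
        n_val = math.floor(fractions[1] * m)
        shuffled = [group[i] for i in order]
        train.extend(shuffled[:n_train])
        val.extend(shuffled[n_train : n_train + n_val])
        test.extend(shuffled[n_train + n_val :])
    return train, val, test


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_tss_bed(path, group_map: Mapping[str, str] | None = None, one_based: bool = False) -> list[TSSRecord]:
    """Read TSS records from 6-column BED (chrom, start, end, name, score, strand).

    The name column is the transcript id; the score column is repurposed as
    the expression-group label unless ``group_map`` (transcript_id -> group)
    overrides it. ``one_based=True`` declares 1-based input starts.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "score": str},
    )
    records = []
    for row in df.itertuples(index=False):
        start = int(row.start) - (1 if one_based else 0)
        end = int(row.end)
        pos = start if row.strand == "+" else end - 1
        group = group_map.get(row.name, str(row.score)) if group_map else str(row.score)
        records.append(
            TSSRecord(chrom=row.chrom, pos=pos, strand=row.strand, transcript_id=row.name, group=group)
        )
    return records


def write_windows_fasta(windows: Iterable[PromoterWindow], path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.id}\n{w.sequence}\n")


def windows_manifest(
    windows: Sequence[PromoterWindow], splits: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Tabular manifest (one row per window); ``splits`` maps id -> split name."""
    rows = [
        {
            "id": w.id,
            "chrom": w.chrom,
            "start": w.genomic_start,
            "end": w.genomic_end,
            "strand": w.strand,
            "label": w.label,
            "gc": w.gc,
            "repeat_frac": w.repeat_frac,
            "split": splits.get(w.id, "") if splits else "",
        }
        for w in windows
    ]
    return pd.DataFrame(rows)


def subset_to_representatives(
    windows: Sequence[PromoterWindow], representative_ids: Iterable[str]
) -> list[PromoterWindow]:
    """Keep only windows named in an externally produced representative-id list
    (e.g. cluster representatives from a redundancy-reduction run)."""
    keep = set(representative_ids)
    return [w for w in windows if w.id in keep]
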