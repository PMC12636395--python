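"""CLS attention scores, layer specificity, and classification metrics.

The classifier's [CLS] token attends over the J sequence tokens; summing the
per-head softmax rows gives one attention weight per token,

    alpha_j = sum_h softmax_j(q*.k_j / sqrt(d)),   sum_j alpha_j = H,

which is then max-normalised per sequence, s_hat_j = alpha_j / max(alpha),
so every sequence's strongest token scores exactly 1. A layer's usefulness
for motif extraction is summarised by the specificity

    Sp = (max s_hat - mean s_hat) / std s_hat,

the z-score of the attention peak: layers where attention concentrates on a
few tokens score high, layers with diffuse attention score near the expected
maximum of standardised noise. Summing rather than averaging over heads is
immaterial downstream — max-normalisation cancels the factor H.

Special tokens ([CLS], [SEP], padding) carry no genomic span and must be
stripped before these functions are applied; J indexes genomic tokens only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import softmax
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
)

from .errors import ConfigError, DegenerateInputError, ShapeError


@dataclass
class AttentionRecord:
    """Per-sequence, per-layer token attention (raw and normalised)."""

    sequence_id: str
    layer: int
    alpha: np.ndarray
    s_hat: np.ndarray
    heads: int
    correct_prediction: bool = True

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.s_hat = np.asarray(self.s_hat, dtype=float)
        if self.alpha.shape != self.s_hat.shape:
            raise ShapeError("alpha and s_hat must have equal length")
        if not (np.all(np.isfinite(self.alpha)) and np.all(np.isfinite(self.s_hat))):
            raise ValueError("attention vectors must be finite")


@dataclass
class LayerSpecificity:
    layer: int
    sp_per_sequence: np.ndarray
    sp_aggregate: float


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float


def cls_attention_from_qk(
    q_cls: Sequence[np.ndarray], keys: Sequence[np.ndarray], d: int | None = None
) -> np.ndarray:
    """Head-summed CLS attention from raw query/key vectors.

    ``q_cls[h]`` is the CLS query of head h (length d); ``keys[h]`` is the
    (J, d) key matrix of head h. Logits are scaled dot products
    ``q* . k_j / sqrt(d)``, softmaxed over tokens per head and summed over
    heads, so the result sums to H.
    """
    if len(q_cls) == 0 or len(q_cls) != len(keys):
        raise ShapeError("need one query vector and one key matrix per head")
    alphas = None
    for h, (q, k) in enumerate(zip(q_cls, keys)):
        q = np.asarray(q, dtype=float)
        k = np.asarray(k, dtype=float)
        if k.ndim != 2 or q.ndim != 1 or k.shape[1] != q.shape[0]:
            raise ShapeError(f"head {h}: keys must be (J, d) with d = len(q_cls)")
        if d is not None and q.shape[0] != d:
            raise ShapeError(f"head {h}: expected dimension {d}, got {q.shape[0]}")
        if not (np.all(np.isfinite(q)) and np.all(np.isfinite(k))):
            raise ValueError(f"head {h}: non-finite query/key values")
        logits = k @ q / np.sqrt(q.shape[0])
        p = softmax(logits)
        if alphas is None:
            alphas = p
        elif p.shape != alphas.shape:
            raise ShapeError("all heads must cover the same J tokens")
        else:
            alphas = alphas + p
    return alphas


def cls_attention_from_matrix(attn: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Head-summed CLS attention from an (H, J) matrix of CLS softmax rows.

    Each row must already be a probability vector over tokens; the result is
    the column sum (equivalently H times the head average).
    """
    attn = np.asarray(attn, dtype=float)
    if attn.ndim != 2:
        raise ShapeError(f"expected an (H, J) matrix, got shape {attn.shape}")
    if not np.all(np.isfinite(attn)):
        raise ValueError("attention matrix must be finite")
    sums = attn.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > tol)
    if bad.size:
        raise ValueError(
            f"head row {bad[0]} is not a probability vector (sums to {sums[bad[0]]:.6g})"
        )
    return attn.sum(axis=0)


def normalize_attention(alpha: np.ndarray) -> np.ndarray:
    """Scale attention so the strongest token scores exactly 1."""
    alpha = np.asarray(alpha, dtype=float)
    m = alpha.max(initial=0.0)
    if m <= 0:
        raise DegenerateInputError("cannot normalise an all-zero attention vector")
    return alpha / m


def layer_specificity(s_hat: np.ndarray, ddof: int = 0) -> float:
    """Z-score of the attention peak: (max - mean) / std.

    Population standard deviation by default (``ddof=0``); a constant vector
    has no peak and scores 0 by convention.
    """
    s_hat = np.asarray(s_hat, dtype=float)
    if s_hat.size < 2:
        raise ShapeError("layer specificity needs at least 2 tokens")
    sigma = s_hat.std(ddof=ddof)
    if sigma == 0:
        return 0.0
    return float((s_hat.max() - s_hat.mean()) / sigma)


def specificity_by_layer(
    records: Iterable[AttentionRecord],
    correct_only: bool = True,
    aggregate: str = "mean",
    ddof: int = 0,
) -> list[LayerSpecificity]:
    """Aggregate per-sequence specificity scores per layer.

    Only correctly predicted sequences contribute by default, so the ranking
    reflects attention the classifier actually used successfully.
    """
    if aggregate not in {"mean", "max"}:
        raise ConfigError(f"aggregate must be 'mean' or 'max', got {aggregate!r}")
    per_layer: dict[int, list[float]] = {}
    for rec in records:
        if correct_only and not rec.correct_prediction:
            continue
        per_layer.setdefault(rec.layer, []).append(layer_specificity(rec.s_hat, ddof=ddof))
    out = []
    for layer in sorted(per_layer):
        sps = np.asarray(per_layer[layer])
        agg = float(sps.mean() if aggregate == "mean" else sps.max())
        out.append(LayerSpecificity(layer=layer, sp_per_sequence=sps, sp_aggregate=agg))
    return out


def select_informative_layers(
    records: Iterable[AttentionRecord], k: int, aggregate: str = "mean"
) -> list[int]:
    """Top-k layers by aggregate specificity, ties broken by lower layer index."""
    stats = specificity_by_layer(records, aggregate=aggregate)
    if not stats:
        raise DegenerateInputError("no usable attention records (all mispredicted?)")
    if k > len(stats):
        raise ConfigError(f"requested top {k} of only {len(stats)} layers")
    ranked = sorted(stats, key=lambda s: (-s.sp_aggregate, s.layer))
    return [s.layer for s in ranked[:k]]


def classification_metrics(labels: Sequence[int], predictions: Sequence[int]) -> MetricReport:
    """Accuracy, precision, recall, F1 and MCC for binary labels.

    Undefined ratios (empty denominator) are reported as 0, including MCC
    when any confusion-matrix margin is empty.
    """
    y, p = np.asarray(labels), np.asarray(predictions)
    if y.shape != p.shape:
        raise ShapeError(f"labels {y.shape} vs predictions {p.shape}")
    return MetricReport(
        accuracy=float(accuracy_score(y, p)),
        precision=float(precision_score(y, p, zero_division=0)),
        recall=float(recall_score(y, p, zero_division=0)),
        f1=float(f1_score(y, p, zero_division=0)),
        mcc=float(matthews_corrcoef(y, p)),
    )
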