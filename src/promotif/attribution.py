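"""Aggregation and ranking of per-token attribution scores, and
cross-validation of attention-derived motifs against them.

Attribution scores (e.g. Shapley values for the positive class, produced by
any external explainer) arrive as one signed value per token occurrence.
Per unique token string we report the mean, the mean of absolute values
(which separates consistently-signed drivers from high-variance tokens),
the occurrence count, the sample standard deviation and a normal-theory 95%
confidence half-width 1.96 * std / sqrt(n). Tokens seen fewer than
``min_occurrences`` times are dropped as noise.

The attribution route is model-agnostic and independent of the attention
route; agreement between the two (a top-ranked token appearing inside a
discovered motif consensus, or vice versa) is the cross-validation signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError


@dataclass(frozen=True)
class TokenAttribution:
    """One occurrence-level attribution score."""

    sequence_id: str
    token: str
    value: float


@dataclass(frozen=True)
class TokenImportance:
    """Aggregated attribution statistics for one unique token string."""

    token: str
    n_occ: int
    mean: float
    abs_mean: float
    std: float
    ci95: float


RANK_KEYS = {"frequency": "n_occ", "mean": "mean", "abs_mean": "abs_mean"}


def aggregate_attributions(
    attrs: Sequence[TokenAttribution], min_occurrences: int = 3
) -> list[TokenImportance]:
    """One importance row per unique token with at least ``min_occurrences``
    occurrences. std is the sample (n-1) standard deviation; with
    ``min_occurrences = 1`` forced, singleton tokens get std = ci95 = 0."""
    if min_occurrences < 1:
        raise ConfigError(f"min_occurrences must be >= 1, got {min_occurrences}")
    if not attrs:
        raise ConfigError("no attributions to aggregate")
    if min_occurrences == 1:
        warnings.warn(
            "min_occurrences=1: singleton tokens get std and ci95 of 0",
            stacklevel=2,
        )
    df = pd.DataFrame(
        {"token": [a.token for a in attrs], "value": [a.value for a in attrs]}
    )
    out = []
    for token, grp in df.groupby("token", sort=True):
        v = grp["value"].to_numpy()
        if v.size < min_occurrences:
            continue
        std = float(v.std(ddof=1)) if v.size > 1 else 0.0
        out.append(
            TokenImportance(
                token=str(token),
                n_occ=int(v.size),
                mean=float(v.mean()),
                abs_mean=float(np.abs(v).mean()),
                std=std,
                ci95=1.96 * std / np.sqrt(v.size),
            )
        )
    return out


def rank_tokens(
    table: Sequence[TokenImportance],
    by: str = "abs_mean",
    top_k: int = 20,
    negative: bool = False,
) -> list[TokenImportance]:
    """Top-k tokens by frequency, mean or abs-mean.

    Descending by default (positive drivers); ``negative=True`` sorts the
    signed mean ascending to surface negative drivers. Ties break on the
    lexicographically smaller token.
    """
    if by not in RANK_KEYS:
        raise ConfigError(f"rank key must be one of {sorted(RANK_KEYS)}, got {by!r}")
    if top_k <= 0:
        raise ConfigError(f"top_k must be positive, got {top_k}")
    attr = RANK_KEYS[by]
    sign = 1.0 if negative else -1.0
    ranked = sorted(table, key=lambda t: (sign * getattr(t, attr), t.token))
    return ranked[:top_k]


@dataclass
class ConcordanceReport:
    """Containment-based agreement between motifs and top tokens."""

    motif_hits: pd.DataFrame  # consensus, corroborated, matching_tokens
    token_hits: pd.DataFrame  # token, corroborated, matching_motifs
    motif_fraction: float
    token_fraction: float


def cross_validate_motifs(
    motifs: Sequence,  # MergedMotif or plain consensus strings
    top_tokens: Sequence[TokenImportance],
) -> ConcordanceReport:
    """Check each attention-derived motif against the attribution top list.

    A motif is corroborated when any top token is a substring of its
    consensus or the consensus is a substring of the token; the symmetric
    token-level view is reported alongside.
    """
    if not motifs or not top_tokens:
        raise ConfigError("cross-validation needs both motifs and top tokens")
    consensi = [m if isinstance(m, str) else m.consensus for m in motifs]
    tokens = [t.token for t in top_tokens]
    motif_rows, token_matches = [], {t: [] for t in tokens}
    for c in consensi:
        hits = [t for t in tokens if t in c or c in t]
        for t in hits:
            token_matches[t].append(c)
        motif_rows.append(
            {"consensus": c, "corroborated": bool(hits), "matching_tokens": ",".join(hits)}
        )
    token_rows = [
        {"token": t, "corroborated": bool(ms), "matching_motifs": ",".join(ms)}
        for t, ms in token_matches.items()
    ]
    motif_df = pd.DataFrame(motif_rows)
    token_df = pd.DataFrame(token_rows)
    return ConcordanceReport(
        motif_hits=motif_df,
        token_hits=token_df,
        motif_fraction=float(motif_df["corroborated"].mean()),
        token_fraction=float(token_df["corroborated"].mean()),
    )


def importance_table(table: Sequence[TokenImportance]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "token": t.token, "n_occ": t.n_occ, "mean": t.mean,
                "abs_mean": t.abs_mean, "std": t.std, "ci95": t.ci95,
            }
            for t in table
        ],
        columns=["token", "n_occ", "mean", "abs_mean", "std", "ci95"],
    )


def read_attributions(path) -> list[TokenAttribution]:
    """Read an attribution table (TSV with sequence_id, token, value)."""
    df = pd.read_csv(path, sep="\t", dtype={"sequence_id": str, "token": str})
    return [
        TokenAttribution(row.sequence_id, row.token, float(row.value))
        for row in df.itertuples(index=False)
    ]
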