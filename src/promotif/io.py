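"""Containers for attention tensors and token spans.

Attention travels in HDF5 (one group per sequence; ``/<seq_id>/layer_<i>``
holds either an (H, J) matrix of CLS softmax rows or a pre-aggregated alpha
vector) with a JSON-lines fallback for small or streaming use. Token spans
travel in a companion TSV (sequence_id, index, token, start, end).
"""

from __future__ import annotations

import json
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .attention import AttentionRecord, cls_attention_from_matrix, normalize_attention
from .windows import TokenSpan


def write_attention_h5(records: Iterable[AttentionRecord], path) -> None:
    with h5py.File(path, "w") as fh:
        for rec in records:
            grp = fh.require_group(rec.sequence_id)
            ds = grp.create_dataset(f"layer_{rec.layer}", data=rec.alpha)
            ds.attrs["heads"] = rec.heads
            ds.attrs["correct_prediction"] = rec.correct_prediction


def read_attention_h5(path) -> list[AttentionRecord]:
    """Load attention records; 2-D datasets are treated as (H, J) CLS-row
    matrices and aggregated, 1-D datasets as ready alpha vectors."""
    records = []
    with h5py.File(path, "r") as fh:
        for seq_id in fh:
            grp = fh[seq_id]
            for name in grp:
                if not name.startswith("layer_"):
                    continue
                ds = grp[name]
                data = np.asarray(ds)
                if data.ndim == 2:
                    alpha = cls_attention_from_matrix(data)
                    heads = data.shape[0]
                else:
                    alpha = data
                    heads = int(ds.attrs.get("heads", 1))
                records.append(
                    AttentionRecord(
                        sequence_id=seq_id,
                        layer=int(name.split("_", 1)[1]),
                        alpha=alpha,
                        s_hat=normalize_attention(alpha),
                        heads=heads,
                        correct_prediction=bool(ds.attrs.get("correct_prediction", True)),
                    )
                )
    records.sort(key=lambda r: (r.sequence_id, r.layer))
    return records


def write_attention_jsonl(records: Iterable[AttentionRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                json.dumps(
                    {
                        "sequence_id": rec.sequence_id,
                        "layer": rec.layer,
                        "alpha": rec.alpha.tolist(),
                        "heads": rec.heads,
                        "correct_prediction": rec.correct_prediction,
                    }
                )
                + "\n"
            )


def read_attention_jsonl(path) -> list[AttentionRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            obj = json.loads(line)
            alpha = np.asarray(obj["alpha"], dtype=float)
            records.append(
                AttentionRecord(
                    sequence_id=obj["sequence_id"],
                    layer=int(obj["layer"]),
                    alpha=alpha,
                    s_hat=normalize_attention(alpha),
                    heads=int(obj.get("heads", 1)),
                    correct_prediction=bool(obj.get("correct_prediction", True)),
                )
            )
    return records


def write_token_spans(spans_by_sequence: Mapping[str, Sequence[TokenSpan]], path) -> None:
    rows = [
        {"sequence_id": sid, "index": i, "token": sp.token, "start": sp.start, "end": sp.end}
        for sid, spans in spans_by_sequence.items()
        for i, sp in enumerate(spans)
    ]
    pd.DataFrame(rows, columns=["sequence_id", "index", "token", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def read_token_spans(path) -> dict[str, list[TokenSpan]]:
    df = pd.read_csv(path, sep="\t", dtype={"sequence_id": str, "token": str})
    out: dict[str, list[TokenSpan]] = {}
    for row in df.sort_values(["sequence_id", "index"]).itertuples(index=False):
        out.setdefault(row.sequence_id, []).append(
            TokenSpan(token=row.token, start=int(row.start), end=int(row.end))
        )
    return out


def read_fasta_sequences(path) -> list[tuple[str, int, str]]:
    """Read windows FASTA into (id, label, sequence) triples; the label is
    the trailing ``:<label>`` field of the record id (0 when absent)."""
    out = []
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    out.append((name, _label_from_id(name), "".join(chunks)))
                name, chunks = line[1:].split()[0], []
            else:
                chunks.append(line)
    if name is not None:
        out.append((name, _label_from_id(name), "".join(chunks)))
    return out


def _label_from_id(name: str) -> int:
    tail = name.rsplit(":", 1)[-1]
    return int(tail) if tail in {"0", "1"} else 0
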