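"""File formats: corpus JSONL, targets CSV, manifests, attention CSV.

A corpus is JSONL with one object per transcript: ``{"id": str, "tokens":
[int, ...]`` or ``"text": str, "word_count": int, "covariates": {...}}``.
When records carry ``"text"`` a whitespace tokenizer with a corpus-built
vocabulary maps words to ids (id 0 is reserved for padding). Targets are CSV
with columns transcript_id, O, C, E, A, N on the raw 0-192 scale.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import TRAITS
from .windowing import Transcript


class WhitespaceVocab:
    """Word -> integer-id map built from a corpus; 0 is the pad id."""

    def __init__(self, word_to_id=None):
        self.word_to_id = dict(word_to_id or {})

    @classmethod
    def build(cls, texts) -> "WhitespaceVocab":
        words = sorted({w for text in texts for w in text.split()})
        return cls({w: i + 1 for i, w in enumerate(words)})

    def __len__(self):
        return len(self.word_to_id)

    def tokenize(self, text: str) -> np.ndarray:
        unk = len(self.word_to_id) + 1
        return np.array(
            [self.word_to_id.get(w, unk) for w in text.split()], dtype=np.int64
        )

    def save(self, path):
        Path(path).write_text(json.dumps(self.word_to_id))

    @classmethod
    def load(cls, path) -> "WhitespaceVocab":
        return cls(json.loads(Path(path).read_text()))


def write_corpus(transcripts, path):
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(json.dumps({
                "id": t.transcript_id,
                "tokens": [int(x) for x in t.tokens],
                "word_count": int(t.word_count),
                "covariates": t.covariates,
            }, sort_keys=True) + "\n")


def read_corpus(path, vocab: WhitespaceVocab = None):
    transcripts = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            if "tokens" in rec:
                tokens = np.asarray(rec["tokens"], dtype=np.int64)
            elif "text" in rec:
                if vocab is None:
                    raise ValueError("text-format corpus needs a vocabulary")
                tokens = vocab.tokenize(rec["text"])
            else:
                raise ValueError(f"record {rec.get('id')} has neither tokens nor text")
            transcripts.append(Transcript(
                transcript_id=str(rec["id"]),
                tokens=tokens,
                word_count=int(rec.get("word_count", len(tokens))),
                covariates=rec.get("covariates", {}),
            ))
    return transcripts


def write_targets(targets: pd.DataFrame, path):
    targets.to_csv(path, index=False)


def read_targets(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("transcript_id", *TRAITS) if c not in df.columns]
    if missing:
        raise ValueError(f"targets CSV missing columns: {missing}")
    df["transcript_id"] = df["transcript_id"].astype(str)
    return df


def profiles_to_csv(profiles, wsets, path):
    """Attention profiles as CSV rows (transcript_id, trait, window_index, offset, alpha)."""
    rows = []
    for p in profiles:
        offsets = wsets[p.transcript_id].offsets if p.transcript_id in wsets else None
        for i, a in enumerate(p.alpha):
            rows.append({
                "transcript_id": p.transcript_id,
                "trait": p.trait,
                "window_index": i,
                "offset": int(offsets[i]) if offsets is not None and i < len(offsets) else -1,
                "alpha": float(a),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_manifest(path, config: dict, seed: int):
    payload = {"config": config, "seed": seed}
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()
    payload["config_hash"] = digest
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True, default=str))
    return digest
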