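"""Synthetic narrative corpora with planted, window-localized trait signal.

The real interview corpus this package targets is access-restricted, so every
pipeline stage is exercised on generated data with known ground truth. Each
synthetic participant gets five latent standard-normal trait values z; the raw
trait score on the 0-192 inventory scale is ``clip(100 + 20 z + delta*g + eps)``.
Transcripts are unigram token streams: inside a designated set S of windows,
tokens are drawn from a trait-specific signal vocabulary at rate
``logistic(beta * z)``; everywhere else signal tokens appear at a constant base
rate. The planted window set S is what attention and occlusion analyses are
expected to recover.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .windowing import Transcript, WindowConfig, window_offsets

TRAITS = ("O", "C", "E", "A", "N")


def logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def plant_positions(mode: str, n_windows: int) -> list:
    """Window indices carrying signal: first 2 / centered 2 / last 2 / every 3rd."""
    t = n_windows
    if t < 1:
        raise ValueError("n_windows must be >= 1")
    if mode == "early":
        s = [0, 1]
    elif mode == "middle":
        lo = max((t - 2) // 2, 0)
        s = [lo, lo + 1]
    elif mode == "late":
        s = [t - 2, t - 1]
    elif mode == "diffuse":
        s = list(range(0, t, 3))
    else:
        raise ValueError(f"unknown planting mode {mode!r}")
    s = sorted({min(max(i, 0), t - 1) for i in s})
    return s


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative recipe; defaults emulate a SPAN-like interview corpus."""

    n_transcripts: int = 1400
    words_mean: float = 2500.0
    words_sigma_log: float = 0.45
    min_words: int = 50
    vocab_size: int = 5000
    signal_tokens_per_trait: int = 40
    base_rate: float = 0.1
    beta: float = 1.0
    sigma_eps: float = 4.0
    gender_delta: float = 0.0
    signal_mode: str = "diffuse"
    # optional content heterogeneity: background tokens can mix in per-block
    # "topic" tokens, mimicking windows that each discuss their own subject;
    # off by default (the planted-signal contracts assume a flat background)
    topic_tokens_per_block: int = 3
    topic_rate: float = 0.0
    window: WindowConfig = field(default_factory=WindowConfig)
    seed: int = 0

    def __post_init__(self):
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")
        if self.beta < 0 or self.sigma_eps < 0:
            raise ValueError("beta and sigma_eps must be >= 0")
        if self.vocab_size <= len(TRAITS) * self.signal_tokens_per_trait:
            raise ValueError("vocab too small for the signal token sets")

    def signal_token_range(self, trait_index: int):
        m = self.signal_tokens_per_trait
        return 1 + trait_index * m, 1 + (trait_index + 1) * m

    @property
    def background_start(self) -> int:
        return 1 + len(TRAITS) * self.signal_tokens_per_trait


@dataclass
class GroundTruth:
    """Per-transcript latents; persisted next to the corpus, never fed to models."""

    records: dict  # transcript_id -> {z, raw, gender, signal_windows, n_windows}

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.records, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            return cls(records=json.load(fh))


def generate(spec: SyntheticSpec):
    """Return (transcripts, targets DataFrame, GroundTruth), all seed-determined."""
    rng = np.random.default_rng(spec.seed)
    n_traits = len(TRAITS)
    mu_log = np.log(spec.words_mean) - spec.words_sigma_log**2 / 2.0
    w, s = spec.window.window_size, spec.window.stride

    transcripts, rows, records = [], [], {}
    for i in range(spec.n_transcripts):
        tid = f"synth{i:05d}"
        length = int(max(spec.min_words, round(rng.lognormal(mu_log, spec.words_sigma_log))))
        z = rng.standard_normal(n_traits)
        gender = int(rng.integers(0, 2))
        eps = rng.normal(0.0, spec.sigma_eps, size=n_traits) if spec.sigma_eps > 0 else np.zeros(n_traits)
        raw = np.clip(100.0 + 20.0 * z + spec.gender_delta * gender + eps, 0.0, 192.0)

        n_win = min(len(window_offsets(length, w, s)), spec.window.max_segments)
        sig_windows = plant_positions(spec.signal_mode, n_win)
        in_sig = np.zeros(length, dtype=bool)
        for wi in sig_windows:
            in_sig[wi * s : min(wi * s + w, length)] = True

        trait_pick = rng.integers(0, n_traits, size=length)
        rate = np.where(in_sig, logistic(spec.beta * z[trait_pick]), spec.base_rate)
        is_signal = rng.random(length) < rate
        sig_off = rng.integers(0, spec.signal_tokens_per_trait, size=length)
        # Background tokens mix a flat unigram draw with per-block "topic"
        # tokens, giving windows the content heterogeneity of real narrative
        # (each stride-length block talks about its own random topic).
        bg = rng.integers(spec.background_start, spec.vocab_size + 1, size=length)
        if spec.topic_rate > 0 and spec.topic_tokens_per_block > 0:
            n_blocks = (length + s - 1) // s
            block_topics = rng.integers(
                spec.background_start, spec.vocab_size + 1,
                size=(n_blocks, spec.topic_tokens_per_block),
            )
            block_of = np.minimum(np.arange(length) // s, n_blocks - 1)
            topical = rng.random(length) < spec.topic_rate
            which = rng.integers(0, spec.topic_tokens_per_block, size=length)
            bg = np.where(topical, block_topics[block_of, which], bg)
        tokens = np.where(
            is_signal,
            1 + trait_pick * spec.signal_tokens_per_trait + sig_off,
            bg,
        ).astype(np.int64)

        transcripts.append(
            Transcript(
                transcript_id=tid,
                tokens=tokens,
                word_count=length,
                covariates={"gender": gender},
            )
        )
        rows.append({"transcript_id": tid, **{t: raw[k] for k, t in enumerate(TRAITS)}})
        records[tid] = {
            "z": z.tolist(),
            "raw": {t: float(raw[k]) for k, t in enumerate(TRAITS)},
            "gender": gender,
            "signal_windows": sig_windows,
            "n_windows": n_win,
        }
    targets = pd.DataFrame(rows)
    return transcripts, targets, GroundTruth(records=records)


def spec_manifest(spec: SyntheticSpec) -> dict:
    d = asdict(spec)
    d["window"] = asdict(spec.window)
    return d
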