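"""Sliding-window segmentation of long transcripts.

A transcript of L tokens is cut into overlapping windows of ``window_size``
tokens advanced by ``stride``. When the remainder divides evenly this yields
T = (L - w) / s + 1 windows; otherwise one final partial window is appended
and right-padded with the pad token so that every real token is covered.
Window sequences are padded (and, past ``max_segments``, truncated) to a
fixed segment count so they can be batched downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    tokens: np.ndarray  # int token ids, length >= 1
    word_count: int
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self, "tokens", np.asarray(self.tokens, dtype=np.int64)
        )
        if self.tokens.size == 0:
            raise ValueError(f"transcript {self.transcript_id}: empty token sequence")
        if self.word_count < 0:
            raise ValueError(f"transcript {self.transcript_id}: negative word_count")


@dataclass(frozen=True)
class WindowConfig:
    """w=512 tokens with stride 256 (50% overlap), padded to 40 segments."""

    window_size: int = 512
    stride: int = 256
    max_segments: int = 40
    pad_token: int = 0

    def __post_init__(self):
        if self.window_size < 1 or self.stride < 1:
            raise ValueError("window_size and stride must be positive")
        if self.stride > self.window_size:
            raise ValueError("stride must not exceed window_size")
        if self.max_segments < 1:
            raise ValueError("max_segments must be >= 1")


@dataclass
class WindowSet:
    transcript_id: str
    windows: np.ndarray  # (max_segments, window_size) int
    mask: np.ndarray  # (max_segments,) bool, True = real window
    offsets: np.ndarray  # (T,) start token index of each real window
    config: WindowConfig

    @property
    def n_windows(self) -> int:
        return int(self.mask.sum())


def filter_corpus(transcripts, min_words: int = 50):
    """Drop transcripts shorter than ``min_words`` words (strictly fewer)."""
    if min_words < 0:
        raise ValueError("min_words must be >= 0")
    transcripts = list(transcripts)
    kept = [t for t in transcripts if t.word_count >= min_words]
    removed = len(transcripts) - len(kept)
    if removed:
        logger.info("filter_corpus: removed %d transcripts under %d words", removed, min_words)
    if not kept:
        raise ValueError("filter_corpus: no transcripts remain after length filter")
    return kept


def window_offsets(length: int, window_size: int, stride: int) -> list:
    """Start offsets 0, s, 2s, ... until the whole sequence is covered."""
    offsets = [0]
    while offsets[-1] + window_size < length:
        offsets.append(offsets[-1] + stride)
    return offsets


def segment(transcript: Transcript, config: WindowConfig) -> WindowSet:
    tokens = transcript.tokens
    w, s, t_max = config.window_size, config.stride, config.max_segments
    offsets = window_offsets(len(tokens), w, s)
    if len(offsets) > t_max:
        logger.warning(
            "segment: transcript %s yields %d windows, truncating to %d",
            transcript.transcript_id, len(offsets), t_max,
        )
        offsets = offsets[:t_max]
    windows = np.full((t_max, w), config.pad_token, dtype=np.int64)
    mask = np.zeros(t_max, dtype=bool)
    for i, off in enumerate(offsets):
        chunk = tokens[off : off + w]
        windows[i, : len(chunk)] = chunk
        mask[i] = True
    return WindowSet(
        transcript_id=transcript.transcript_id,
        windows=windows,
        mask=mask,
        offsets=np.asarray(offsets, dtype=np.int64),
        config=config,
    )


def remove_window(wset: WindowSet, index: int) -> WindowSet:
    """Delete one real window (occlusion); survivors compact left, offsets kept."""
    t = wset.n_windows
    if index < 0 or index >= len(wset.mask) or not wset.mask[index]:
        raise ValueError(f"remove_window: index {index} is not a real window")
    if t <= 1:
        raise ValueError("remove_window: cannot remove the only window")
    keep = [i for i in range(t) if i != index]
    windows = np.full_like(wset.windows, wset.config.pad_token)
    windows[: t - 1] = wset.windows[keep]
    mask = np.zeros_like(wset.mask)
    mask[: t - 1] = True
    return replace(
        wset,
        windows=windows,
        mask=mask,
        offsets=wset.offsets[keep],
    )
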