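"""Attention-based interpretability: top windows, occlusion, embedding probes.

The attention weights learned by the aggregator double as explanations: the
windows with the largest alpha are the model's claimed evidence. Two checks
ground that claim. Leave-one-window-out occlusion removes the highest-alpha
window and reports the percentage change of the raw-scale prediction (a
positive drop means the window was driving the score up). The embedding
probe fits a ridge regression on either a single random window's embedding
or the mean embedding over all windows, quantifying how much trait signal a
partial versus full context carries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.metrics import r2_score

from .aggregator import AttentionProfile
from .windowing import WindowSet, remove_window

__all__ = [
    "AttributionReport",
    "ProbeResult",
    "top_k_windows",
    "occlusion_drop",
    "attention_distribution",
    "embedding_probe",
]


@dataclass
class AttributionReport:
    transcript_id: str
    trait: str
    topk: list  # [{"window_index", "offset", "alpha"}], alpha descending
    drop_pct: float  # signed; negative = score rose after removal
    raw_full: float
    raw_removed: float
    removed_index: int


@dataclass
class ProbeResult:
    mode: str  # "single_window" | "mean_all_windows"
    probe_r2: float
    n_train: int
    n_test: int


def top_k_windows(profile: AttentionProfile, k: int, offsets=None) -> list:
    """The min(k, T) real windows with largest alpha; ties -> lower index."""
    if k < 1:
        raise ValueError("k must be >= 1")
    real = np.flatnonzero(profile.mask if profile.mask is not None else profile.alpha > 0)
    ranked = sorted(real, key=lambda i: (-profile.alpha[i], i))[: min(k, len(real))]
    return [
        {
            "window_index": int(i),
            "offset": int(offsets[i]) if offsets is not None and i < len(offsets) else None,
            "alpha": float(profile.alpha[i]),
        }
        for i in ranked
    ]


def occlusion_drop(model, wset: WindowSet, k: int = 3) -> AttributionReport:
    """Remove the argmax-attention window, re-run the frozen pipeline, and
    report the signed percentage drop of the raw-scale prediction.

    ``model`` is a trained :class:`~traitlens.training.TraitModel`. The
    occluded transcript is NOT re-segmented: the window is deleted and the
    survivors re-encoded, matching window-granular removal.
    """
    if wset.n_windows < 2:
        raise ValueError("occlusion needs at least 2 windows")
    _, raw_full, profile = model.predict_windows(wset)
    if raw_full == 0.0:
        raise ValueError("occlusion drop undefined: full-set prediction is 0")
    top = top_k_windows(profile, k, offsets=wset.offsets)
    removed_index = top[0]["window_index"]
    reduced = remove_window(wset, removed_index)
    _, raw_removed, reduced_profile = model.predict_windows(reduced)
    reduced_profile.validate()
    return AttributionReport(
        transcript_id=wset.transcript_id,
        trait=model.trait,
        topk=top,
        drop_pct=float(100.0 * (raw_full - raw_removed) / raw_full),
        raw_full=float(raw_full),
        raw_removed=float(raw_removed),
        removed_index=removed_index,
    )


def attention_distribution(profiles) -> dict:
    """Per-trait normalized attention curves for one shared transcript.

    Returns ``{trait: {"alpha": vector summing to 1 over real windows,
    "thirds": (first, middle, last mass)}}``.
    """
    profiles = list(profiles)
    tids = {p.transcript_id for p in profiles}
    if len(tids) != 1:
        raise ValueError("attention_distribution expects profiles of one transcript")
    out = {}
    for p in profiles:
        real = np.flatnonzero(p.mask if p.mask is not None else p.alpha > 0)
        alpha = p.alpha.copy()
        alpha[real] = alpha[real] / alpha[real].sum()
        chunks = np.array_split(real, 3)
        thirds = tuple(float(alpha[c].sum()) if len(c) else 0.0 for c in chunks)
        out[p.trait] = {"alpha": alpha, "thirds": thirds}
    return out


def embedding_probe(embeds, targets, mode: str, ridge_penalty: float = 1.0,
                    split_seed: int = 0) -> ProbeResult:
    """Ridge-probe R^2 of trait targets from window embeddings.

    ``mode="single_window"`` uses one randomly chosen real window per
    transcript; ``mode="mean_all_windows"`` uses the masked mean over all
    real windows. Fit on a seeded 80:20 split; R^2 on the held-out part.
    """
    embeds, targets = list(embeds), np.asarray(targets, dtype=np.float64)
    if len(embeds) < 20:
        raise ValueError("embedding probe needs >=20 transcripts")
    rng = np.random.default_rng(split_seed)
    if mode == "single_window":
        feats = []
        for e in embeds:
            real = np.flatnonzero(e.mask)
            feats.append(e.vectors[rng.choice(real)])
        features = np.stack(feats)
    elif mode == "mean_all_windows":
        features = np.stack(
            [e.vectors[e.mask].mean(axis=0) for e in embeds]
        )
    else:
        raise ValueError(f"unknown probe mode {mode!r}")
    order = rng.permutation(len(embeds))
    n_train = int(round(0.8 * len(embeds)))
    tr, te = order[:n_train], order[n_train:]
    probe = Ridge(alpha=ridge_penalty).fit(features[tr], targets[tr])
    r2 = float(r2_score(targets[te], probe.predict(features[te])))
    return ProbeResult(mode=mode, probe_r2=r2, n_train=len(tr), n_test=len(te))
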