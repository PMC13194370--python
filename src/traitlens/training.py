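"""Two-step and continuous-flow training with leakage-safe target scaling.

Workflow per fold and trait: fit a z-score scaler on the fold's training
targets only; fine-tune the segment encoder on window-level MSE (every window
inherits its transcript's normalized target); freeze it; train the sequence
aggregator on the frozen embeddings; report test MSE and R^2 in the
normalized space. The continuous-flow (CF) ablation instead optimizes
encoder and aggregator jointly with a single loss.

Cross-validation uses a seeded shuffle into equal folds (default 5, i.e. an
80:20 train:test split) with 5% of each fold's training portion reserved for
early-stopping validation. Early stopping halts after `patience` epochs
without validation-MSE improvement and restores the best checkpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import r2_score

from .aggregator import AggregatorConfig, AttentionProfile, build_variant, predict as agg_predict
from .encoder import EmbeddingSequence, TinyEncoder, finetune_encoder, median_baseline
from .nn import Adam, Tensor, concat, stack
from .windowing import Transcript, WindowConfig, segment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetScaler:
    """Per-trait (mu, sigma) fit on training-fold targets only."""

    trait: str
    mu: float
    sigma: float  # population standard deviation

    @classmethod
    def fit(cls, values, trait: str = "") -> "TargetScaler":
        values = np.asarray(values, dtype=np.float64)
        if len(np.unique(values)) < 2:
            raise ValueError("scaler needs >=2 distinct target values")
        sigma = float(values.std())  # ddof=0
        if sigma == 0.0:
            raise ValueError("degenerate targets: sigma = 0")
        return cls(trait=trait, mu=float(values.mean()), sigma=sigma)

    def transform(self, y):
        return (np.asarray(y, dtype=np.float64) - self.mu) / self.sigma

    def inverse(self, y_norm):
        return np.asarray(y_norm, dtype=np.float64) * self.sigma + self.mu


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-5  # aggregator / ablation default
    stage1_lr: float = 2e-5  # segment-encoder fine-tuning default
    batch: int = 8
    max_epochs: int = 50
    patience: int = 5
    min_delta: float = 0.0  # minimum val-MSE improvement that counts as progress
    seed: int = 0

    def __post_init__(self):
        if min(self.lr, self.stage1_lr) <= 0 or self.batch < 1 or self.max_epochs < 0:
            raise ValueError("invalid training configuration")


@dataclass
class FoldPlan:
    n_folds: int
    val_fraction: float
    seed: int
    folds: list  # [{"train": [...], "val": [...], "test": [...]}, ...]

    @property
    def assignments(self) -> dict:
        return {tid: k for k, f in enumerate(self.folds) for tid in f["test"]}


def make_folds(ids, n_folds: int = 5, val_fraction: float = 0.05, seed: int = 0) -> FoldPlan:
    ids = list(ids)
    if len(ids) < n_folds:
        raise ValueError("fewer transcripts than folds")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    splits = np.array_split(np.arange(len(ids)), n_folds)
    folds = []
    for k in range(n_folds):
        test = [order[i] for i in splits[k]]
        pool = [t for t in order if t not in set(test)]
        pool = [pool[i] for i in rng.permutation(len(pool))]
        n_val = int(round(val_fraction * len(pool))) if val_fraction > 0 else 0
        folds.append({"train": pool[n_val:], "val": pool[:n_val], "test": test})
    return FoldPlan(n_folds=n_folds, val_fraction=val_fraction, seed=seed, folds=folds)


def evaluate(y_true, y_pred):
    """(MSE, R^2) in normalized space; R^2 about the test-set mean."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if len(y_true) < 2:
        raise ValueError("R^2 undefined for fewer than 2 test points")
    mse = float(np.mean((y_true - y_pred) ** 2))
    return mse, float(r2_score(y_true, y_pred))


@dataclass
class TraitModel:
    """Frozen encoder + trained aggregator + fold scaler: one trait's model."""

    trait: str
    encoder: TinyEncoder
    aggregator: object
    scaler: TargetScaler
    window_config: WindowConfig

    def predict_transcript(self, transcript: Transcript):
        wset = segment(transcript, self.window_config)
        return self.predict_windows(wset)

    def predict_windows(self, wset):
        embeds = self.encoder.encode_windows(wset)
        score, profile = agg_predict(self.aggregator, embeds, trait=self.trait)
        return score, float(self.scaler.inverse(score)), profile


def _batchify(embed_targets):
    xs = np.stack([e.vectors for e, _ in embed_targets])
    ms = np.stack([e.mask for e, _ in embed_targets])
    ys = np.array([y for _, y in embed_targets], dtype=np.float64)
    return xs, ms, ys


def train_aggregator(model, train_set, val_set, config: TrainConfig) -> dict:
    """Stage-2 training loop on frozen embedding sequences."""
    if not train_set:
        raise ValueError("empty stage-2 training set")
    x_tr, m_tr, y_tr = _batchify(train_set)
    x_va, m_va, y_va = _batchify(val_set) if val_set else (x_tr, m_tr, y_tr)

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.lr)
    history = {"train_mse": [], "val_mse": [], "best_epoch": -1, "epochs_run": 0}
    best_val, best_state, since_best = np.inf, model.state_dict(), 0
    n = len(y_tr)
    for epoch in range(config.max_epochs):
        model.train()
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch):
            idx = order[start : start + config.batch]
            pred, _ = model.forward(x_tr[idx], m_tr[idx])
            loss = ((pred - y_tr[idx]) ** 2.0).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        model.eval()
        val_pred, _ = model.forward(x_va, m_va)
        val_mse = float(np.mean((val_pred.data - y_va) ** 2))
        history["train_mse"].append(epoch_loss / n)
        history["val_mse"].append(val_mse)
        history["epochs_run"] = epoch + 1
        if val_mse < best_val - config.min_delta:
            best_val, best_state, since_best = val_mse, model.state_dict(), 0
            history["best_epoch"] = epoch
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    model.load_state_dict(best_state)
    model.eval()
    return history


@dataclass
class FoldResult:
    model: TraitModel
    report_row: dict
    predictions: pd.DataFrame  # transcript_id, y_true_norm, y_pred_norm, y_pred_raw
    stage1_history: dict = field(default_factory=dict)
    stage2_history: dict = field(default_factory=dict)
    embeddings: dict = field(default_factory=dict)  # id -> EmbeddingSequence


def _trait_targets(targets: pd.DataFrame, trait: str) -> dict:
    if trait not in targets.columns:
        raise ValueError(f"targets table has no column for trait {trait!r}")
    return dict(zip(targets["transcript_id"], targets[trait].astype(float)))


def _segment_all(transcripts, window_config):
    return {t.transcript_id: segment(t, window_config) for t in transcripts}


def two_step_train(
    transcripts,
    targets: pd.DataFrame,
    trait: str,
    encoder: TinyEncoder,
    window_config: WindowConfig,
    agg_config: AggregatorConfig,
    train_config: TrainConfig,
    fold: dict,
) -> FoldResult:
    """Fine-tune -> freeze -> aggregate for one trait on one fold."""
    y_raw = _trait_targets(targets, trait)
    missing = [tid for part in ("train", "val", "test") for tid in fold[part] if tid not in y_raw]
    if missing:
        raise ValueError(f"missing targets for transcripts: {missing[:5]}")
    by_id = {t.transcript_id: t for t in transcripts}
    wsets = _segment_all([by_id[tid] for part in ("train", "val", "test") for tid in fold[part]],
                         window_config)

    scaler = TargetScaler.fit([y_raw[tid] for tid in fold["train"]], trait=trait)
    norm = {tid: float(scaler.transform(y_raw[tid])) for tid in y_raw}

    # stage 1: window-level fine-tuning of the segment encoder
    stage1_cfg = TrainConfig(
        lr=train_config.stage1_lr, stage1_lr=train_config.stage1_lr,
        batch=train_config.batch, max_epochs=train_config.max_epochs,
        patience=train_config.patience, min_delta=train_config.min_delta,
        seed=train_config.seed,
    )
    h1 = finetune_encoder(
        encoder,
        [(wsets[tid], norm[tid]) for tid in fold["train"]],
        stage1_cfg,
        val_pairs=[(wsets[tid], norm[tid]) for tid in fold["val"]] or None,
    )
    encoder.freeze()
    frozen_checksum = encoder.checksum()

    embeds = {tid: encoder.encode_windows(wsets[tid]) for tid in wsets}

    # stage 2: sequence aggregation over frozen embeddings
    model = build_variant(agg_config)
    h2 = train_aggregator(
        model,
        [(embeds[tid], norm[tid]) for tid in fold["train"]],
        [(embeds[tid], norm[tid]) for tid in fold["val"]],
        train_config,
    )
    if encoder.checksum() != frozen_checksum:
        raise RuntimeError("two-step isolation violated: encoder changed in stage 2")

    return _finish_fold(
        "2step-" + agg_config.variant, trait, encoder, model, scaler,
        window_config, wsets, embeds, norm, fold, h1, h2,
        extra_row={"encoder_checksum_post_stage1": frozen_checksum},
    )


def _finish_fold(variant, trait, encoder, model, scaler, window_config,
                 wsets, embeds, norm, fold, h1, h2, extra_row=None) -> FoldResult:
    test_ids = fold["test"]
    x, m, _ = _batchify([(embeds[tid], 0.0) for tid in test_ids])
    model.eval()
    pred, _ = model.forward(x, m)
    y_true = np.array([norm[tid] for tid in test_ids])
    y_pred = pred.data
    mse, r2 = evaluate(y_true, y_pred)

    base_pred = np.array([median_baseline(encoder, wsets[tid]) for tid in test_ids])
    base_mse, base_r2 = evaluate(y_true, base_pred)

    row = {
        "trait": trait, "variant": variant, "mse": mse, "r2": r2,
        "baseline_mse": base_mse, "baseline_r2": base_r2,
        "stage1_epochs": h1.get("epochs_run", 0), "stage1_best": h1.get("best_epoch", -1),
        "epochs_run": h2["epochs_run"], "best_epoch": h2["best_epoch"],
        "n_test": len(test_ids), "scaler_mu": scaler.mu, "scaler_sigma": scaler.sigma,
        "train_ids": tuple(fold["train"]),
        **(extra_row or {}),
    }
    preds = pd.DataFrame({
        "transcript_id": test_ids,
        "y_true_norm": y_true,
        "y_pred_norm": y_pred,
        "y_pred_raw": scaler.inverse(y_pred),
        "baseline_norm": base_pred,
    })
    logger.info("%s/%s: test MSE %.4f R2 %.4f (baseline R2 %.4f)", variant, trait, mse, r2, base_r2)
    bundle = TraitModel(trait, encoder, model, scaler, window_config)
    return FoldResult(bundle, row, preds, h1, h2, embeds)


def cf_train(
    transcripts,
    targets: pd.DataFrame,
    trait: str,
    encoder: TinyEncoder,
    window_config: WindowConfig,
    agg_config: AggregatorConfig,
    train_config: TrainConfig,
    fold: dict,
) -> FoldResult:
    """Continuous-flow ablation: encoder + aggregator trained end to end."""
    if encoder.frozen:
        raise ValueError("cf_train requires an unfrozen encoder")
    y_raw = _trait_targets(targets, trait)
    by_id = {t.transcript_id: t for t in transcripts}
    wsets = _segment_all([by_id[tid] for part in ("train", "val", "test") for tid in fold[part]],
                         window_config)
    scaler = TargetScaler.fit([y_raw[tid] for tid in fold["train"]], trait=trait)
    norm = {tid: float(scaler.transform(y_raw[tid])) for tid in y_raw}

    model = build_variant(agg_config)
    params = encoder.parameters() + model.parameters()
    opt = Adam(params, lr=train_config.lr)
    rng = np.random.default_rng(train_config.seed)
    t_max = window_config.max_segments
    d = encoder.embed_dim

    def joint_forward(tid):
        ws = wsets[tid]
        cls = encoder.forward_cls(ws.windows[ws.mask])  # (T, d) in-graph
        n_pad = t_max - ws.n_windows
        if n_pad:
            cls = concat([cls, Tensor(np.zeros((n_pad, d)))], axis=0)
        return cls

    def eval_mse(ids):
        model.eval()
        embeds = [(encoder.encode_windows(wsets[tid]), norm[tid]) for tid in ids]
        x, m, y = _batchify(embeds)
        pred, _ = model.forward(x, m)
        return float(np.mean((pred.data - y) ** 2))

    history = {"train_mse": [], "val_mse": [], "best_epoch": -1, "epochs_run": 0}
    best_val, since_best = np.inf, 0
    best_state = (encoder.state_dict(), model.state_dict())
    train_ids = list(fold["train"])
    val_ids = list(fold["val"]) or train_ids
    for epoch in range(train_config.max_epochs):
        model.train()
        order = rng.permutation(len(train_ids))
        epoch_loss = 0.0
        for start in range(0, len(train_ids), train_config.batch):
            batch = [train_ids[i] for i in order[start : start + train_config.batch]]
            x = stack([joint_forward(tid) for tid in batch], axis=0)
            m = np.stack([wsets[tid].mask for tid in batch])
            y = np.array([norm[tid] for tid in batch])
            pred, _ = model.forward(x, m)
            loss = ((pred - y) ** 2.0).mean()
            opt.zero_grad()
            for p in params:
                p.grad = None
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(batch)
        val_mse = eval_mse(val_ids)
        history["train_mse"].append(epoch_loss / len(train_ids))
        history["val_mse"].append(val_mse)
        history["epochs_run"] = epoch + 1
        if val_mse < best_val - train_config.min_delta:
            best_val, since_best = val_mse, 0
            best_state = (encoder.state_dict(), model.state_dict())
            history["best_epoch"] = epoch
        else:
            since_best += 1
            if since_best >= train_config.patience:
                break
    encoder.load_state_dict(best_state[0])
    model.load_state_dict(best_state[1])
    model.eval()

    embeds = {tid: encoder.encode_windows(wsets[tid]) for tid in wsets}
    return _finish_fold(
        "cf-" + agg_config.variant, trait, encoder, model, scaler,
        window_config, wsets, embeds, norm, fold, {}, history,
    )


def summarize_report(rows) -> pd.DataFrame:
    """Per-(variant, trait) mean and sd of the fold metrics."""
    df = pd.DataFrame(rows)
    metrics = ["mse", "r2", "baseline_mse", "baseline_r2"]
    out = df.groupby(["variant", "trait"])[metrics].agg(["mean", "std"])
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()
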