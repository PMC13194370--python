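"""Sensitivity and bias audits on saved predictions.

Transcripts are stratified by length (short < 1,500 words; medium 1,500-3,500
inclusive; long > 3,500) and per-stratum MSE/R^2 are recomputed from test
predictions. Covariate bias is measured as the Pearson correlation between a
covariate (gender coded 0/1, or word count) and the model's predictions, with
the standard t-test p-value; no multiple-testing correction is applied across
trait models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .training import evaluate

SHORT_MAX = 1500  # short: word_count < 1500
LONG_MIN = 3500  # long: word_count > 3500
STRATA_LABELS = ("short", "medium", "long")


@dataclass(frozen=True)
class BiasReport:
    trait: str
    covariate: str
    pearson_r: float
    p_value: float
    n: int


def stratify_by_length(transcripts) -> dict:
    """Partition transcripts into short/medium/long word-count strata."""
    out = {label: [] for label in STRATA_LABELS}
    for t in transcripts:
        if t.word_count < SHORT_MAX:
            out["short"].append(t.transcript_id)
        elif t.word_count > LONG_MIN:
            out["long"].append(t.transcript_id)
        else:
            out["medium"].append(t.transcript_id)
    return out


def strata_metrics(predictions: pd.DataFrame, strata: dict) -> dict:
    """Test metrics restricted to each stratum.

    ``predictions`` needs columns transcript_id, y_true_norm, y_pred_norm.
    Strata with fewer than 2 test transcripts are reported as None rather
    than raising.
    """
    out = {}
    for label, ids in strata.items():
        sub = predictions[predictions["transcript_id"].isin(set(ids))]
        if len(sub) < 2:
            out[label] = {"mse": None, "r2": None, "n": len(sub)}
            continue
        mse, r2 = evaluate(sub["y_true_norm"], sub["y_pred_norm"])
        out[label] = {"mse": mse, "r2": r2, "n": len(sub)}
    return out


def covariate_correlation(predictions, covariate_values, trait: str = "",
                          covariate_name: str = "") -> BiasReport:
    """Pearson r (two-sided p) between predictions and a numeric covariate."""
    x = np.asarray(predictions, dtype=np.float64)
    y = np.asarray(covariate_values, dtype=np.float64)
    if len(x) != len(y):
        raise ValueError("predictions and covariate differ in length")
    if len(x) < 3:
        raise ValueError("correlation needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in predictions or covariate")
    r, p = stats.pearsonr(x, y)
    return BiasReport(trait=trait, covariate=covariate_name,
                      pearson_r=float(r), p_value=float(p), n=len(x))
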