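"""Weighted-average ensemble and precision-recall evaluation.

The ensemble prediction is the convex combination

    P(alpha) = alpha * P_RNN + (1 - alpha) * P_CNN,

with ``alpha`` chosen to maximize AUPRC on the inner 10% tuning patients
over a 0.01-step grid (ties broken toward the smallest alpha; because the
grid contains 0 and 1, the tuned ensemble can never score below either
single model on the tuning set).

AUPRC uses the average-precision estimator (step integration over ranked
positives, tied scores grouped into one step); AUROC is the tie-corrected
rank statistic. Precision at a sensitivity target picks the highest
threshold whose sensitivity reaches the target, with no interpolation.
Confidence intervals come from 1000 bootstrap resamples of 50% of the
segments drawn without replacement (2.5th/97.5th percentiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .beats import UnsliceableSegmentError, build_beat_matrix, detect_beats, scale_values
from .models import PredictionSet
from .qc import QCThresholds, check_segment

SENSITIVITY_TARGETS = (0.6, 0.7, 0.8)


def _scores_labels(predictions, labels=None) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(predictions, PredictionSet):
        if predictions.labels is None:
            raise ValueError("PredictionSet has no labels")
        return predictions.probabilities, np.asarray(predictions.labels)
    return np.asarray(predictions, dtype=np.float64), np.asarray(labels)


def _ranked_counts(scores: np.ndarray, labels: np.ndarray):
    """Cumulative TP/FP after each distinct-score group, scores descending."""
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    # last index of each tied-score group
    last = np.flatnonzero(np.diff(s) != 0)
    ends = np.concatenate([last, [s.size - 1]])
    cum_tp = np.cumsum(y == 1)[ends]
    cum_fp = np.cumsum(y == 0)[ends]
    return s[ends], cum_tp, cum_fp


def auprc(predictions, labels=None) -> float:
    """Average precision: sum over score groups of dRecall x precision."""
    scores, y = _scores_labels(predictions, labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    _, tp, fp = _ranked_counts(scores, y)
    recall = tp / n_pos
    precision = tp / (tp + fp)
    d_recall = np.diff(np.concatenate([[0.0], recall]))
    return float(np.sum(d_recall * precision))


def auroc(predictions, labels=None) -> float:
    """Probability a random positive outranks a random negative; ties count half."""
    scores, y = _scores_labels(predictions, labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def precision_at_sensitivity(predictions, target: float, labels=None) -> tuple[float, float, float]:
    """(threshold, precision, achieved sensitivity) at the highest threshold
    whose sensitivity is >= target; classification rule is score >= threshold."""
    scores, y = _scores_labels(predictions, labels)
    if not 0.0 < target <= 1.0:
        raise ValueError("target must be in (0, 1]")
    n_pos = int(np.sum(y == 1))
    if n_pos == 0 or np.sum(y == 0) == 0:
        raise ValueError("both classes must be present")
    thresholds, tp, fp = _ranked_counts(scores, y)
    sens = tp / n_pos
    idx = int(np.argmax(sens >= target))  # first (highest-threshold) group reaching target
    return (
        float(thresholds[idx]),
        float(tp[idx] / (tp[idx] + fp[idx])),
        float(sens[idx]),
    )


@dataclass
class EnsembleWeights:
    alpha: float
    grid: np.ndarray
    curve: np.ndarray  # tuning AUPRC at each grid alpha

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


def _check_aligned(p_rnn: PredictionSet, p_cnn: PredictionSet) -> None:
    if len(p_rnn.ids) != len(p_cnn.ids) or not np.array_equal(p_rnn.ids, p_cnn.ids):
        raise ValueError("prediction sets are not aligned on the same segments")


def optimize_alpha(
    p_rnn: PredictionSet, p_cnn: PredictionSet, grid_step: float = 0.01
) -> EnsembleWeights:
    """Grid-search the mixing weight by tuning-set AUPRC."""
    _check_aligned(p_rnn, p_cnn)
    if p_rnn.labels is None:
        raise ValueError("tuning predictions need labels")
    y = np.asarray(p_rnn.labels)
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2.0, grid_step), 10)
    curve = np.array(
        [
            auprc(a * p_rnn.probabilities + (1.0 - a) * p_cnn.probabilities, y)
            for a in grid
        ]
    )
    best = int(np.argmax(curve))  # argmax returns the first = smallest alpha on ties
    return EnsembleWeights(alpha=float(grid[best]), grid=grid, curve=curve)


def ensemble_predict(
    p_rnn: PredictionSet, p_cnn: PredictionSet, weights: EnsembleWeights | float
) -> PredictionSet:
    """Elementwise convex combination of aligned prediction sets."""
    _check_aligned(p_rnn, p_cnn)
    alpha = weights.alpha if isinstance(weights, EnsembleWeights) else float(weights)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return PredictionSet(
        ids=p_rnn.ids,
        probabilities=alpha * p_rnn.probabilities + (1.0 - alpha) * p_cnn.probabilities,
        labels=p_rnn.labels,
        model_tag="ensemble",
    )


def bootstrap_ci(
    predictions,
    metric,
    labels=None,
    n_resamples: int = 1000,
    fraction: float = 0.5,
    seed: int = 0,
    replace: bool = False,
) -> tuple[float, float]:
    """95% CI of ``metric`` over resamples of ``fraction`` of the segments.

    Resampling is segment-level and without replacement by default;
    single-class resamples are redrawn. Deterministic given ``seed``.
    """
    scores, y = _scores_labels(predictions, labels)
    n = scores.size
    m = int(np.floor(fraction * n))
    if m < 2:
        raise ValueError(f"resample size {m} too small (n={n}, fraction={fraction})")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 53)))
    values = np.empty(n_resamples)
    for i in range(n_resamples):
        for _ in range(1000):
            idx = rng.choice(n, size=m, replace=replace)
            ys = y[idx]
            if ys.min() != ys.max():
                break
        else:
            raise ValueError("could not draw a two-class resample")
        values[i] = metric(scores[idx], ys)
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class EvalReport:
    """Point metrics with bootstrap CIs for one model's predictions."""

    model_tag: str
    n_segments: int
    n_positive: int
    auprc: float
    auprc_ci: tuple[float, float]
    auroc: float
    auroc_ci: tuple[float, float]
    precision_at: dict
    n_resamples: int
    resample_fraction: float

    def to_dict(self) -> dict:
        return {
            "model": self.model_tag,
            "n_segments": self.n_segments,
            "n_positive": self.n_positive,
            "auprc": self.auprc,
            "auprc_ci": list(self.auprc_ci),
            "auroc": self.auroc,
            "auroc_ci": list(self.auroc_ci),
            "precision_at_sensitivity": self.precision_at,
            "n_resamples": self.n_resamples,
            "resample_fraction": self.resample_fraction,
        }


def evaluate_predictions(
    predictions: PredictionSet,
    n_resamples: int = 1000,
    fraction: float = 0.5,
    seed: int = 0,
    sensitivity_targets=SENSITIVITY_TARGETS,
) -> EvalReport:
    """Full metric panel with bootstrap CIs for one prediction set."""
    scores, y = _scores_labels(predictions)
    prec_block: dict = {}
    for target in sensitivity_targets:
        thr, prec, sens = precision_at_sensitivity(scores, target, labels=y)
        ci = bootstrap_ci(
            scores,
            lambda s, yy, t=target: precision_at_sensitivity(s, t, labels=yy)[1],
            labels=y,
            n_resamples=n_resamples,
            fraction=fraction,
            seed=seed,
        )
        prec_block[f"{target:.1f}"] = {
            "threshold": thr,
            "precision": prec,
            "achieved_sensitivity": sens,
            "precision_ci": list(ci),
        }
    return EvalReport(
        model_tag=predictions.model_tag,
        n_segments=int(scores.size),
        n_positive=int(np.sum(y == 1)),
        auprc=auprc(scores, y),
        auprc_ci=bootstrap_ci(
            scores, lambda s, yy: auprc(s, yy), labels=y, n_resamples=n_resamples,
            fraction=fraction, seed=seed,
        ),
        auroc=auroc(scores, y),
        auroc_ci=bootstrap_ci(
            scores, lambda s, yy: auroc(s, yy), labels=y, n_resamples=n_resamples,
            fraction=fraction, seed=seed,
        ),
        precision_at=prec_block,
        n_resamples=n_resamples,
        resample_fraction=fraction,
    )


def predict_over_record(
    record,
    models: dict,
    weights: EnsembleWeights | float,
    stride_s: float = 20.0,
    qc_thresholds: QCThresholds | None = None,
) -> pd.DataFrame:
    """Sliding 20-s-window ensemble prediction trace over one record.

    Returns a frame with columns ``time_s`` (window END time), ``p_cnn``,
    ``p_rnn`` and ``p_ensemble``; QC-invalid or unsliceable windows carry
    NaN. Suitable for plotting against the 2-s moving-average pressure.
    """
    qc_thresholds = qc_thresholds or QCThresholds()
    fs = 100
    in_len = 20 * fs
    if record.n_samples < in_len:
        raise ValueError(f"record shorter than 20 s ({record.n_samples} samples)")
    stride = int(round(stride_s * fs))
    starts = list(range(0, record.n_samples - in_len + 1, stride))
    alpha = weights.alpha if isinstance(weights, EnsembleWeights) else float(weights)

    x_cnn, x_rnn, ok = [], [], []
    for s in starts:
        window = record.pressure[s : s + in_len]
        if not check_segment(window, qc_thresholds).valid:
            ok.append(False)
            continue
        try:
            beats = detect_beats(window)
            x_rnn.append(build_beat_matrix(beats).values)
        except (UnsliceableSegmentError, ValueError):
            ok.append(False)
            continue
        x_cnn.append(scale_values(window))
        ok.append(True)

    n = len(starts)
    p_cnn = np.full(n, np.nan)
    p_rnn = np.full(n, np.nan)
    if x_cnn:
        valid = np.flatnonzero(ok)
        pc = models["cnn"].predict(np.asarray(x_cnn)).probabilities
        pr = models["rnn"].predict(np.asarray(x_rnn)).probabilities
        p_cnn[valid] = pc
        p_rnn[valid] = pr
    return pd.DataFrame(
        {
            "time_s": record.t0 + (np.asarray(starts) + in_len) / fs,
            "p_cnn": p_cnn,
            "p_rnn": p_rnn,
            "p_ensemble": alpha * p_rnn + (1.0 - alpha) * p_cnn,
        }
    )
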