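import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from stepop.ensemble import (
    auprc,
    auroc,
    bootstrap_ci,
    ensemble_predict,
    optimize_alpha,
    precision_at_sensitivity,
    predict_over_record,
)
from stepop.models import PredictionSet
from stepop.record_io import WaveformRecord


def pset(scores, labels, tag="m"):
    return PredictionSet(
        ids=np.arange(len(scores)), probabilities=np.asarray(scores, dtype=float),
        labels=np.asarray(labels), model_tag=tag,
    )


def pairwise_auroc(scores, labels):
    """O(n^2) oracle: P(pos outranks neg), ties count one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def enumerate_auprc(scores, labels):
    """Oracle: walk distinct thresholds high to low, sum dRecall x precision."""
    order = sorted(set(scores), reverse=True)
    n_pos = sum(labels)
    ap, prev_rec = 0.0, 0.0
    for thr in order:
        sel = [y for s, y in zip(scores, labels) if s >= thr]
        tp = sum(sel)
        rec, prec = tp / n_pos, tp / len(sel)
        ap += (rec - prev_rec) * prec
        prev_rec = rec
    return ap


def test_perfect_ranking_gives_auprc_one():
    assert auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0


def test_three_point_worked_example():
    assert auprc([0.9, 0.8, 0.7], [0, 1, 1]) == pytest.approx(7 / 12)


def test_auprc_matches_oracles_on_random_fixtures():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = int(rng.integers(5, 200))
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            continue
        s = np.round(rng.random(n), 2)  # coarse scores force ties
        got = auprc(s, y)
        assert got == pytest.approx(enumerate_auprc(list(s), list(y)), abs=1e-12)
        assert got == pytest.approx(average_precision_score(y, s), abs=1e-12)


def test_random_scores_null_auprc_is_prevalence():
    rng = np.random.default_rng(1)
    n = 100_000
    y = (rng.random(n) < 0.13).astype(int)
    s = rng.random(n)
    assert auprc(s, y) == pytest.approx(y.mean(), abs=0.01)


def test_auroc_perfect_ties_and_pair_oracle():
    assert auroc([0.9, 0.8, 0.2], [1, 1, 0]) == 1.0
    assert auroc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5
    rng = np.random.default_rng(2)
    for _ in range(30):
        n = int(rng.integers(5, 120))
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            continue
        s = np.round(rng.random(n), 1)
        got = auroc(s, y)
        assert got == pytest.approx(pairwise_auroc(list(s), list(y)), abs=1e-12)
        assert got == pytest.approx(roc_auc_score(y, s), abs=1e-12)


def test_single_class_inputs_rejected():
    with pytest.raises(ValueError):
        auprc([0.5, 0.6], [1, 1])
    with pytest.raises(ValueError):
        auroc([0.5, 0.6], [0, 0])


def test_precision_at_sensitivity_enumeration():
    thr, prec, sens = precision_at_sensitivity([0.9, 0.6, 0.4, 0.2], 0.6, labels=[1, 0, 1, 0])
    # highest threshold reaching sens>=0.6 admits both positives
    assert thr == pytest.approx(0.4)
    assert sens == 1.0
    assert prec == pytest.approx(2 / 3)


def test_precision_at_full_sensitivity_captures_all_positives():
    scores = [0.9, 0.5, 0.3, 0.1]
    labels = [1, 0, 1, 0]
    thr, _, sens = precision_at_sensitivity(scores, 1.0, labels=labels)
    assert thr <= 0.3
    assert sens == 1.0


def test_perfect_classifier_precision_is_one():
    _, prec, sens = precision_at_sensitivity([0.9, 0.8, 0.1], 0.8, labels=[1, 1, 0])
    assert prec == 1.0 and sens == 1.0


def test_alpha_tie_breaks_to_zero_when_models_identical():
    p = pset([0.8, 0.6, 0.3], [1, 1, 0])
    w = optimize_alpha(p, p)
    assert w.alpha == 0.0
    assert np.allclose(w.curve, w.curve[0])


def test_alpha_prefers_the_ranking_model():
    y = [1, 1, 0, 0]
    p_rnn = pset([0.9, 0.8, 0.2, 0.1], y, "rnn")
    p_cnn = pset([0.1, 0.2, 0.8, 0.9], y, "cnn")
    w = optimize_alpha(p_rnn, p_cnn)
    assert auprc(w.alpha * p_rnn.probabilities + (1 - w.alpha) * p_cnn.probabilities,
                 np.array(y)) == 1.0
    assert w.alpha > 0.5


def test_alpha_matches_brute_force_grid():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, 60)
    y[:5] = 1
    y[5:10] = 0
    pr = pset(rng.random(60), y, "rnn")
    pc = pset(rng.random(60), y, "cnn")
    w = optimize_alpha(pr, pc, grid_step=0.01)
    grid = np.round(np.arange(0, 1.0001, 0.01), 10)
    brute = [auprc(a * pr.probabilities + (1 - a) * pc.probabilities, y) for a in grid]
    assert w.alpha == grid[int(np.argmax(brute))]
    assert np.allclose(w.curve, brute)
    # grid contains the endpoints, so the tuned mix dominates both single models
    assert w.curve.max() >= max(brute[0], brute[-1])


def test_ensemble_endpoints_and_worked_combination():
    y = [1, 0]
    pr = pset([0.8, 0.3], y, "rnn")
    pc = pset([0.6, 0.2], y, "cnn")
    assert np.array_equal(ensemble_predict(pr, pc, 0.0).probabilities, pc.probabilities)
    assert np.array_equal(ensemble_predict(pr, pc, 1.0).probabilities, pr.probabilities)
    out = ensemble_predict(pset([0.8], [1]), pset([0.6], [1]), 0.65)
    assert out.probabilities[0] == pytest.approx(0.73)


def test_ensemble_monotone_in_alpha_when_rnn_dominates():
    y = [1, 0, 1]
    pr = pset([0.9, 0.5, 0.8], y, "rnn")
    pc = pset([0.4, 0.2, 0.6], y, "cnn")
    prev = None
    for a in np.linspace(0, 1, 11):
        cur = ensemble_predict(pr, pc, a).probabilities
        if prev is not None:
            assert np.all(cur >= prev - 1e-12)
        prev = cur


def test_misaligned_prediction_sets_rejected():
    pr = pset([0.8, 0.3], [1, 0], "rnn")
    pc = PredictionSet(ids=np.array([5, 6]), probabilities=np.array([0.5, 0.5]),
                       labels=np.array([1, 0]), model_tag="cnn")
    with pytest.raises(ValueError, match="aligned"):
        ensemble_predict(pr, pc, 0.5)


def test_bootstrap_is_deterministic_and_degenerate_for_perfect_scores():
    rng = np.random.default_rng(4)
    y = rng.integers(0, 2, 200)
    y[:10] = 1
    y[10:20] = 0
    s = y + rng.normal(0, 1e-6, 200)  # essentially perfect
    ci1 = bootstrap_ci(s, lambda a, b: auprc(a, b), labels=y, n_resamples=100, seed=5)
    ci2 = bootstrap_ci(s, lambda a, b: auprc(a, b), labels=y, n_resamples=100, seed=5)
    assert ci1 == ci2
    assert ci1[1] - ci1[0] < 1e-9


def test_bootstrap_ci_covers_point_estimate():
    rng = np.random.default_rng(6)
    hits = 0
    trials = 60
    for _ in range(trials):
        n = 300
        y = rng.integers(0, 2, n)
        y[:5] = 1
        y[5:10] = 0
        s = np.clip(y * 0.3 + rng.random(n) * 0.7, 0, 1)
        point = auprc(s, y)
        lo, hi = bootstrap_ci(s, lambda a, b: auprc(a, b), labels=y,
                              n_resamples=200, seed=int(rng.integers(1 << 30)))
        hits += lo <= point <= hi
    assert hits >= trials - 1


def test_bootstrap_rejects_tiny_samples():
    with pytest.raises(ValueError):
        bootstrap_ci([0.5, 0.6], lambda a, b: auprc(a, b), labels=[1, 0], fraction=0.5)


class _StubModel:
    """Predicts 1 - mean of the scaled window / matrix (lower pressure -> higher risk)."""

    def predict(self, X, ids=None, labels=None):
        probs = 1.0 - np.asarray(X).reshape(len(X), -1).mean(axis=1)
        return PredictionSet(ids=np.arange(len(probs)), probabilities=np.clip(probs, 0, 1),
                             labels=None, model_tag="stub")


def test_predict_over_record_requires_20s():
    rec = WaveformRecord("P0", 100, np.full(1500, 80.0))
    with pytest.raises(ValueError, match="shorter"):
        predict_over_record(rec, {"cnn": _StubModel(), "rnn": _StubModel()}, 0.5)


def test_predict_over_record_marks_artifact_windows_missing(clean_record):
    _, record, _ = clean_record
    pressure = record.pressure[:20000].copy()
    pressure[5000:5100] = np.nan  # missing gap inside the third window
    rec = WaveformRecord("P0", 100, pressure)
    trace = predict_over_record(rec, {"cnn": _StubModel(), "rnn": _StubModel()}, 0.65)
    assert len(trace) == 10  # non-overlapping 20-s windows over 200 s
    bad = trace[np.isnan(trace["p_ensemble"])]
    good = trace[~np.isnan(trace["p_ensemble"])]
    assert list(bad["time_s"]) == [60.0]  # only the window covering the gap
    assert len(good) == 9
    assert np.allclose(
        good["p_ensemble"], 0.65 * good["p_rnn"] + 0.35 * good["p_cnn"]
    )
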