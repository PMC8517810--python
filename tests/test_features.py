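import numpy as np
import pandas as pd
import pytest

from stepop.beats import BeatSequence, detect_beats
from stepop.features import (
    FEATURE_NAMES,
    apply_scaler,
    extract_features,
    fit_robust_scaler,
)
from stepop.synthetic import SimConfig, simulate_record


def _two_beat_segment(sys1, dia1, sys2, dia2):
    """Triangular beats with exact known systolic/diastolic pressures.

    Each beat spans 101 samples (1.0 s at 100 Hz) from its own foot back to
    its own foot; boundaries are disjoint so the inclusive end sample of one
    cycle never reads into the next beat.
    """
    def beat(sys, dia):
        up = np.linspace(dia, sys, 25, endpoint=False)
        down = np.linspace(sys, dia, 76)
        return np.concatenate([up, down])  # 101 samples, min=dia, max=sys

    seg = np.concatenate([beat(sys1, dia1), beat(sys2, dia2)])
    beats = BeatSequence(boundaries=[(0, 100), (101, 201)], beats_normalized=[])
    return seg, beats


def test_equal_pulse_pressures_give_zero_ppv():
    seg, beats = _two_beat_segment(120, 80, 110, 70)
    fv = extract_features(seg, beats)
    assert fv.pp_max == pytest.approx(40.0)
    assert fv.pp_min == pytest.approx(40.0)
    assert fv.ppv == pytest.approx(0.0)
    assert fv.pp_range == pytest.approx(0.0)


def test_ppv_formula_on_60_40_fixture():
    seg, beats = _two_beat_segment(130, 70, 110, 70)  # PP 60 and 40
    fv = extract_features(seg, beats)
    assert fv.ppv == pytest.approx((60 - 40) * 2.0 / (60 + 40))
    assert fv.ppv == pytest.approx(0.4)


def test_rectangular_beat_area_and_map():
    # constant 100 mmHg over exactly 1.0 s per beat
    seg = np.full(201, 100.0)
    beats = BeatSequence(boundaries=[(0, 100), (100, 200)], beats_normalized=[])
    fv = extract_features(seg, beats)
    assert fv.beat_area_avg == pytest.approx(100.0)
    assert fv.map_avg == pytest.approx(100.0)
    assert fv.mean_beat_length == pytest.approx(1.0)


def test_requires_two_beats():
    seg = np.full(201, 100.0)
    with pytest.raises(ValueError):
        extract_features(seg, BeatSequence(boundaries=[(0, 100)], beats_normalized=[]))


def brute_force_features(segment, boundaries, fs=100):
    per = []
    for s, e in boundaries:
        cyc = [float(v) for v in segment[s : e + 1]]
        sys_p, dia_p = max(cyc), min(cyc)
        area = sum((a + b) / 2 for a, b in zip(cyc, cyc[1:])) / fs
        per.append(
            dict(
                length=(e - s) / fs,
                sys=sys_p,
                dia=dia_p,
                pp=sys_p - dia_p,
                st=cyc.index(sys_p) / fs,
                area=area,
                map=area / ((e - s) / fs),
            )
        )
    pps = [b["pp"] for b in per]
    mean = lambda xs: sum(xs) / len(xs)
    return {
        "mean_beat_length": mean([b["length"] for b in per]),
        "map_avg": mean([b["map"] for b in per]),
        "pp_max": max(pps),
        "pp_min": min(pps),
        "pp_range": max(pps) - min(pps),
        "pp_avg": mean(pps),
        "ppv": (max(pps) - min(pps)) * 2.0 / (max(pps) + min(pps)),
        "systolic_time_avg": mean([b["st"] for b in per]),
        "systolic_pressure_avg": mean([b["sys"] for b in per]),
        "systolic_pressure_range": max(b["sys"] for b in per) - min(b["sys"] for b in per),
        "diastolic_pressure_avg": mean([b["dia"] for b in per]),
        "beat_area_avg": mean([b["area"] for b in per]),
    }


def test_features_match_brute_force_on_simulated_segments():
    cfg = SimConfig(n_patients=1, duration_s=600.0, event_schedule=(), seed=6)
    record, _ = simulate_record(cfg, 0)
    for start in range(2000, 40000, 2000):
        seg = record.pressure[start : start + 2000]
        beats = detect_beats(seg)
        fv = extract_features(seg, beats)
        oracle = brute_force_features(seg, beats.boundaries)
        for name in FEATURE_NAMES:
            assert getattr(fv, name) == pytest.approx(oracle[name], abs=1e-9), name


def test_ppv_invariant_under_pressure_scaling():
    seg, beats = _two_beat_segment(130, 70, 110, 70)
    fv1 = extract_features(seg, beats)
    fv2 = extract_features(seg * 1.3, beats)
    assert fv1.ppv == pytest.approx(fv2.ppv)


def test_quartiles_use_linear_interpolation_convention():
    scaler = fit_robust_scaler(np.tile(np.array([[1.0], [2.0], [3.0], [4.0], [5.0]]), (1, 12)))
    assert scaler.q1[0] == pytest.approx(2.0)
    assert scaler.q2[0] == pytest.approx(3.0)
    assert scaler.q3[0] == pytest.approx(4.0)


def test_scaled_median_is_zero_and_q3_maps_correctly():
    rng = np.random.default_rng(0)
    X = rng.normal(50, 10, (101, 12))
    scaler = fit_robust_scaler(X)
    med = apply_scaler(scaler, scaler.q2[None, :])
    assert np.allclose(med, 0.0, atol=1e-12)
    q3 = apply_scaler(scaler, scaler.q3[None, :])
    assert np.allclose(q3, (scaler.q3 - scaler.q2) / (scaler.q3 - scaler.q1))
    med_train = np.median(apply_scaler(scaler, X), axis=0)
    assert np.allclose(med_train, 0.0, atol=1e-12)


def test_translation_invariance_of_scaling():
    rng = np.random.default_rng(1)
    X = rng.normal(0, 1, (50, 12))
    s1 = fit_robust_scaler(X)
    s2 = fit_robust_scaler(X + 7.5)
    assert np.allclose(apply_scaler(s1, X), apply_scaler(s2, X + 7.5), atol=1e-12)


def test_degenerate_feature_scales_to_zero():
    X = np.random.default_rng(2).normal(size=(20, 12))
    X[:, 3] = 42.0
    scaler = fit_robust_scaler(X)
    assert scaler.degenerate[3]
    out = apply_scaler(scaler, X)
    assert np.all(out[:, 3] == 0.0)


def test_apply_scaler_checks_feature_names():
    X = np.random.default_rng(0).normal(size=(10, 12))
    scaler = fit_robust_scaler(X)
    df = pd.DataFrame(X[:, :11], columns=list(FEATURE_NAMES[:11]))
    with pytest.raises(ValueError, match="missing"):
        apply_scaler(scaler, df)


def test_class_conditional_feature_ordering_on_cohort():
    """Hypotension-bound segments show lower MAP, shorter beats, higher PPV."""
    cfg = SimConfig(n_patients=6, duration_s=1500.0, artifact_rate=0.0, seed=13)
    from stepop.labeling import extract_segment_pairs

    rows = []
    for idx in range(cfg.n_patients):
        record, _ = simulate_record(cfg, idx)
        pairs, _ = extract_segment_pairs(record)
        for p in pairs:
            if not p.usable:
                continue
            seg = record.pressure[p.input_start_index : p.input_start_index + 2000]
            try:
                fv = extract_features(seg, detect_beats(seg))
            except ValueError:
                continue
            rows.append((p.label, fv))
    pos = [fv for lab, fv in rows if lab == "positive"]
    neg = [fv for lab, fv in rows if lab == "negative"]
    assert len(pos) >= 10 and len(neg) >= 10
    mean = lambda vs, n: float(np.mean([getattr(v, n) for v in vs]))
    assert mean(pos, "map_avg") < mean(neg, "map_avg")
    assert mean(pos, "mean_beat_length") < mean(neg, "mean_beat_length")
    assert mean(pos, "ppv") > mean(neg, "ppv")
    assert mean(pos, "diastolic_pressure_avg") < mean(neg, "diastolic_pressure_avg")
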