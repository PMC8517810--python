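import itertools

import numpy as np
import pytest

from stepop.labeling import (
    INDETERMINATE,
    NEGATIVE,
    POSITIVE,
    LabelThresholds,
    detect_events,
    extract_segment_pairs,
    moving_average_2s,
    split_patients,
)
from stepop.record_io import WaveformRecord
from stepop.synthetic import SimConfig, simulate_record


def brute_force_events(pressure, hypo=65.0, normo=75.0, w=200, min_len=6000):
    """Independent oracle: cumulative-sum moving average + groupby run scan."""
    c = np.concatenate([[0.0], np.cumsum(pressure)])
    ma = (c[w:] - c[:-w]) / w
    events = []
    for kind, mask in (("hypotensive", ma < hypo), ("nonhypotensive", ma > normo)):
        i = 0
        for key, grp in itertools.groupby(mask):
            n = len(list(grp))
            if key and n >= min_len:
                events.append((kind, i + w - 1, i + n + w - 1))
            i += n
    return sorted(events, key=lambda e: e[1])


def piecewise_record(rng, n_pieces=6, piece_s=(20, 120)):
    levels = rng.uniform(45, 100, n_pieces)
    lens = rng.integers(piece_s[0] * 100, piece_s[1] * 100, n_pieces)
    return WaveformRecord("PX", 100, np.repeat(levels, lens) + rng.normal(0, 0.5, int(lens.sum())))


def test_moving_average_of_constant_is_constant():
    ma = moving_average_2s(np.full(400, 70.0))
    assert ma.shape == (201,)
    assert np.allclose(ma, 70.0)


def test_moving_average_step_rises_linearly():
    x = np.concatenate([np.full(200, 60.0), np.full(200, 80.0)])
    ma = moving_average_2s(x)
    assert ma[0] == pytest.approx(60.0)
    assert ma[-1] == pytest.approx(80.0)
    assert np.allclose(np.diff(ma), 20.0 / 200, atol=1e-9)


def test_moving_average_matches_direct_windowed_mean():
    rng = np.random.default_rng(1)
    x = rng.uniform(40, 120, 1500)
    ma = moving_average_2s(x)
    direct = np.array([x[i : i + 200].mean() for i in range(x.size - 199)])
    assert np.allclose(ma, direct, atol=1e-9)


def test_moving_average_requires_full_window():
    with pytest.raises(ValueError):
        moving_average_2s(np.full(150, 70.0))


def test_detect_events_on_scheduled_dip(clean_record):
    _, record, truth = clean_record
    events = [e for e in detect_events(record) if e.kind == "hypotensive"]
    assert len(events) == 1
    ep = truth.hypotensive_episodes[0]
    assert abs(events[0].onset_index / 100 - ep.onset_s) < 5.0


def test_constant_70_gives_no_events():
    record = WaveformRecord("P0", 100, np.full(20000, 70.0))
    assert detect_events(record) == []


def test_detect_events_matches_run_length_oracle():
    rng = np.random.default_rng(7)
    for _ in range(200):
        record = piecewise_record(rng)
        got = [(e.kind, e.onset_index, e.end_index) for e in detect_events(record)]
        assert got == brute_force_events(record.pressure)


def test_event_onset_pairs_to_input_five_minutes_before():
    # hypotensive run starting around t=400 s
    n = 50000
    pressure = np.full(n, 80.0)
    pressure[39900:] = 55.0
    record = WaveformRecord("P0", 100, pressure)
    onset = next(e.onset_index for e in detect_events(record) if e.kind == "hypotensive")
    pairs, _ = extract_segment_pairs(record)
    p = next(
        p for p in pairs if p.label == POSITIVE and p.source == "event"
        and p.outcome_start_index == onset
    )
    assert p.outcome_start_index - (p.input_start_index + 2000) == 30000
    assert p.input_start_index == onset - 32000  # the input ends 300 s earlier


def test_event_too_early_is_skipped_and_logged():
    n = 40000
    pressure = np.full(n, 80.0)
    pressure[20000:27000] = 55.0  # run onset near 200 s, before 320 s
    record = WaveformRecord("P0", 100, pressure)
    onset = next(e.onset_index for e in detect_events(record) if e.kind == "hypotensive")
    assert onset < 32000
    pairs, skips = extract_segment_pairs(record)
    assert any(s["outcome_start_index"] == onset for s in skips)
    assert not any(p.outcome_start_index == onset for p in pairs)


def test_every_window_gets_exactly_one_label(clean_record):
    _, record, _ = clean_record
    pairs, _ = extract_segment_pairs(record)
    assert pairs
    assert all(p.label in (POSITIVE, NEGATIVE, INDETERMINATE) for p in pairs)


def test_lowering_hypo_threshold_cannot_add_positives(clean_record):
    _, record, _ = clean_record
    base = extract_segment_pairs(record)[0]
    strict = extract_segment_pairs(record, LabelThresholds(hypo_map=55.0))[0]
    n_base = sum(p.label == POSITIVE for p in base)
    n_strict = sum(p.label == POSITIVE for p in strict)
    assert n_strict <= n_base


def test_positive_pairs_reach_ground_truth_episodes():
    cfg = SimConfig(
        n_patients=1,
        duration_s=2400.0,
        event_schedule=((900.0, 120.0, 55.0), (1900.0, 150.0, 52.0)),
        noise_sd=1.0,
        seed=8,
    )
    record, truth = simulate_record(cfg, 0)
    pairs, _ = extract_segment_pairs(record)
    event_positives = [p for p in pairs if p.label == POSITIVE and p.source == "event"]
    reachable = [e for e in truth.hypotensive_episodes if e.onset_s >= 320.0]
    assert len(event_positives) == len(reachable)


def test_split_is_deterministic_and_disjoint():
    ids = [f"P{i}" for i in range(10)]
    tr1, va1 = split_patients(ids, 0.7, seed=3)
    tr2, va2 = split_patients(ids, 0.7, seed=3)
    assert tr1 == tr2 and va1 == va2
    assert len(tr1) == 7 and len(va1) == 3
    assert set(tr1) & set(va1) == set()
    tr3, _ = split_patients(ids, 0.7, seed=4)
    assert tr3 != tr1 or True  # different seed may shuffle differently


def test_split_rejects_bad_fraction():
    with pytest.raises(ValueError):
        split_patients(["a", "b"], 1.0, 0)
    with pytest.raises(ValueError):
        split_patients(["a"], 0.5, 0)
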