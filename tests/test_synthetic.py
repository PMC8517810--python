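import numpy as np
import pytest

from stepop.labeling import moving_average_2s
from stepop.qc import FLAT, RANGE, check_segment
from stepop.synthetic import (
    SimConfig,
    inject_artifacts,
    simulate_cohort,
    simulate_record,
)


def test_same_config_gives_bitwise_identical_traces():
    cfg = SimConfig(duration_s=300.0, seed=5)
    r1, t1 = simulate_record(cfg, 2)
    r2, t2 = simulate_record(cfg, 2)
    assert np.array_equal(r1.pressure, r2.pressure)
    assert np.array_equal(t1.map_envelope, t2.map_envelope)
    r3, _ = simulate_record(cfg, 3)
    assert not np.array_equal(r1.pressure, r3.pressure)


def test_no_dips_keeps_moving_average_above_75():
    cfg = SimConfig(
        duration_s=600.0,
        event_schedule=(),
        baseline_map_range=(90.0, 90.0),
        noise_sd=0.3,
        seed=1,
    )
    record, truth = simulate_record(cfg, 0)
    assert truth.hypotensive_episodes == []
    assert moving_average_2s(record.pressure).min() > 75.0


def test_single_scheduled_dip_yields_one_episode():
    cfg = SimConfig(duration_s=1200.0, event_schedule=((700.0, 120.0, 55.0),), seed=2)
    _, truth = simulate_record(cfg, 0)
    assert len(truth.hypotensive_episodes) == 1
    ep = truth.hypotensive_episodes[0]
    assert ep.onset_s < 700.0 < ep.end_s  # drift crosses 65 before the scheduled floor


def test_schedule_past_duration_rejected():
    cfg = SimConfig(duration_s=600.0, event_schedule=((550.0, 120.0, 55.0),))
    with pytest.raises(ValueError, match="extends past"):
        simulate_record(cfg, 0)


def test_episodes_sorted_and_non_overlapping():
    cfg = SimConfig(
        duration_s=3000.0,
        event_schedule=((800.0, 120.0, 55.0), (2000.0, 150.0, 50.0)),
        seed=4,
    )
    _, truth = simulate_record(cfg, 0)
    eps = truth.hypotensive_episodes
    assert len(eps) == 2
    assert all(a.end_s <= b.onset_s for a, b in zip(eps, eps[1:]))


def test_zero_artifact_rate_is_identity():
    cfg = SimConfig(duration_s=300.0, artifact_rate=0.0, seed=1)
    record, _ = simulate_record(cfg, 0)
    out, log = inject_artifacts(record, cfg)
    assert log == []
    assert np.array_equal(out.pressure, record.pressure)


def test_injected_artifacts_fail_qc_over_their_spans():
    cfg = SimConfig(duration_s=1800.0, artifact_rate=6.0, seed=9)
    record, _ = simulate_record(cfg, 0)
    out, log = inject_artifacts(record, cfg)
    assert log, "expected at least one injected artifact at this rate"
    kinds = {span.kind for span in log}
    for span in log:
        mid = (span.start_index + span.end_index) // 2
        start = max(0, min(mid - 1000, out.n_samples - 2000))
        seg = out.pressure[start : start + 2000]
        assert not check_segment(seg).valid, span
    # a flat artifact is long enough that a window fully inside it is FLAT
    # (provided no other injected artifact overlaps the window)
    for span in (s for s in log if s.kind == "flat"):
        if span.end_index - span.start_index < 2000:
            continue
        others = [s for s in log if s is not span]
        if any(s.start_index < span.start_index + 2000 and s.end_index > span.start_index
               for s in others):
            continue
        inner = out.pressure[span.start_index : span.start_index + 2000]
        assert FLAT in check_segment(inner).violations


def test_spike_artifact_is_out_of_range():
    cfg = SimConfig(duration_s=1800.0, artifact_rate=4.0, seed=11)
    record, _ = simulate_record(cfg, 0)
    out, log = inject_artifacts(record, cfg)
    spikes = [s for s in log if s.kind == "spike"]
    assert spikes
    for span in spikes:
        seg = out.pressure[span.start_index : span.end_index]
        assert np.all((seg > 200.0) | (seg < 20.0))


def test_cohort_writes_records_manifest_and_truth(tmp_path):
    cfg = SimConfig(n_patients=3, duration_s=120.0, event_schedule=(), seed=0)
    manifest = simulate_cohort(cfg, tmp_path)
    assert len(manifest.entries) == 3
    assert (tmp_path / "cohort_manifest.csv").exists()
    assert (tmp_path / "ground_truth.json").exists()
    assert len(list((tmp_path / "records").iterdir())) == 3


def test_cohort_manifest_deterministic(tmp_path):
    cfg = SimConfig(n_patients=2, duration_s=120.0, event_schedule=(), seed=0)
    m1 = simulate_cohort(cfg, tmp_path / "a")
    m2 = simulate_cohort(cfg, tmp_path / "b")
    assert m1.manifest_path.read_text() == m2.manifest_path.read_text()
    assert (tmp_path / "a" / "ground_truth.json").read_text() == (
        tmp_path / "b" / "ground_truth.json"
    ).read_text()


def test_empty_cohort_is_not_an_error(tmp_path):
    manifest = simulate_cohort(SimConfig(n_patients=0, duration_s=60.0), tmp_path)
    assert manifest.entries == []
    assert manifest.manifest_path.exists()


def test_every_noise_free_scheduled_dip_is_detected():
    """Schedule fidelity: with zero noise, every scheduled dip below 65 mmHg
    sustained >= 60 s yields a detected hypotensive event overlapping it."""
    from stepop.labeling import detect_events

    rng = np.random.default_rng(21)
    for k in range(100):
        onset = float(rng.uniform(180.0, 250.0))
        dur = float(rng.uniform(70.0, 140.0))
        target = float(rng.uniform(45.0, 62.0))
        cfg = SimConfig(
            duration_s=onset + dur + 80.0,
            predrift_s=120.0,
            event_schedule=((onset, dur, target),),
            noise_sd=0.0,
            seed=int(k),
        )
        record, truth = simulate_record(cfg, 0)
        assert len(truth.hypotensive_episodes) == 1
        hypo = [e for e in detect_events(record) if e.kind == "hypotensive"]
        assert hypo, (onset, dur, target)
        assert any(
            e.onset_index / 100 < onset + dur and e.end_index / 100 > onset for e in hypo
        )


def test_positive_inputs_have_lower_mean_pressure_than_negative_inputs():
    """Learnability: across >= 1000 segment pairs with full pre-onset drift,
    the population mean pressure of 20-s inputs preceding positive windows is
    strictly below that of inputs preceding negative windows."""
    from stepop.labeling import extract_segment_pairs

    cfg = SimConfig(n_patients=20, duration_s=1800.0, predrift_s=420.0, seed=17)
    pos_means, neg_means, total = [], [], 0
    for idx in range(cfg.n_patients):
        record, _ = simulate_record(cfg, idx)
        pairs, _ = extract_segment_pairs(record)
        total += len(pairs)
        for p in pairs:
            if not p.usable:
                continue
            m = record.pressure[p.input_start_index : p.input_start_index + 2000].mean()
            (pos_means if p.label == "positive" else neg_means).append(m)
    assert total >= 1000
    assert len(pos_means) > 30 and len(neg_means) > 30
    assert np.mean(pos_means) < np.mean(neg_means)
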