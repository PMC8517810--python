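"""Synthetic arterial-pressure cohort generator.

Produces pulsatile ABP records with a known mean-arterial-pressure (MAP)
envelope, scheduled hypotensive dips with gradual pre-onset drift, and
injectable artifacts matching each downstream exclusion criterion. The
generator is deliberately simple and fully controllable rather than a
validated hemodynamic model: every beat is a fixed two-bump template
(systolic peak plus dicrotic wave) stretched foot-to-foot and scaled between
diastolic and systolic envelopes derived from the MAP trajectory and pulse
pressure.

Physiologic couplings are built in so class-conditional feature statistics
behave like real hypotension: as the MAP envelope falls below baseline, heart
rate rises (shorter beats), mean pulse pressure falls and beat-to-beat pulse
pressure variability grows. The pre-onset drift is a linear MAP decline over
``predrift_s`` seconds, which guarantees learnable signal at the 5-minute
prediction horizon.

Everything is deterministic given ``(seed, patient_index)``.
"""

from __future__ import annotations

import csv
import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import record_io
from .record_io import WaveformRecord

RECOVERY_S = 60.0  # linear MAP recovery time after a dip

ARTIFACT_KINDS = ("gap", "spike", "flat", "step")


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings.

    ``event_schedule`` is a list of ``(onset_s, duration_s, target_map)``
    hypotensive dips applied to every patient; ``None`` draws 0-2 dips per
    patient at random. ``artifact_rate`` is the expected number of artifacts
    per hour for each artifact class.
    """

    n_patients: int = 50
    duration_s: float = 1800.0
    sampling_rate: int = 100
    hr_range: tuple[float, float] = (60.0, 110.0)
    baseline_map_range: tuple[float, float] = (85.0, 100.0)
    pulse_pressure_range: tuple[float, float] = (35.0, 55.0)
    event_schedule: tuple[tuple[float, float, float], ...] | None = None
    predrift_s: float = 420.0
    pre_dip_map: float = 68.0
    plummet_s: float = 30.0
    artifact_rate: float = 0.0
    noise_sd: float = 1.0
    map_wander_mmhg: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sampling_rate not in (100, 500):
            raise ValueError("sampling_rate must be 100 or 500")
        lo, hi = self.hr_range
        if not (20.0 < lo <= hi < 240.0):
            raise ValueError("hr_range must lie within (20, 240)")
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")


@dataclass
class Episode:
    onset_s: float
    end_s: float


@dataclass
class GroundTruth:
    """Per-record truth the simulator knows exactly.

    ``map_envelope`` is the noise-free per-sample MAP at 100 Hz;
    ``beat_feet_s`` are the foot (cycle-onset) times of every generated beat.
    """

    patient_id: str
    hypotensive_episodes: list[Episode]
    normotensive_stretches: list[Episode]
    map_envelope: np.ndarray
    beat_feet_s: np.ndarray
    beat_maps: np.ndarray

    def to_jsonable(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "hypotensive_episodes": [[e.onset_s, e.end_s] for e in self.hypotensive_episodes],
            "normotensive_stretches": [[e.onset_s, e.end_s] for e in self.normotensive_stretches],
            "beat_feet_s": np.round(self.beat_feet_s, 6).tolist(),
            "beat_maps": np.round(self.beat_maps, 6).tolist(),
        }


@dataclass
class ArtifactSpan:
    kind: str
    start_index: int
    end_index: int  # half-open


def _beat_shape_unnormalized(phases: np.ndarray) -> np.ndarray:
    raw = np.exp(-0.5 * ((phases - 0.25) / 0.09) ** 2)
    raw = raw + 0.32 * np.exp(-0.5 * ((phases - 0.55) / 0.14) ** 2)
    r0 = np.exp(-0.5 * (0.25 / 0.09) ** 2) + 0.32 * np.exp(-0.5 * (0.55 / 0.14) ** 2)
    r1 = np.exp(-0.5 * (0.75 / 0.09) ** 2) + 0.32 * np.exp(-0.5 * (0.45 / 0.14) ** 2)
    chord = (1.0 - phases) * r0 + phases * r1
    return raw - chord


# peak of the shape over a full cycle; partial beats at a record's end must
# still be normalized by the full-cycle peak
_SHAPE_PEAK = float(_beat_shape_unnormalized(np.linspace(0.0, 1.0, 2001)).max())


def _beat_template(phases: np.ndarray) -> np.ndarray:
    """Normalized beat shape on phase in [0, 1): 0 at both feet, peak 1.

    Sum of a systolic bump and a smaller, later dicrotic bump; the linear
    chord between the endpoint values is subtracted so both feet sit exactly
    at zero, then the curve is scaled to unit full-cycle peak.
    """
    return _beat_shape_unnormalized(phases) / _SHAPE_PEAK


def _patient_rng(seed: int, patient_index: int, tag: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, patient_index, tag)))


def _map_envelope(config: SimConfig, schedule, baseline: float, rng) -> np.ndarray:
    fs = config.sampling_rate
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs
    # slow physiologic wander: two incommensurate slow sinusoids
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    env = baseline + config.map_wander_mmhg * (
        0.7 * np.sin(2 * np.pi * t / 613.0 + ph1) + 0.3 * np.sin(2 * np.pi * t / 151.0 + ph2)
    )
    for onset, dur, target in schedule:
        # Hypotension develops in two phases, mirroring how intraoperative
        # events typically look on the monitor: a gradual decline from
        # baseline toward a prodromal level just above the hypotensive
        # threshold over the pre-onset drift, then an abrupt plummet to the
        # dip floor at the event onset. The plummet keeps the detected
        # moving-average crossing close to the scheduled onset.
        pre_dip = min(max(config.pre_dip_map, target), baseline)
        plummet = min(config.plummet_s, config.predrift_s)
        drift_start = max(0.0, onset - config.predrift_s)
        plummet_start = max(drift_start, onset - plummet)
        blend = np.zeros(n)  # fraction of (baseline -> target) applied
        pre_frac = (baseline - pre_dip) / max(baseline - target, 1e-9)
        ramp = (t >= drift_start) & (t < plummet_start)
        if plummet_start > drift_start:
            blend[ramp] = pre_frac * (t[ramp] - drift_start) / (plummet_start - drift_start)
        fall = (t >= plummet_start) & (t < onset)
        if onset > plummet_start:
            blend[fall] = pre_frac + (1.0 - pre_frac) * (t[fall] - plummet_start) / (
                onset - plummet_start
            )
        hold = (t >= onset) & (t < onset + dur)
        blend[hold] = 1.0
        rec = (t >= onset + dur) & (t < onset + dur + RECOVERY_S)
        blend[rec] = 1.0 - (t[rec] - (onset + dur)) / RECOVERY_S
        dipped = env + blend * (target - env)
        env = np.minimum(env, dipped)
    return env


def _auto_schedule(config: SimConfig, rng) -> list[tuple[float, float, float]]:
    """Draw 0-2 hypotensive dips that fit within the record with full drift.

    Episodes are sustained (4-10 min) and arrive in clusters of 1-3 dips with
    only brief partial recoveries in between: intraoperative hypotension
    tends to persist and recur, so a sizable share of positive outcome
    windows is preceded by already-low pressure five minutes earlier,
    alongside onset-anchored windows whose inputs lie in the gradual
    pre-onset drift. Full recovery to baseline happens once per cluster.
    """
    earliest = config.predrift_s + 60.0
    latest = config.duration_s - 360.0
    if latest <= earliest:
        return []
    n_clusters = int(rng.integers(0, 3))
    schedule: list[tuple[float, float, float]] = []
    last_end = 0.0
    for _ in range(n_clusters):
        onset = float(rng.uniform(earliest, latest))
        if onset - config.predrift_s < last_end:
            continue
        n_sub = 1 + int(rng.integers(0, 3))
        for _ in range(n_sub):
            dur = min(float(rng.uniform(240.0, 600.0)), config.duration_s - 60.0 - onset)
            if dur < 90.0:
                break
            target = float(rng.uniform(48.0, 60.0))
            schedule.append((onset, dur, target))
            last_end = onset + dur + RECOVERY_S
            onset = onset + dur + float(rng.uniform(45.0, 90.0))
            if onset > config.duration_s - 180.0:
                break
    return sorted(schedule)


def _episodes_from_envelope(env: np.ndarray, fs: int) -> tuple[list[Episode], list[Episode]]:
    def runs(mask: np.ndarray, min_len: int) -> list[Episode]:
        out: list[Episode] = []
        i = 0
        n = mask.size
        while i < n:
            if mask[i]:
                j = i
                while j < n and mask[j]:
                    j += 1
                if j - i >= min_len:
                    out.append(Episode(i / fs, j / fs))
                i = j
            else:
                i += 1
        return out

    min_len = 60 * fs
    return runs(env < 65.0, min_len), runs(env > 75.0, min_len)


def simulate_record(config: SimConfig, patient_index: int) -> tuple[WaveformRecord, GroundTruth]:
    """Generate one patient's record and its ground truth.

    Deterministic given ``(config.seed, patient_index)``. Raises if the event
    schedule extends past ``duration_s``.
    """
    if config.event_schedule is not None:
        for onset, dur, target in config.event_schedule:
            if onset < 0 or onset + dur > config.duration_s:
                raise ValueError(
                    f"event schedule entry (onset={onset}, duration={dur}) "
                    f"extends past record duration {config.duration_s} s"
                )
    rng = _patient_rng(config.seed, patient_index)
    schedule = (
        list(config.event_schedule)
        if config.event_schedule is not None
        else _auto_schedule(config, rng)
    )
    baseline = float(rng.uniform(*config.baseline_map_range))
    env = _map_envelope(config, schedule, baseline, rng)
    fs = config.sampling_rate
    n = env.size

    hr_base = float(rng.uniform(*config.hr_range))
    pp_base = float(rng.uniform(*config.pulse_pressure_range))

    pressure = np.empty(n)
    feet_s: list[float] = []
    beat_maps: list[float] = []
    pos = 0
    hr_jit = 0.0
    pp_jit = 0.0
    while pos < n:
        deficit = max(0.0, (baseline - env[pos]) / baseline)
        hr_jit = 0.9 * hr_jit + float(rng.normal(0.0, 1.0))
        hr = np.clip(hr_base * (1.0 + 0.35 * deficit) + hr_jit, 25.0, 220.0)
        period = 60.0 / hr
        nb = max(int(round(period * fs)), 10)
        pp_sd = 0.04 * (1.0 + 2.5 * deficit)
        pp_jit = 0.85 * pp_jit + float(rng.normal(0.0, pp_sd))
        pp = max(pp_base * (1.0 - 0.25 * deficit) * (1.0 + pp_jit), 25.0)

        end = min(pos + nb, n)
        phases = (np.arange(pos, end) - pos) / nb
        shape = _beat_template(phases)
        seg_env = env[pos:end]
        beat_map = float(seg_env.mean())
        # anchor so the discrete beat mean equals the local MAP exactly
        full_shape = _beat_template(np.arange(nb) / nb)
        dbp = beat_map - pp * float(full_shape.mean())
        pressure[pos:end] = dbp + pp * shape
        feet_s.append(pos / fs)
        beat_maps.append(beat_map)
        pos = end

    if config.noise_sd > 0:
        pressure = pressure + rng.normal(0.0, config.noise_sd, size=n)

    record = WaveformRecord(
        patient_id=f"P{patient_index:04d}",
        sampling_rate=fs,
        pressure=pressure,
    )
    env_100 = env[:: fs // 100]
    hypo, normo = _episodes_from_envelope(env_100, 100)
    truth = GroundTruth(
        patient_id=record.patient_id,
        hypotensive_episodes=hypo,
        normotensive_stretches=normo,
        map_envelope=env_100,
        beat_feet_s=np.asarray(feet_s),
        beat_maps=np.asarray(beat_maps),
    )
    return record, truth


def inject_artifacts(
    record: WaveformRecord, config: SimConfig
) -> tuple[WaveformRecord, list[ArtifactSpan]]:
    """Insert one of each artifact class at Poisson-rate positions.

    Artifact classes mirror the exclusion criteria: missing-value gaps,
    out-of-range spikes/troughs, flat stretches with range under 20 mmHg
    lasting over 20 s, and step discontinuities over 30 mmHg between adjacent
    samples. Returns the modified record and the log of injected spans.
    """
    if record.sampling_rate != 100:
        raise ValueError("inject_artifacts expects a 100 Hz record")
    if config.artifact_rate <= 0:
        return record, []
    fs = 100
    n = record.n_samples
    tag = zlib.crc32(record.patient_id.encode()) & 0x7FFFFFFF
    rng = _patient_rng(config.seed, tag, tag=1)
    hours = n / fs / 3600.0
    pressure = record.pressure.copy()
    log: list[ArtifactSpan] = []

    for kind in ARTIFACT_KINDS:
        count = int(rng.poisson(config.artifact_rate * hours))
        for _ in range(count):
            if kind == "gap":
                length = int(rng.uniform(0.5, 3.0) * fs)
                start = int(rng.integers(0, max(1, n - length)))
                pressure[start : start + length] = np.nan
                log.append(ArtifactSpan("gap", start, start + length))
            elif kind == "spike":
                length = int(rng.integers(1, 4))
                start = int(rng.integers(0, max(1, n - length)))
                value = float(rng.uniform(205.0, 240.0)) if rng.random() < 0.5 else float(
                    rng.uniform(5.0, 15.0)
                )
                pressure[start : start + length] = value
                log.append(ArtifactSpan("spike", start, start + length))
            elif kind == "flat":
                length = int(rng.uniform(22.0, 30.0) * fs)
                start = int(rng.integers(0, max(1, n - length)))
                level = float(np.clip(np.nanmean(pressure[start : start + length]), 40.0, 150.0))
                pressure[start : start + length] = level
                log.append(ArtifactSpan("flat", start, start + length))
            else:  # step
                length = int(rng.uniform(1.0, 5.0) * fs)
                start = int(rng.integers(0, max(1, n - length)))
                offset = float(rng.uniform(35.0, 60.0)) * (1.0 if rng.random() < 0.5 else -1.0)
                span = pressure[start : start + length]
                pressure[start : start + length] = np.clip(span + offset, 0.0, 250.0)
                log.append(ArtifactSpan("step", start, start + length))
    log.sort(key=lambda s: s.start_index)
    return replace(record, pressure=pressure), log


@dataclass
class CohortManifest:
    root: Path
    entries: list[dict]

    @property
    def manifest_path(self) -> Path:
        return self.root / "cohort_manifest.csv"


def simulate_cohort(
    config: SimConfig, out_dir: str | Path, record_format: str = "bin"
) -> CohortManifest:
    """Simulate, artifact-inject and write ``n_patients`` records.

    Writes one record file per patient, a ground-truth JSON, an artifact-span
    CSV and a delimited cohort manifest. Deterministic given the config.
    """
    root = Path(out_dir)
    records_dir = root / "records"
    records_dir.mkdir(parents=True, exist_ok=True)
    ext = "abp" if record_format == "bin" else "csv"

    entries: list[dict] = []
    truths: dict[str, dict] = {}
    artifact_rows: list[tuple] = []
    for idx in range(config.n_patients):
        record, truth = simulate_record(config, idx)
        record = record_io.resample_to_100hz(record)
        record, art_log = inject_artifacts(record, config)
        path = records_dir / f"{record.patient_id}.{ext}"
        record_io.write_record(record, path, format=record_format)
        truths[record.patient_id] = truth.to_jsonable()
        for span in art_log:
            artifact_rows.append((record.patient_id, span.kind, span.start_index, span.end_index))
        entries.append(
            {
                "patient_id": record.patient_id,
                "path": str(path.relative_to(root)),
                "n_samples": record.n_samples,
                "n_events": len(truth.hypotensive_episodes),
            }
        )

    manifest = CohortManifest(root=root, entries=entries)
    with open(manifest.manifest_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "path", "n_samples", "n_events"])
        for e in entries:
            w.writerow([e["patient_id"], e["path"], e["n_samples"], e["n_events"]])
    with open(root / "ground_truth.json", "w") as fh:
        json.dump(truths, fh, sort_keys=True)
    with open(root / "artifact_log.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "kind", "start_index", "end_index"])
        w.writerows(artifact_rows)
    return manifest


def load_ground_truth(root: str | Path) -> dict[str, GroundTruth]:
    with open(Path(root) / "ground_truth.json") as fh:
        raw = json.load(fh)
    out: dict[str, GroundTruth] = {}
    for pid, d in raw.items():
        out[pid] = GroundTruth(
            patient_id=pid,
            hypotensive_episodes=[Episode(*e) for e in d["hypotensive_episodes"]],
            normotensive_stretches=[Episode(*e) for e in d["normotensive_stretches"]],
            map_envelope=np.array([]),
            beat_feet_s=np.asarray(d["beat_feet_s"]),
            beat_maps=np.asarray(d["beat_maps"]),
        )
    return out
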