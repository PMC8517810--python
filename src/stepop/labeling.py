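"""Hypotension event detection and input/outcome segment pairing.

Definitions (all on the canonical 100 Hz trace):

* 2-s moving average (MA): trailing mean of 200 samples; the MA value at
  record index ``t`` (``t >= 199``) averages samples ``t-199 .. t``.
* Hypotensive event: MA < 65 mmHg sustained for at least 60 s (6000
  consecutive MA samples). Nonhypotensive event: MA > 75 mmHg sustained for
  at least 60 s. Maximal qualifying runs are reported once.
* Each 60-s outcome window starting at index ``o`` is paired with the 20-s
  input segment ``[o - 320 s, o - 300 s)``: the input ends a full 5 minutes
  before the outcome starts, so a positive label is a true 5-minute warning.

Candidate outcome windows are enumerated on a configurable stride grid and
labeled positive if the MA stays under 65 for the entire 60 s (the window
begins a qualifying hypotensive run), negative if the MA stays over 75
throughout, and indeterminate otherwise. Event-onset-anchored windows are
added on top of the grid. Indeterminate and QC-failing pairs are kept in the
manifest but excluded from model data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .qc import QCResult, QCThresholds, check_segment
from .record_io import WaveformRecord

POSITIVE = "positive"
NEGATIVE = "negative"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class LabelThresholds:
    """Event definition constants; defaults are the study definitions."""

    hypo_map: float = 65.0
    normo_map: float = 75.0
    ma_window_s: float = 2.0
    event_min_duration_s: float = 60.0
    horizon_s: float = 300.0
    input_len_s: float = 20.0
    outcome_len_s: float = 60.0

    def __post_init__(self) -> None:
        if self.horizon_s <= 0:
            raise ValueError("horizon_s must be positive")


@dataclass(frozen=True)
class Event:
    kind: str  # "hypotensive" | "nonhypotensive"
    onset_index: int  # record index where the qualifying MA run starts
    end_index: int  # half-open record index where the run ends


@dataclass
class SegmentPair:
    patient_id: str
    input_start_index: int
    outcome_start_index: int
    label: str
    qc_input: QCResult
    qc_outcome: QCResult
    source: str = "grid"  # "grid" | "event"

    @property
    def usable(self) -> bool:
        return self.label in (POSITIVE, NEGATIVE) and self.qc_input.valid and self.qc_outcome.valid


def moving_average_2s(values: np.ndarray, fs: int = 100, window_s: float = 2.0) -> np.ndarray:
    """Trailing moving average; output ``j`` covers samples ``j .. j+w-1``.

    Output length is ``len(values) - w + 1``; the value at output index ``j``
    is the MA at record index ``j + w - 1``.
    """
    values = np.asarray(values, dtype=np.float64)
    w = int(round(window_s * fs))
    if values.size < w:
        raise ValueError(f"need at least {w} samples, got {values.size}")
    return np.lib.stride_tricks.sliding_window_view(values, w).mean(axis=1)


def _qualifying_runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal True-runs of length >= min_len, as half-open index pairs."""
    out = []
    n = mask.size
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_len:
                out.append((i, j))
            i = j
        else:
            i += 1
    return out


def detect_events(
    record: WaveformRecord, thresholds: LabelThresholds | None = None
) -> list[Event]:
    """Find maximal hypotensive and nonhypotensive MA runs of >= 60 s."""
    thresholds = thresholds or LabelThresholds()
    if record.sampling_rate != 100:
        raise ValueError("detect_events expects a 100 Hz record")
    fs = 100
    w = int(round(thresholds.ma_window_s * fs))
    min_len = int(round(thresholds.event_min_duration_s * fs))
    if record.n_samples < w:
        return []
    ma = moving_average_2s(record.pressure, fs, thresholds.ma_window_s)
    offset = w - 1
    with np.errstate(invalid="ignore"):
        lo = ma < thresholds.hypo_map
        hi = ma > thresholds.normo_map
    events = [
        Event("hypotensive", s + offset, e + offset) for s, e in _qualifying_runs(lo, min_len)
    ] + [
        Event("nonhypotensive", s + offset, e + offset) for s, e in _qualifying_runs(hi, min_len)
    ]
    events.sort(key=lambda ev: ev.onset_index)
    return events


def extract_segment_pairs(
    record: WaveformRecord,
    thresholds: LabelThresholds | None = None,
    qc_thresholds: QCThresholds | None = None,
    stride_s: float = 20.0,
) -> tuple[list[SegmentPair], list[dict]]:
    """Enumerate labeled (input, outcome) segment pairs for one record.

    Returns the pairs and a skip log for event-anchored windows whose input
    segment would start before the record does.
    """
    thresholds = thresholds or LabelThresholds()
    qc_thresholds = qc_thresholds or QCThresholds()
    if record.sampling_rate != 100:
        raise ValueError("extract_segment_pairs expects a 100 Hz record")
    fs = 100
    n = record.n_samples
    in_len = int(round(thresholds.input_len_s * fs))
    out_len = int(round(thresholds.outcome_len_s * fs))
    gap = int(round(thresholds.horizon_s * fs))
    w = int(round(thresholds.ma_window_s * fs))
    offset = w - 1
    min_outcome_start = in_len + gap

    events = detect_events(record, thresholds)
    if n < w:
        return [], []

    ma = moving_average_2s(record.pressure, fs, thresholds.ma_window_s)
    with np.errstate(invalid="ignore"):
        lo = (ma < thresholds.hypo_map).astype(np.int64)
        hi = (ma > thresholds.normo_map).astype(np.int64)
    clo = np.concatenate([[0], np.cumsum(lo)])
    chi = np.concatenate([[0], np.cumsum(hi)])

    def window_label(o: int) -> str:
        # MA indices (output coordinates) covering record indices [o, o+out_len)
        a, b = o - offset, o + out_len - offset
        if a < 0 or b > ma.size:
            return INDETERMINATE
        if clo[b] - clo[a] == b - a:
            return POSITIVE
        if chi[b] - chi[a] == b - a:
            return NEGATIVE
        return INDETERMINATE

    def make_pair(o: int, label: str, source: str) -> SegmentPair:
        i0 = o - gap - in_len
        return SegmentPair(
            patient_id=record.patient_id,
            input_start_index=i0,
            outcome_start_index=o,
            label=label,
            qc_input=check_segment(record.pressure[i0 : i0 + in_len], qc_thresholds),
            qc_outcome=check_segment(record.pressure[o : o + out_len], qc_thresholds),
            source=source,
        )

    pairs: dict[int, SegmentPair] = {}
    skip_log: list[dict] = []
    for ev in events:
        o = ev.onset_index
        if o < min_outcome_start:
            skip_log.append(
                {
                    "patient_id": record.patient_id,
                    "outcome_start_index": o,
                    "reason": "input window before record start",
                }
            )
            continue
        if o + out_len > n:
            continue
        label = POSITIVE if ev.kind == "hypotensive" else NEGATIVE
        pairs[o] = make_pair(o, label, "event")

    stride = int(round(stride_s * fs))
    for o in range(min_outcome_start, n - out_len + 1, stride):
        if o not in pairs:
            pairs[o] = make_pair(o, window_label(o), "grid")

    ordered = [pairs[o] for o in sorted(pairs)]
    return ordered, skip_log


def split_patients(
    patient_ids, train_frac: float = 0.7, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Deterministic patient-level train/validation split."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    ids = sorted(set(patient_ids))
    if len(ids) < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7)))
    perm = rng.permutation(len(ids))
    n_train = min(max(int(round(train_frac * len(ids))), 1), len(ids) - 1)
    train = sorted(ids[i] for i in perm[:n_train])
    val = sorted(ids[i] for i in perm[n_train:])
    return train, val
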