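"""Artifact screening for waveform segments.

Four exclusion criteria are applied to every 20-s input and 60-s outcome
segment; a segment meeting any of them is excluded and never edited:

* ``MISSING`` — any missing (NaN) sample,
* ``RANGE``   — any pressure strictly over 200 mmHg or strictly under 20 mmHg,
* ``FLAT``    — max minus min strictly under 20 mmHg,
* ``JUMP``    — any adjacent-sample difference strictly over 30 mmHg
  (a gradient over 3000 mmHg/s at 100 Hz).

All thresholds use strict inequalities ("over"/"under"); a value exactly at a
threshold does not violate. Adjacent pairs straddling a missing sample are not
evaluated for JUMP — MISSING already excludes the segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = "MISSING"
RANGE = "RANGE"
FLAT = "FLAT"
JUMP = "JUMP"

ALL_CODES = (MISSING, RANGE, FLAT, JUMP)


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds in mmHg; defaults are the screening criteria."""

    p_max: float = 200.0
    p_min: float = 20.0
    flat_range: float = 20.0
    max_jump: float = 30.0

    def __post_init__(self) -> None:
        for name in ("p_max", "p_min", "flat_range", "max_jump"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class QCResult:
    violations: frozenset[str] = frozenset()

    @property
    def valid(self) -> bool:
        return not self.violations

    def codes(self) -> str:
        """Stable string form for manifests, e.g. ``"FLAT|RANGE"`` or ``"OK"``."""
        if self.valid:
            return "OK"
        return "|".join(sorted(self.violations))


def check_segment(values: np.ndarray, thresholds: QCThresholds | None = None) -> QCResult:
    """Screen one segment; reports every violated criterion, never edits data."""
    thresholds = thresholds or QCThresholds()
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot QC an empty segment")

    violations = set()
    missing = np.isnan(values)
    if missing.any():
        violations.add(MISSING)
    finite = values[~missing]
    if finite.size:
        if np.any(finite > thresholds.p_max) or np.any(finite < thresholds.p_min):
            violations.add(RANGE)
        if finite.max() - finite.min() < thresholds.flat_range:
            violations.add(FLAT)
    if finite.size >= 2:
        diffs = np.abs(np.diff(values))
        # NaN-straddling pairs give NaN diffs; NaN > x is False, so they are skipped.
        if np.any(diffs > thresholds.max_jump):
            violations.add(JUMP)
    return QCResult(frozenset(violations))
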