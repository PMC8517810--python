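"""Cardiac-cycle slicing, beat normalization and model-input assembly.

A 20-s QC-valid segment is sliced into foot-to-foot cardiac cycles: systolic
peaks are found as local maxima with a 0.3-s refractory distance and 10-mmHg
prominence, and the cycle boundary (foot) is the pressure minimum between
consecutive peaks. Each full cycle is linearly interpolated to 100 points.
The recurrent model consumes a fixed 30x100 matrix: segments with more than
30 cycles keep the most recent 30 (pre-truncation), segments with fewer are
prepadded with zero rows. The convolutional model consumes the raw length-2000
segment after the same fixed affine scaling.

Scaling is anchored at the physiologic QC bounds, x' = (x - 20) / (200 - 20)
clipped to [0, 1], rather than per-segment min-max: absolute pressure level is
exactly the signal the task needs, so it must survive scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

N_BEAT_ROWS = 30
BEAT_LEN = 100
SCALE_LO = 20.0
SCALE_HI = 200.0


class UnsliceableSegmentError(ValueError):
    """Raised when fewer than two systolic peaks can be found."""


@dataclass
class BeatSequence:
    """Foot-to-foot cycle boundaries and length-100 normalized beats.

    ``boundaries`` are half-open ``(start, end)`` sample indices into the
    source segment; ``beats_normalized`` holds the un-scaled mmHg beats
    interpolated to 100 points each.
    """

    boundaries: list[tuple[int, int]]
    beats_normalized: list[np.ndarray] = field(default_factory=list)

    @property
    def n_beats(self) -> int:
        return len(self.boundaries)


@dataclass
class BeatMatrix:
    values: np.ndarray  # (30, 100)
    n_real_beats: int

    def __post_init__(self) -> None:
        assert self.values.shape == (N_BEAT_ROWS, BEAT_LEN)


def detect_beats(
    segment: np.ndarray,
    fs: int = 100,
    min_distance_s: float = 0.3,
    prominence: float = 10.0,
) -> BeatSequence:
    """Slice a segment into full foot-to-foot cardiac cycles.

    First and last partial cycles are discarded. Raises
    :class:`UnsliceableSegmentError` when fewer than two peaks are found.
    """
    segment = np.asarray(segment, dtype=np.float64)
    peaks, _ = find_peaks(
        segment, distance=max(int(round(min_distance_s * fs)), 1), prominence=prominence
    )
    if peaks.size < 2:
        raise UnsliceableSegmentError(
            f"unsliceable segment: found {peaks.size} systolic peak(s)"
        )
    feet = [
        int(np.argmin(segment[peaks[i] : peaks[i + 1]])) + peaks[i] for i in range(peaks.size - 1)
    ]
    # Recover the edge cycles: the foot of the first peak's cycle (minimum
    # before it) and the foot ending the last cycle (minimum after it) often
    # lie inside the segment. Accept them only when the resulting cycle is
    # plausibly complete — at least 3/4 of the median cycle length and not
    # pinned to the segment boundary — so cut partial cycles stay excluded.
    median_len = float(np.median(np.diff(peaks))) if peaks.size > 1 else np.inf
    lead = int(np.argmin(segment[: peaks[0]])) if peaks[0] > 0 else 0
    if 0 < lead and feet[0] - lead >= 0.75 * median_len:
        feet.insert(0, lead)
    trail = int(np.argmin(segment[peaks[-1] :])) + peaks[-1]
    if trail < segment.size - 1 and trail - feet[-1] >= 0.75 * median_len:
        feet.append(trail)
    boundaries = [(feet[i], feet[i + 1]) for i in range(len(feet) - 1)]
    beats = [normalize_beat(segment[s : e + 1]) for s, e in boundaries]
    return BeatSequence(boundaries=boundaries, beats_normalized=beats)


def normalize_beat(beat: np.ndarray) -> np.ndarray:
    """Linearly interpolate one beat onto 100 equally spaced points."""
    beat = np.asarray(beat, dtype=np.float64)
    if beat.size < 2:
        raise ValueError("beat must have at least 2 samples")
    grid = np.linspace(0.0, beat.size - 1.0, BEAT_LEN)
    return np.interp(grid, np.arange(beat.size), beat)


def scale_values(values: np.ndarray) -> np.ndarray:
    """Fixed physiologic-range min-max map to [0, 1], anchored at 20/200 mmHg."""
    values = np.asarray(values, dtype=np.float64)
    return np.clip((values - SCALE_LO) / (SCALE_HI - SCALE_LO), 0.0, 1.0)


def build_beat_matrix(beats: BeatSequence) -> BeatMatrix:
    """Assemble the fixed 30x100 input: scaled beats, prepadded/pretruncated.

    More than 30 beats: keep the last 30 (drop the oldest time steps). Fewer:
    zero rows occupy the first ``30 - n`` rows so real beats stay most recent.
    """
    if beats.n_beats == 0:
        raise ValueError("cannot build a beat matrix from zero beats")
    kept = beats.beats_normalized[-N_BEAT_ROWS:]
    mat = np.zeros((N_BEAT_ROWS, BEAT_LEN))
    for row, beat in enumerate(kept, start=N_BEAT_ROWS - len(kept)):
        mat[row] = scale_values(beat)
    return BeatMatrix(values=mat, n_real_beats=len(kept))


def segment_to_model_inputs(segment: np.ndarray) -> tuple[np.ndarray, BeatMatrix, BeatSequence]:
    """Convenience: (scaled length-2000 array, BeatMatrix, BeatSequence)."""
    beats = detect_beats(segment)
    return scale_values(segment), build_beat_matrix(beats), beats
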