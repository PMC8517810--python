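"""Waveform record I/O and resampling to the pipeline's canonical 100 Hz.

A :class:`WaveformRecord` holds one patient's continuous arterial-pressure
trace. Missing samples are represented by NaN, a sentinel no physiologic
pressure can take. Two on-disk formats are supported:

* CSV with header ``time_s,abp_mmhg``; empty pressure cells are missing.
* A versioned binary container (magic ``ABPW1``) storing the sampling rate,
  patient id, t0 and a float64 payload; NaN encodes missing samples.

Indexing is 0-based and time is ``t0 + i / sampling_rate``; all windows used
downstream are half-open ``[start, end)``.
"""

from __future__ import annotations

import csv
import io
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as _signal

MISSING = np.nan
SUPPORTED_RATES = (100, 500)
_MAGIC = b"ABPW1"


class RecordFormatError(ValueError):
    """Raised when a record file cannot be parsed."""


@dataclass
class WaveformRecord:
    """One patient's continuous ABP trace.

    Parameters
    ----------
    patient_id : str
        Stable identifier; used for patient-level splits.
    sampling_rate : int
        Samples per second; 100 or 500 on ingest, exactly 100 after
        canonicalization.
    pressure : np.ndarray
        Pressure in mmHg, float array; NaN marks missing samples.
    t0 : float
        Time offset in seconds of sample 0.
    """

    patient_id: str
    sampling_rate: int
    pressure: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=np.float64)
        if self.sampling_rate not in SUPPORTED_RATES:
            raise ValueError(
                f"sampling_rate must be one of {SUPPORTED_RATES}, "
                f"got {self.sampling_rate}"
            )

    @property
    def n_samples(self) -> int:
        return self.pressure.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    def equals(self, other: "WaveformRecord") -> bool:
        return (
            self.patient_id == other.patient_id
            and self.sampling_rate == other.sampling_rate
            and self.t0 == other.t0
            and self.pressure.shape == other.pressure.shape
            and bool(
                np.all(
                    (self.pressure == other.pressure)
                    | (np.isnan(self.pressure) & np.isnan(other.pressure))
                )
            )
        )


def read_record(path: str | Path, format: str = "csv") -> WaveformRecord:
    """Read a record from disk.

    ``format`` is ``"csv"`` or ``"bin"``. CSV parsing reports malformed rows
    with their 1-based line number and rejects non-monotone time columns.
    """
    path = Path(path)
    if format == "csv":
        return _read_csv(path)
    if format == "bin":
        return _read_bin(path)
    raise ValueError(f"unknown format {format!r}")


def write_record(record: WaveformRecord, path: str | Path, format: str = "csv") -> Path:
    """Write a record; lossless round-trip for both formats."""
    path = Path(path)
    if format == "csv":
        _write_csv(record, path)
    elif format == "bin":
        _write_bin(record, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def resample_to_100hz(record: WaveformRecord, anti_alias: bool = False) -> WaveformRecord:
    """Canonicalize to 100 Hz.

    500 Hz input is decimated 5:1 by keeping every 5th sample, so every kept
    value equals a source value and missing sentinels propagate; with
    ``anti_alias=True`` a zero-phase low-pass is applied first (only possible
    on gap-free records). 100 Hz input is returned unchanged.
    """
    if record.sampling_rate == 100:
        return record
    if record.sampling_rate != 500:
        raise ValueError(f"unsupported sampling rate {record.sampling_rate}")
    values = record.pressure
    if anti_alias:
        if np.isnan(values).any():
            raise ValueError("anti-alias filtering requires a gap-free record")
        sos = _signal.butter(8, 40.0, btype="low", fs=500.0, output="sos")
        values = _signal.sosfiltfilt(sos, values)
    return replace(record, sampling_rate=100, pressure=values[::5].copy())


# -- CSV ------------------------------------------------------------------


def _write_csv(record: WaveformRecord, path: Path) -> None:
    times = record.times()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "abp_mmhg"])
        for t, p in zip(times, record.pressure):
            w.writerow([f"{t:.6f}", "" if np.isnan(p) else repr(float(p))])


def _read_csv(path: Path) -> WaveformRecord:
    times: list[float] = []
    values: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [c.strip().lower() for c in header[:2]] != ["time_s", "abp_mmhg"]:
            raise RecordFormatError(f"{path}: line 1: expected header 'time_s,abp_mmhg'")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise RecordFormatError(f"{path}: line {lineno}: expected 2 columns, got {len(row)}")
            try:
                t = float(row[0])
            except ValueError:
                raise RecordFormatError(f"{path}: line {lineno}: bad time value {row[0]!r}") from None
            cell = row[1].strip()
            if cell == "":
                p = MISSING
            else:
                try:
                    p = float(cell)
                except ValueError:
                    raise RecordFormatError(
                        f"{path}: line {lineno}: bad pressure value {row[1]!r}"
                    ) from None
            times.append(t)
            values.append(p)
    if not times:
        raise RecordFormatError(f"{path}: no data rows")
    t = np.asarray(times)
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 3  # +2 header/1-based, +1 second row of pair
            raise RecordFormatError(f"{path}: line {bad}: time column not strictly increasing")
        rate = int(round(1.0 / float(np.median(dt))))
    else:
        rate = 100
    if rate not in SUPPORTED_RATES:
        raise RecordFormatError(f"{path}: inferred sampling rate {rate} not in {SUPPORTED_RATES}")
    return WaveformRecord(
        patient_id=path.stem,
        sampling_rate=rate,
        pressure=np.asarray(values),
        t0=float(t[0]),
    )


# -- binary container ------------------------------------------------------


def _write_bin(record: WaveformRecord, path: Path) -> None:
    pid = record.patient_id.encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<IIQd", record.sampling_rate, len(pid), record.n_samples, record.t0))
        fh.write(pid)
        fh.write(np.ascontiguousarray(record.pressure, dtype="<f8").tobytes())


def _read_bin(path: Path) -> WaveformRecord:
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise RecordFormatError(f"{path}: bad magic bytes {magic!r}")
        rate, id_len, n, t0 = struct.unpack("<IIQd", fh.read(struct.calcsize("<IIQd")))
        pid = fh.read(id_len).decode("utf-8")
        payload = fh.read(8 * n)
        if len(payload) != 8 * n:
            raise RecordFormatError(f"{path}: truncated payload")
        pressure = np.frombuffer(payload, dtype="<f8").copy()
    return WaveformRecord(patient_id=pid, sampling_rate=int(rate), pressure=pressure, t0=t0)
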