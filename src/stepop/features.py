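"""The 12 per-segment waveform features and robust scaling.

All per-beat quantities are computed on un-scaled mmHg values over the
detected foot-to-foot cycles of a 20-s segment: systolic pressure is the
cycle maximum, diastolic the cycle minimum, pulse pressure (PP) their
difference, systolic time the foot-to-peak interval, beat area the
trapezoidal integral of pressure over the cycle, and per-beat MAP the
time-average (area / cycle length). Segment-level features are averages or
extremes across full beats, plus

    PPV = (PP_max - PP_min) * 2.0 / (PP_max + PP_min),

the normalized spread of pulse pressures. Robust scaling maps each feature
through x' = (x - Q2) / (Q3 - Q1) with quartiles estimated on the training
fold only (linear-interpolation quartile convention).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .beats import BeatSequence

FEATURE_NAMES = (
    "mean_beat_length",
    "map_avg",
    "pp_max",
    "pp_min",
    "pp_range",
    "pp_avg",
    "ppv",
    "systolic_time_avg",
    "systolic_pressure_avg",
    "systolic_pressure_range",
    "diastolic_pressure_avg",
    "beat_area_avg",
)


@dataclass(frozen=True)
class FeatureVector:
    mean_beat_length: float  # s
    map_avg: float  # mmHg
    pp_max: float  # mmHg
    pp_min: float  # mmHg
    pp_range: float  # mmHg
    pp_avg: float  # mmHg
    ppv: float  # dimensionless
    systolic_time_avg: float  # s
    systolic_pressure_avg: float  # mmHg
    systolic_pressure_range: float  # mmHg
    diastolic_pressure_avg: float  # mmHg
    beat_area_avg: float  # mmHg*s

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def extract_features(segment: np.ndarray, beats: BeatSequence, fs: int = 100) -> FeatureVector:
    """Compute the 12 features from one segment's detected beats."""
    segment = np.asarray(segment, dtype=np.float64)
    if beats.n_beats < 2:
        raise ValueError(f"need at least 2 full beats, got {beats.n_beats}")

    lengths, maps, pps, sys_times, sys_ps, dia_ps, areas = [], [], [], [], [], [], []
    for s, e in beats.boundaries:
        cycle = segment[s : e + 1]  # inclusive end sample spans the full duration
        length = (e - s) / fs
        sys_p = float(cycle.max())
        dia_p = float(cycle.min())
        area = float(np.trapezoid(cycle, dx=1.0 / fs))
        lengths.append(length)
        maps.append(area / length)
        pps.append(sys_p - dia_p)
        sys_times.append(int(np.argmax(cycle)) / fs)
        sys_ps.append(sys_p)
        dia_ps.append(dia_p)
        areas.append(area)

    pp_max, pp_min = max(pps), min(pps)
    # a pulseless (constant) segment has zero pulse pressure everywhere
    ppv = 0.0 if pp_max + pp_min == 0 else (pp_max - pp_min) * 2.0 / (pp_max + pp_min)
    return FeatureVector(
        mean_beat_length=float(np.mean(lengths)),
        map_avg=float(np.mean(maps)),
        pp_max=pp_max,
        pp_min=pp_min,
        pp_range=pp_max - pp_min,
        pp_avg=float(np.mean(pps)),
        ppv=ppv,
        systolic_time_avg=float(np.mean(sys_times)),
        systolic_pressure_avg=float(np.mean(sys_ps)),
        systolic_pressure_range=float(max(sys_ps) - min(sys_ps)),
        diastolic_pressure_avg=float(np.mean(dia_ps)),
        beat_area_avg=float(np.mean(areas)),
    )


def features_table(
    vectors: list[FeatureVector], patient_ids: list[str], labels: list[int]
) -> pd.DataFrame:
    df = pd.DataFrame([v.as_array() for v in vectors], columns=list(FEATURE_NAMES))
    df.insert(0, "patient_id", patient_ids)
    df["label"] = labels
    return df


@dataclass
class RobustScaler:
    """Median/IQR scaler fitted on the training fold only.

    Features whose IQR is zero are flagged degenerate and scale to 0.
    """

    q1: np.ndarray
    q2: np.ndarray
    q3: np.ndarray
    degenerate: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def to_dict(self) -> dict:
        return {
            "q1": self.q1.tolist(),
            "q2": self.q2.tolist(),
            "q3": self.q3.tolist(),
            "degenerate": self.degenerate.tolist(),
            "feature_names": list(self.feature_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RobustScaler":
        return cls(
            q1=np.asarray(d["q1"]),
            q2=np.asarray(d["q2"]),
            q3=np.asarray(d["q3"]),
            degenerate=np.asarray(d["degenerate"], dtype=bool),
            feature_names=tuple(d["feature_names"]),
        )


def fit_robust_scaler(
    features: np.ndarray | pd.DataFrame, feature_names: tuple[str, ...] = FEATURE_NAMES
) -> RobustScaler:
    """Estimate per-feature quartiles (linear interpolation convention)."""
    if isinstance(features, pd.DataFrame):
        feature_names = tuple(c for c in features.columns if c in FEATURE_NAMES) or feature_names
        X = features[list(feature_names)].to_numpy(dtype=np.float64)
    else:
        X = np.asarray(features, dtype=np.float64)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 training rows to fit quartiles")
    q1, q2, q3 = np.percentile(X, [25.0, 50.0, 75.0], axis=0, method="linear")
    return RobustScaler(q1=q1, q2=q2, q3=q3, degenerate=(q3 - q1) <= 0.0, feature_names=feature_names)


def apply_scaler(scaler: RobustScaler, features: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Elementwise (x - Q2) / (Q3 - Q1); degenerate features map to 0."""
    if isinstance(features, pd.DataFrame):
        missing = [c for c in scaler.feature_names if c not in features.columns]
        if missing:
            raise ValueError(f"feature columns missing: {missing}")
        X = features[list(scaler.feature_names)].to_numpy(dtype=np.float64)
    else:
        X = np.asarray(features, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != scaler.q2.size:
            raise ValueError(
                f"expected {scaler.q2.size} features, got {X.shape[1]}"
            )
    iqr = np.where(scaler.degenerate, 1.0, scaler.q3 - scaler.q1)
    out = (X - scaler.q2) / iqr
    out[:, scaler.degenerate] = 0.0
    return out
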