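"""End-to-end orchestration: simulate -> label -> preprocess -> train -> tune
-> evaluate, with one global seed, stage manifests and a CONSORT-style count
summary.

Each stage reads and writes files under a run directory, so stages can be run
individually (the CLI maps onto them) or chained with :func:`run_all`. A run
is fully reproducible from its emitted config: the global seed is expanded
deterministically into per-stage seeds, and repeated runs from the same
config produce byte-identical reports and manifests.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import record_io
from .beats import UnsliceableSegmentError, build_beat_matrix, detect_beats, scale_values
from .ensemble import (
    EnsembleWeights,
    ensemble_predict,
    evaluate_predictions,
    optimize_alpha,
)
from .features import (
    FEATURE_NAMES,
    RobustScaler,
    apply_scaler,
    extract_features,
    fit_robust_scaler,
)
from .labeling import LabelThresholds, extract_segment_pairs, split_patients
from .models import (
    CnnConfig,
    FittedLogistic,
    FittedModel,
    PredictionSet,
    RnnConfig,
    TrainConfig,
    CNNModel,
    RNNModel,
    inner_split,
    train_cnn,
    train_logistic,
    train_rnn,
)
from .qc import QCThresholds
from .synthetic import SimConfig, simulate_cohort

# Defaults that are deliberate design choices rather than printed study
# constants; echoed in the emitted run manifest so a reader can tell which
# knobs carry evidential weight.
NON_PAPER_FIELDS = [
    "sim.*",
    "stride_s",
    "record_format",
    "train.epochs",
    "train.batch_size",
    "train.weight_decay",
    "train.dtype",
    "cnn.*",
    "rnn.hidden_size",
    "rnn.fc_width",
    "rnn.dropout",
    "alpha_grid_step",
    "bootstrap.replace (without-replacement subsampling)",
    "qc/label boundary semantics: strict inequalities",
]


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    labels: LabelThresholds = field(default_factory=LabelThresholds)
    qc: QCThresholds = field(default_factory=QCThresholds)
    train: TrainConfig = field(default_factory=TrainConfig)
    cnn: CnnConfig = field(default_factory=CnnConfig)
    rnn: RnnConfig = field(default_factory=RnnConfig)
    stride_s: float = 20.0
    train_frac: float = 0.7
    alpha_grid_step: float = 0.01
    n_resamples: int = 1000
    resample_fraction: float = 0.5
    record_format: str = "bin"
    seed: int = 0

    def resolve_seeds(self) -> "PipelineConfig":
        """Expand the global seed into per-stage seeds (one knob only)."""
        return dataclasses.replace(
            self,
            sim=dataclasses.replace(self.sim, seed=self.seed),
            train=dataclasses.replace(self.train, seed=self.seed + 1),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["non_paper_defaults"] = NON_PAPER_FIELDS
        return _listify(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d.pop("non_paper_defaults", None)
        sub = {
            "sim": SimConfig,
            "labels": LabelThresholds,
            "qc": QCThresholds,
            "train": TrainConfig,
            "cnn": CnnConfig,
            "rnn": RnnConfig,
        }
        kwargs = {}
        for key, val in d.items():
            if key in sub:
                kwargs[key] = sub[key](**_tupleize(val))
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, list):
        return [_listify(v) for v in obj]
    return obj


def _tupleize(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, list):
            out[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        else:
            out[k] = v
    return out


def small_config(seed: int = 0, n_patients: int = 50) -> PipelineConfig:
    """Desk-scale learnable cohort: strong 7-min pre-onset drift, modest
    artifact load, training sizes that finish on one CPU in minutes."""
    return PipelineConfig(
        sim=SimConfig(
            n_patients=n_patients,
            duration_s=1800.0,
            predrift_s=420.0,
            artifact_rate=2.0,
            noise_sd=1.0,
            seed=seed,
        ),
        train=TrainConfig(epochs=15, batch_size=256, seed=seed),
        n_resamples=200,
        seed=seed,
    )


def tiny_config(seed: int = 0) -> PipelineConfig:
    """Minimal config for smoke and reproducibility checks."""
    return PipelineConfig(
        sim=SimConfig(
            n_patients=8,
            duration_s=1200.0,
            event_schedule=((700.0, 120.0, 55.0),),
            artifact_rate=1.0,
            seed=seed,
        ),
        train=TrainConfig(epochs=2, batch_size=128, seed=seed),
        n_resamples=50,
        seed=seed,
    )


# -- stages ----------------------------------------------------------------


def stage_simulate(config: PipelineConfig, run_dir: str | Path) -> Path:
    run_dir = Path(run_dir)
    cohort_dir = run_dir / "cohort"
    simulate_cohort(config.sim, cohort_dir, record_format=config.record_format)
    config.to_yaml(run_dir / "config.yaml")
    return cohort_dir


def _load_records(config: PipelineConfig, run_dir: Path) -> dict[str, record_io.WaveformRecord]:
    cohort_dir = run_dir / "cohort"
    manifest = pd.read_csv(cohort_dir / "cohort_manifest.csv")
    fmt = config.record_format
    records = {}
    for _, row in manifest.iterrows():
        rec = record_io.read_record(cohort_dir / row["path"], format=fmt)
        records[row["patient_id"]] = record_io.resample_to_100hz(rec)
    return records


def stage_label(config: PipelineConfig, run_dir: str | Path) -> pd.DataFrame:
    """Enumerate and label segment pairs for every record; write the segment
    manifest, skip log and patient split."""
    run_dir = Path(run_dir)
    records = _load_records(config, run_dir)
    rows, skips = [], []
    for pid in sorted(records):
        pairs, skip_log = extract_segment_pairs(
            records[pid], config.labels, config.qc, config.stride_s
        )
        skips.extend(skip_log)
        for p in pairs:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "input_start_index": p.input_start_index,
                    "outcome_start_index": p.outcome_start_index,
                    "label": p.label,
                    "qc_input": p.qc_input.codes(),
                    "qc_outcome": p.qc_outcome.codes(),
                    "source": p.source,
                    "usable": p.usable,
                }
            )
    segments = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "input_start_index", "outcome_start_index",
            "label", "qc_input", "qc_outcome", "source", "usable",
        ],
    )
    segments.to_csv(run_dir / "segments.csv", index=False)
    pd.DataFrame(skips, columns=["patient_id", "outcome_start_index", "reason"]).to_csv(
        run_dir / "skip_log.csv", index=False
    )
    train_ids, val_ids = split_patients(sorted(records), config.train_frac, config.seed)
    with open(run_dir / "split.json", "w") as fh:
        json.dump({"train": train_ids, "validation": val_ids}, fh, indent=1, sort_keys=True)
    return segments


def stage_features(config: PipelineConfig, run_dir: str | Path) -> dict:
    """Build aligned model inputs for every usable labeled pair.

    Pairs whose input cannot be sliced into >= 2 beats are dropped from all
    three models' data (logged) so prediction sets stay aligned. The robust
    feature scaler is fitted on training-fold rows only.
    """
    run_dir = Path(run_dir)
    records = _load_records(config, run_dir)
    segments = pd.read_csv(run_dir / "segments.csv")
    with open(run_dir / "split.json") as fh:
        split = json.load(fh)
    train_set = set(split["train"])

    in_len = int(round(config.labels.input_len_s * 100))
    usable = segments[segments["usable"]]
    x_cnn, x_rnn, feats, meta, dropped = [], [], [], [], []
    for _, row in usable.iterrows():
        seg = records[row["patient_id"]].pressure[
            row["input_start_index"] : row["input_start_index"] + in_len
        ]
        try:
            beats = detect_beats(seg)
            if beats.n_beats < 2:
                raise UnsliceableSegmentError("fewer than 2 full beats")
            fv = extract_features(seg, beats)
        except (UnsliceableSegmentError, ValueError) as exc:
            dropped.append(
                {
                    "patient_id": row["patient_id"],
                    "outcome_start_index": row["outcome_start_index"],
                    "reason": str(exc),
                }
            )
            continue
        x_cnn.append(scale_values(seg))
        x_rnn.append(build_beat_matrix(beats).values)
        feats.append(fv.as_array())
        meta.append(
            {
                "seg_id": f"{row['patient_id']}:{row['outcome_start_index']}",
                "patient_id": row["patient_id"],
                "label": 1 if row["label"] == "positive" else 0,
                "fold": "train" if row["patient_id"] in train_set else "validation",
            }
        )

    meta_df = pd.DataFrame(meta)
    feat_arr = np.asarray(feats)
    train_mask = (meta_df["fold"] == "train").to_numpy()
    scaler = fit_robust_scaler(feat_arr[train_mask])
    feat_scaled = apply_scaler(scaler, feat_arr)

    np.savez_compressed(
        run_dir / "inputs.npz",
        x_cnn=np.asarray(x_cnn, dtype=np.float32),
        x_rnn=np.asarray(x_rnn, dtype=np.float32),
        x_feat=feat_scaled,
        y=meta_df["label"].to_numpy(),
        seg_id=meta_df["seg_id"].to_numpy(dtype="U"),
        patient_id=meta_df["patient_id"].to_numpy(dtype="U"),
        fold=meta_df["fold"].to_numpy(dtype="U"),
    )
    feat_table = pd.DataFrame(feat_arr, columns=list(FEATURE_NAMES))
    feat_table.insert(0, "seg_id", meta_df["seg_id"])
    feat_table.insert(1, "patient_id", meta_df["patient_id"])
    feat_table["label"] = meta_df["label"]
    feat_table["fold"] = meta_df["fold"]
    feat_table.to_csv(run_dir / "features.csv", index=False)
    with open(run_dir / "scaler.json", "w") as fh:
        json.dump(scaler.to_dict(), fh, indent=1, sort_keys=True)
    pd.DataFrame(dropped, columns=["patient_id", "outcome_start_index", "reason"]).to_csv(
        run_dir / "unsliceable_log.csv", index=False
    )

    # fix the inner 90/10 model-selection split once, shared by CNN and RNN
    y_tr = meta_df.loc[train_mask, "label"].to_numpy()
    pid_tr = meta_df.loc[train_mask, "patient_id"].to_numpy()
    _, tune_patients = inner_split(
        pid_tr, y_tr, config.train.model_select_frac, config.train.seed
    )
    split["tune"] = tune_patients
    with open(run_dir / "split.json", "w") as fh:
        json.dump(split, fh, indent=1, sort_keys=True)
    return {"n_usable": len(meta_df), "n_dropped": len(dropped)}


def _load_inputs(run_dir: Path):
    data = np.load(run_dir / "inputs.npz", allow_pickle=False)
    with open(run_dir / "split.json") as fh:
        split = json.load(fh)
    return data, split


def stage_train(config: PipelineConfig, run_dir: str | Path, model: str) -> None:
    """Train one model on the training fold and persist it.

    For the deep models the inner tuning patients' predictions are also
    written, ready for the ensemble weight search.
    """
    run_dir = Path(run_dir)
    data, split = _load_inputs(run_dir)
    fold = data["fold"]
    tr = fold == "train"
    y = data["y"][tr]
    pids = data["patient_id"][tr]
    seg_ids = data["seg_id"][tr]
    models_dir = run_dir / "models"
    models_dir.mkdir(exist_ok=True)

    if model == "logistic":
        fitted = train_logistic(data["x_feat"][tr], y, pids, seed=config.train.seed)
        payload = {
            "coef": fitted.model.coef_.tolist(),
            "intercept": fitted.model.intercept_.tolist(),
            "best_c": fitted.best_c,
            "cv_scores": fitted.cv_scores,
        }
        with open(models_dir / "logistic.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        return

    tune_patients = split["tune"]
    if model == "cnn":
        fitted = train_cnn(data["x_cnn"][tr], y, pids, config.train, config.cnn, tune_patients)
        X = data["x_cnn"]
    elif model == "rnn":
        fitted = train_rnn(data["x_rnn"][tr], y, pids, config.train, config.rnn, tune_patients)
        X = data["x_rnn"]
    else:
        raise ValueError(f"unknown model {model!r}")

    np.savez_compressed(models_dir / f"{model}.npz", **fitted.network.get_state())
    with open(models_dir / f"{model}.json", "w") as fh:
        json.dump(
            {
                "model": model,
                "best_epoch": fitted.best_epoch,
                "tune_patients": fitted.tune_patients,
                "history": fitted.history,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    tune_mask = tr & np.isin(data["patient_id"], tune_patients)
    probs = fitted.network.predict_proba(X[tune_mask])
    pd.DataFrame(
        {
            "seg_id": data["seg_id"][tune_mask],
            "label": data["y"][tune_mask],
            "prob": probs,
        }
    ).to_csv(run_dir / f"predictions_tune_{model}.csv", index=False)


def _load_network(config: PipelineConfig, run_dir: Path, model: str):
    state = dict(np.load(run_dir / "models" / f"{model}.npz"))
    dtype = np.dtype(config.train.dtype).type
    if model == "cnn":
        net = CNNModel(config.cnn, seed=config.train.seed, dtype=dtype)
    else:
        net = RNNModel(config.rnn, seed=config.train.seed, dtype=dtype)
    net.set_state(state)
    with open(run_dir / "models" / f"{model}.json") as fh:
        meta = json.load(fh)
    return FittedModel(
        network=net,
        model_tag=model,
        history=meta["history"],
        tune_patients=meta["tune_patients"],
        best_epoch=meta["best_epoch"],
    )


def _load_logistic(run_dir: Path) -> FittedLogistic:
    from sklearn.linear_model import LogisticRegression

    with open(run_dir / "models" / "logistic.json") as fh:
        payload = json.load(fh)
    clf = LogisticRegression()
    clf.coef_ = np.asarray(payload["coef"])
    clf.intercept_ = np.asarray(payload["intercept"])
    clf.classes_ = np.array([0, 1])
    clf.n_features_in_ = clf.coef_.shape[1]
    return FittedLogistic(
        model=clf, model_tag="logistic", best_c=payload["best_c"], cv_scores=payload["cv_scores"]
    )


def stage_tune(config: PipelineConfig, run_dir: str | Path) -> EnsembleWeights:
    """Search the ensemble weight on the inner tuning predictions."""
    run_dir = Path(run_dir)
    p = {}
    for model in ("rnn", "cnn"):
        df = pd.read_csv(run_dir / f"predictions_tune_{model}.csv")
        df = df.sort_values("seg_id").reset_index(drop=True)
        p[model] = PredictionSet(
            ids=df["seg_id"].to_numpy(),
            probabilities=df["prob"].to_numpy(),
            labels=df["label"].to_numpy(),
            model_tag=model,
        )
    weights = optimize_alpha(p["rnn"], p["cnn"], config.alpha_grid_step)
    pd.DataFrame({"alpha": weights.grid, "tuning_auprc": weights.curve}).to_csv(
        run_dir / "alpha_curve.csv", index=False
    )
    with open(run_dir / "alpha.json", "w") as fh:
        json.dump({"alpha": weights.alpha}, fh, indent=1, sort_keys=True)
    return weights


def stage_evaluate(config: PipelineConfig, run_dir: str | Path) -> dict:
    """Predict the validation fold with all models and write the report."""
    run_dir = Path(run_dir)
    data, _ = _load_inputs(run_dir)
    va = data["fold"] == "validation"
    y = data["y"][va]
    ids = data["seg_id"][va]
    with open(run_dir / "alpha.json") as fh:
        alpha = json.load(fh)["alpha"]

    preds: dict[str, PredictionSet] = {}
    cnn = _load_network(config, run_dir, "cnn")
    rnn = _load_network(config, run_dir, "rnn")
    logit = _load_logistic(run_dir)
    preds["cnn"] = cnn.predict(data["x_cnn"][va], ids=ids, labels=y)
    preds["rnn"] = rnn.predict(data["x_rnn"][va], ids=ids, labels=y)
    preds["logistic"] = logit.predict(data["x_feat"][va], ids=ids, labels=y)
    preds["ensemble"] = ensemble_predict(preds["rnn"], preds["cnn"], alpha)

    report = {"alpha": alpha, "models": {}}
    for tag in ("cnn", "rnn", "logistic", "ensemble"):
        report["models"][tag] = evaluate_predictions(
            preds[tag],
            n_resamples=config.n_resamples,
            fraction=config.resample_fraction,
            seed=config.seed,
        ).to_dict()
    report["validation_prevalence"] = float(np.mean(y))
    with open(run_dir / "eval_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    pd.DataFrame(
        {
            "seg_id": ids,
            "label": y,
            "p_cnn": preds["cnn"].probabilities,
            "p_rnn": preds["rnn"].probabilities,
            "p_logistic": preds["logistic"].probabilities,
            "p_ensemble": preds["ensemble"].probabilities,
        }
    ).to_csv(run_dir / "predictions_val.csv", index=False)
    return report


def consort_summary(run_dir: str | Path) -> dict:
    """Stage-by-stage data-flow accounting, recomputed from the manifests."""
    run_dir = Path(run_dir)
    cohort = pd.read_csv(run_dir / "cohort" / "cohort_manifest.csv")
    segments = pd.read_csv(run_dir / "segments.csv")
    with open(run_dir / "split.json") as fh:
        split = json.load(fh)
    qc_fail = (segments["qc_input"] != "OK") | (segments["qc_outcome"] != "OK")
    labeled = segments["label"].isin(["positive", "negative"])
    counts = {
        "patients_simulated": int(len(cohort)),
        "patients_train": len(split["train"]),
        "patients_validation": len(split["validation"]),
        "pairs_enumerated": int(len(segments)),
        "pairs_qc_excluded": int(qc_fail.sum()),
        "pairs_indeterminate": int((~qc_fail & ~labeled).sum()),
        "pairs_usable": int(segments["usable"].sum()),
        "qc_codes": {},
        "labels": segments.loc[segments["usable"], "label"].value_counts().to_dict(),
    }
    for col in ("qc_input", "qc_outcome"):
        vc = segments.loc[segments[col] != "OK", col].value_counts()
        counts["qc_codes"][col] = {str(k): int(v) for k, v in vc.items()}
    inputs_path = run_dir / "inputs.npz"
    if inputs_path.exists():
        data = np.load(inputs_path)
        dropped = pd.read_csv(run_dir / "unsliceable_log.csv")
        fold = data["fold"]
        y = data["y"]
        counts["pairs_unsliceable"] = int(len(dropped))
        counts["model_segments"] = {
            "train": {
                "total": int(np.sum(fold == "train")),
                "positive": int(np.sum(y[fold == "train"])),
            },
            "validation": {
                "total": int(np.sum(fold == "validation")),
                "positive": int(np.sum(y[fold == "validation"])),
            },
        }
        # conservation: usable = modeled + unsliceable
        assert counts["pairs_usable"] == len(y) + len(dropped)
    assert (
        counts["pairs_enumerated"]
        == counts["pairs_qc_excluded"] + counts["pairs_indeterminate"] + counts["pairs_usable"]
        + int((~qc_fail & labeled & ~segments["usable"]).sum())
    )
    with open(run_dir / "consort.json", "w") as fh:
        json.dump(counts, fh, indent=1, sort_keys=True)
    return counts


@dataclass
class RunResult:
    run_dir: Path
    report: dict
    consort: dict
    alpha: float


def run_all(config: PipelineConfig, run_dir: str | Path) -> RunResult:
    """Execute the full flow; any stage failure aborts with the stage name."""
    config = config.resolve_seeds()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    log_lines = []
    stages = [
        ("simulate", lambda: stage_simulate(config, run_dir)),
        ("label", lambda: stage_label(config, run_dir)),
        ("features", lambda: stage_features(config, run_dir)),
        ("train_cnn", lambda: stage_train(config, run_dir, "cnn")),
        ("train_rnn", lambda: stage_train(config, run_dir, "rnn")),
        ("train_logistic", lambda: stage_train(config, run_dir, "logistic")),
        ("tune", lambda: stage_tune(config, run_dir)),
        ("evaluate", lambda: stage_evaluate(config, run_dir)),
        ("consort", lambda: consort_summary(run_dir)),
    ]
    for name, fn in stages:
        t0 = time.time()
        try:
            fn()
        except Exception as exc:
            (run_dir / "PARTIAL_RUN").write_text(f"failed at stage {name}: {exc}\n")
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log_lines.append(f"{name}: {time.time() - t0:.1f}s")
    (run_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    with open(run_dir / "eval_report.json") as fh:
        report = json.load(fh)
    with open(run_dir / "consort.json") as fh:
        consort = json.load(fh)
    return RunResult(run_dir=run_dir, report=report, consort=consort, alpha=report["alpha"])
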