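"""The three classifiers and their training procedures.

* 1-D CNN on the scaled length-2000 waveform: conv / batch-norm / ReLU /
  max-pool blocks, global average pooling and fully connected layers with a
  sigmoid output.
* Stacked bidirectional LSTM (3 layers) on the 30x100 beat matrix; the final
  forward and backward hidden states feed a fully connected head.
* L2-penalized logistic regression on the 12 robust-scaled features, with
  the penalty strength chosen by patient-grouped 5-fold cross-validation.

Both networks minimize class-weighted binary cross entropy (weights 1 for
negatives, 20 for positives) with AdamW (beta1=0.9, beta2=0.99, learning
rate 1e-4). Model selection trains on 90% of the training-fold patients and
keeps the epoch checkpoint with the best AUPRC on the remaining 10%; that
same inner 10% later serves as the ensemble's weight-tuning set. Training is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold

from .nn.core import Tensor, add, matmul, mean, mul, relu, reshape, concat, select_time, softplus
from .nn import layers as L
from .nn.optim import AdamW

BCE_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.99
    weight_decay: float = 0.01
    class_weights: tuple[float, float] = (1.0, 20.0)  # (negative, positive)
    epochs: int = 20
    batch_size: int = 256
    model_select_frac: float = 0.10
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if min(self.class_weights) <= 0:
            raise ValueError("class weights must be positive")


@dataclass(frozen=True)
class CnnConfig:
    conv_blocks: tuple[tuple[int, int, int], ...] = ((7, 16, 4), (5, 32, 4), (3, 64, 4))
    fc_width: int = 64
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if not self.conv_blocks:
            raise ValueError("need at least one conv block")


@dataclass(frozen=True)
class RnnConfig:
    n_layers: int = 3
    bidirectional: bool = True
    hidden_size: int = 64
    fc_width: int = 64
    dropout: float = 0.0


@dataclass
class PredictionSet:
    ids: np.ndarray
    probabilities: np.ndarray
    labels: np.ndarray | None
    model_tag: str

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.probabilities):
                raise ValueError("labels and probabilities must align")
        if len(self.ids) != len(self.probabilities):
            raise ValueError("ids and probabilities must align")
        if self.probabilities.size and (
            not np.all(np.isfinite(self.probabilities))
            or self.probabilities.min() < 0
            or self.probabilities.max() > 1
        ):
            raise ValueError("probabilities must be finite and within [0, 1]")


def weighted_bce(
    probabilities: np.ndarray,
    labels: np.ndarray,
    class_weights: tuple[float, float] = (1.0, 20.0),
    eps: float = BCE_EPS,
) -> float:
    """Mean over the batch of w(y) * [-y log p - (1-y) log(1-p)].

    Probabilities exactly at 0 or 1 are clipped at ``eps``.
    """
    p = np.clip(np.asarray(probabilities, dtype=np.float64), eps, 1.0 - eps)
    y = np.asarray(labels, dtype=np.float64)
    w = np.where(y == 1, class_weights[1], class_weights[0])
    return float(np.mean(w * (-y * np.log(p) - (1.0 - y) * np.log1p(-p))))


def _weighted_bce_from_logits(z: Tensor, y: np.ndarray, w: np.ndarray) -> Tensor:
    """Same loss as :func:`weighted_bce`, composed stably from logits:
    -log sigmoid(z) = softplus(-z) and -log(1 - sigmoid(z)) = softplus(z)."""
    pos = mul(softplus(mul(z, -1.0)), w * y)
    neg = mul(softplus(z), w * (1.0 - y))
    return mean(add(pos, neg))


class _Network:
    """Shared plumbing: parameter collection, state snapshots, prediction."""

    layers_with_state: list[L.Layer]

    def parameters(self) -> list[Tensor]:
        return [p for layer in self._layers() for p in layer.parameters()]

    def _layers(self) -> list[L.Layer]:
        raise NotImplementedError

    def forward(self, X: np.ndarray, training: bool) -> Tensor:
        raise NotImplementedError

    def get_state(self) -> dict:
        state = {f"param_{i}": p.data.copy() for i, p in enumerate(self.parameters())}
        for j, layer in enumerate(self._layers()):
            for k, v in layer.state_dict().items():
                state[f"buffer_{j}_{k}"] = v
        return state

    def set_state(self, state: dict) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = state[f"param_{i}"].copy()
        for j, layer in enumerate(self._layers()):
            sd = layer.state_dict()
            if sd:
                layer.load_state({k: state[f"buffer_{j}_{k}"] for k in sd})

    def predict_proba(self, X: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        if len(X) == 0:
            return np.zeros(0)
        out = []
        for i in range(0, len(X), batch_size):
            z = self.forward(X[i : i + batch_size], training=False)
            out.append(1.0 / (1.0 + np.exp(-z.data.astype(np.float64))))
        return np.concatenate(out)


class CNNModel(_Network):
    """1-D convolutional classifier over the scaled length-2000 segment."""

    def __init__(self, config: CnnConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence((seed, 11)))
        self.convs: list[L.Conv1d] = []
        self.bns: list[L.BatchNorm1d] = []
        self.pools: list[L.MaxPool1d] = []
        c_in = 1
        for kernel, filters, pool in config.conv_blocks:
            self.convs.append(L.Conv1d(c_in, filters, kernel, rng, dtype))
            self.bns.append(L.BatchNorm1d(filters, dtype))
            self.pools.append(L.MaxPool1d(pool))
            c_in = filters
        self.dropout = L.Dropout(config.dropout, np.random.default_rng(np.random.SeedSequence((seed, 12))))
        self.fc1 = L.Linear(c_in, config.fc_width, rng, dtype)
        self.fc2 = L.Linear(config.fc_width, 1, rng, dtype)
        self.dtype = dtype

    def _layers(self):
        return [*self.convs, *self.bns, self.fc1, self.fc2]

    def forward(self, X: np.ndarray, training: bool) -> Tensor:
        h = np.asarray(X, dtype=self.dtype)[:, None, :]  # (N, 1, 2000)
        for conv, bn, pool in zip(self.convs, self.bns, self.pools):
            h = pool(relu(bn(conv(h), training)))
        h = L.global_avg_pool(h)  # (N, C)
        h = self.dropout(relu(self.fc1(h)), training)
        z = self.fc2(h)
        return reshape(z, (z.shape[0],))


class RNNModel(_Network):
    """Stacked bidirectional LSTM over the (N, 30, 100) beat matrix."""

    def __init__(self, config: RnnConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence((seed, 21)))
        H = config.hidden_size
        self.cells: list[tuple[L.LSTMCell, L.LSTMCell | None]] = []
        n_in = 100
        for _ in range(config.n_layers):
            fwd = L.LSTMCell(n_in, H, rng, dtype, reverse=False)
            bwd = L.LSTMCell(n_in, H, rng, dtype, reverse=True) if config.bidirectional else None
            self.cells.append((fwd, bwd))
            n_in = H * (2 if config.bidirectional else 1)
        self.dropout = L.Dropout(config.dropout, np.random.default_rng(np.random.SeedSequence((seed, 22))))
        self.fc1 = L.Linear(n_in, config.fc_width, rng, dtype)
        self.fc2 = L.Linear(config.fc_width, 1, rng, dtype)
        self.dtype = dtype

    def _layers(self):
        flat = []
        for fwd, bwd in self.cells:
            flat.append(fwd)
            if bwd is not None:
                flat.append(bwd)
        return [*flat, self.fc1, self.fc2]

    def forward(self, X: np.ndarray, training: bool) -> Tensor:
        seq = np.asarray(X, dtype=self.dtype)  # (N, 30, 100)
        out_f = out_b = None
        for fwd, bwd in self.cells:
            out_f = fwd(seq)
            if bwd is not None:
                out_b = bwd(seq)
                seq = concat([out_f, out_b], axis=2)
            else:
                seq = out_f
        T = X.shape[1]
        if out_b is not None:
            feat = concat([select_time(out_f, T - 1), select_time(out_b, 0)], axis=1)
        else:
            feat = select_time(out_f, T - 1)
        h = self.dropout(relu(self.fc1(feat)), training)
        z = self.fc2(h)
        return reshape(z, (z.shape[0],))


@dataclass
class FittedModel:
    """A trained network plus its selection history and inner tuning split."""

    network: _Network
    model_tag: str
    history: list[dict]
    tune_patients: list[str]
    best_epoch: int

    def predict(self, X: np.ndarray, ids=None, labels=None) -> PredictionSet:
        probs = self.network.predict_proba(X)
        ids = np.arange(len(probs)) if ids is None else ids
        return PredictionSet(ids=ids, probabilities=probs, labels=labels, model_tag=self.model_tag)


def inner_split(
    patient_ids: np.ndarray,
    labels: np.ndarray,
    frac: float = 0.10,
    seed: int = 0,
    max_tries: int = 100,
) -> tuple[list[str], list[str]]:
    """Patient-level (fit, tune) split; both sides must contain both classes."""
    pids = np.asarray(patient_ids)
    y = np.asarray(labels)
    unique = sorted(set(pids.tolist()))
    if len(unique) < 2:
        raise ValueError("need at least 2 patients for the inner split")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 31)))
    n_tune = min(max(int(round(frac * len(unique))), 1), len(unique) - 1)
    for _ in range(max_tries):
        perm = rng.permutation(len(unique))
        tune = {unique[i] for i in perm[:n_tune]}
        fit = set(unique) - tune
        tune_mask = np.isin(pids, sorted(tune))
        if len(set(y[tune_mask])) == 2 and len(set(y[~tune_mask])) == 2:
            return sorted(fit), sorted(tune)
    raise ValueError("could not find an inner split with both classes on both sides")


def _train_network(
    network: _Network,
    X: np.ndarray,
    y: np.ndarray,
    patient_ids: np.ndarray,
    config: TrainConfig,
    model_tag: str,
    tune_patients: list[str] | None = None,
) -> FittedModel:
    from .ensemble import auprc  # local import to avoid a cycle

    y = np.asarray(y, dtype=np.float64)
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    pids = np.asarray(patient_ids)
    if tune_patients is None:
        _, tune_patients = inner_split(pids, y, config.model_select_frac, config.seed)
    tune_mask = np.isin(pids, tune_patients)
    fit_idx = np.flatnonzero(~tune_mask)
    tune_idx = np.flatnonzero(tune_mask)
    if len(set(y[fit_idx].tolist())) < 2 or len(set(y[tune_idx].tolist())) < 2:
        raise ValueError("inner fit/tune folds must each contain both classes")

    w = np.where(y == 1, config.class_weights[1], config.class_weights[0])
    opt = AdamW(
        network.parameters(),
        lr=config.learning_rate,
        betas=(config.adam_beta1, config.adam_beta2),
        weight_decay=config.weight_decay,
    )
    shuffle_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 41)))
    history: list[dict] = []
    best_ap, best_state, best_epoch = -np.inf, network.get_state(), -1
    for epoch in range(config.epochs):
        perm = shuffle_rng.permutation(fit_idx)
        losses = []
        for start in range(0, len(perm), config.batch_size):
            batch = perm[start : start + config.batch_size]
            z = network.forward(X[batch], training=True)
            loss = _weighted_bce_from_logits(z, y[batch], w[batch])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        p_tune = network.predict_proba(X[tune_idx])
        ap = auprc(p_tune, y[tune_idx])
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "tune_auprc": ap})
        if ap > best_ap:
            best_ap, best_state, best_epoch = ap, network.get_state(), epoch
    network.set_state(best_state)
    return FittedModel(
        network=network,
        model_tag=model_tag,
        history=history,
        tune_patients=list(tune_patients),
        best_epoch=best_epoch,
    )


def train_cnn(
    X: np.ndarray,
    y: np.ndarray,
    patient_ids: np.ndarray,
    train_config: TrainConfig | None = None,
    cnn_config: CnnConfig | None = None,
    tune_patients: list[str] | None = None,
) -> FittedModel:
    """Train the CNN on scaled length-2000 segments with inner 90/10 selection."""
    train_config = train_config or TrainConfig()
    cnn_config = cnn_config or CnnConfig()
    net = CNNModel(cnn_config, seed=train_config.seed, dtype=np.dtype(train_config.dtype).type)
    return _train_network(net, X, y, patient_ids, train_config, "cnn", tune_patients)


def train_rnn(
    X: np.ndarray,
    y: np.ndarray,
    patient_ids: np.ndarray,
    train_config: TrainConfig | None = None,
    rnn_config: RnnConfig | None = None,
    tune_patients: list[str] | None = None,
) -> FittedModel:
    """Train the bidirectional LSTM on (N, 30, 100) beat matrices."""
    train_config = train_config or TrainConfig()
    rnn_config = rnn_config or RnnConfig()
    net = RNNModel(rnn_config, seed=train_config.seed, dtype=np.dtype(train_config.dtype).type)
    return _train_network(net, X, y, patient_ids, train_config, "rnn", tune_patients)


@dataclass
class FittedLogistic:
    model: LogisticRegression
    model_tag: str
    best_c: float
    cv_scores: dict

    def predict(self, X: np.ndarray, ids=None, labels=None) -> PredictionSet:
        X = np.asarray(X, dtype=np.float64)
        probs = self.model.predict_proba(X)[:, 1] if len(X) else np.zeros(0)
        ids = np.arange(len(probs)) if ids is None else ids
        return PredictionSet(ids=ids, probabilities=probs, labels=labels, model_tag=self.model_tag)


def train_logistic(
    X: np.ndarray,
    y: np.ndarray,
    patient_ids: np.ndarray | None = None,
    c_grid: np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
) -> FittedLogistic:
    """L2 logistic regression; C chosen by patient-grouped 5-fold CV AUPRC."""
    from .ensemble import auprc

    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    groups = np.asarray(patient_ids) if patient_ids is not None else np.arange(len(y))
    c_grid = np.logspace(-3, 3, 7) if c_grid is None else np.asarray(c_grid)
    n_folds = min(n_folds, len(set(groups.tolist())))
    cv_scores: dict = {}
    if n_folds >= 2:
        splitter = GroupKFold(n_splits=n_folds)
        for c in c_grid:
            scores = []
            for tr, te in splitter.split(X, y, groups):
                if len(set(y[tr].tolist())) < 2 or len(set(y[te].tolist())) < 2:
                    continue
                clf = LogisticRegression(C=c, max_iter=2000, tol=tol, solver="lbfgs")
                clf.fit(X[tr], y[tr])
                scores.append(auprc(clf.predict_proba(X[te])[:, 1], y[te]))
            cv_scores[float(c)] = float(np.mean(scores)) if scores else -np.inf
        best_c = float(max(cv_scores, key=lambda c: (cv_scores[c], -c)))
    else:
        best_c = 1.0
    final = LogisticRegression(C=best_c, max_iter=5000, tol=tol, solver="lbfgs")
    final.fit(X, y)
    return FittedLogistic(model=final, model_tag="logistic", best_c=best_c, cv_scores=cv_scores)


def predict(model, inputs: np.ndarray, ids=None, labels=None) -> PredictionSet:
    """Apply a fitted model (network or logistic wrapper) to new inputs."""
    return model.predict(inputs, ids=ids, labels=labels)
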