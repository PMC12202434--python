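"""The forecasters and their training protocol.

Four architectures, all sequence-to-sequence over a 96-sample (24 h) input
window with two channels (normalized glucose and its first difference):

``naive``
    Training-free persistence baseline: output the last observed value(s).
``lstm``
    One LSTM cell with N memory units (N = window length) followed by a
    dense layer of size h.
``stacked_lstm``
    Five LSTM layers in an encoder scheme of N, N/2, N/2, N/4, N/4 units
    with 0.05 dropout, then a dense layer of size h.
``dil_unet``
    A four-stage 1-D encoder–decoder with skip connections: filters start at
    4x the number of input features (8), double per encoding stage, two
    bottleneck convolutions at 128 filters, a mirrored decoder, dropout 0.1,
    dilation rate 1, and a final dense layer of size h.

Training uses Adam, batch size 1 by default, per-instance glycemic-range
weights, and early stopping after two epochs without a training-loss
improvement of at least 1e-4.  The loss is either the MSE on the normalized
scale or the ISO-adapted loss on the mg/dl scale (the denormalization is an
affine map, applied inside the loss so its gradient flows through).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from glucodiy import nn
from glucodiy.objectives import (
    GlycemicThresholds,
    IsoLossParams,
    iso_gamma,
    iso_gamma_grad,
)
from glucodiy.preprocessing import InstanceSet, NormalizationParams, denormalize

ARCHITECTURES = ("naive", "lstm", "stacked_lstm", "dil_unet")


@dataclass(frozen=True)
class ModelSpec:
    architecture: str = "lstm"
    window_length: int = 96
    n_features: int = 2
    prediction_steps: int = 2

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.architecture == "dil_unet" and self.window_length % 16:
            raise ValueError("dil_unet needs a window length divisible by 16 (4 halvings)")

    @property
    def dropout_rate(self) -> float:
        return {"naive": 0.0, "lstm": 0.0, "stacked_lstm": 0.05, "dil_unet": 0.1}[self.architecture]

    @property
    def base_filters(self) -> int:
        return 4 * self.n_features

    @property
    def dilation_rate(self) -> int:
        return 1


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.001
    batch_size: int = 1
    early_stop_patience: int = 2
    early_stop_min_delta: float = 0.0001
    max_epochs: int = 50
    loss: str = "iso"             # "mse" | "iso"
    monitor: str = "train"        # "train" | "val"
    seed: int = 0
    grad_sample_clip: float = 1e6  # per-sample |dL/dy| bound for the barrier loss

    def __post_init__(self) -> None:
        if self.early_stop_patience < 1 or self.early_stop_min_delta <= 0:
            raise ValueError("patience >= 1 and min_delta > 0 required")
        if self.loss not in ("mse", "iso"):
            raise ValueError("loss must be 'mse' or 'iso'")


@dataclass
class TrainingHistory:
    losses: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    stop_reason: str = ""


class EarlyStopping:
    """Stop after ``patience`` consecutive epochs without improving the best
    loss seen so far by at least ``min_delta``."""

    def __init__(self, patience: int, min_delta: float):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.bad = 0

    def update(self, loss: float) -> bool:
        """Record one epoch's monitored loss; True means stop now."""
        if loss < self.best - self.min_delta:
            self.bad = 0
        else:
            self.bad += 1
        self.best = min(self.best, loss)
        return self.bad >= self.patience


def early_stop_trace(losses, patience: int = 2, min_delta: float = 0.0001) -> tuple[int, str]:
    """Replay the early-stopping rule on a loss trace.

    Returns (stopped_epoch, reason): the 1-based epoch after which training
    stops, and 'early_stop' or 'max_epochs' (the trace exhausted).
    """
    stopper = EarlyStopping(patience, min_delta)
    for e, loss in enumerate(losses, start=1):
        if stopper.update(loss):
            return e, "early_stop"
    return len(losses), "max_epochs"


# ---------------------------------------------------------------------------
# Architectures
# ---------------------------------------------------------------------------


def naive_forecast(window, h: int, mode: str = "hold") -> np.ndarray:
    """Persistence baseline on a 1-D glucose window.

    ``hold``: repeat the last observed value h times.  ``literal``: output
    the final h input values in order (the alternative reading of "the last
    values of the input sequence").
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or w.size < h:
        raise ValueError("window must be 1-D with length >= h")
    if mode == "hold":
        return np.full(h, w[-1])
    if mode == "literal":
        return w[-h:].copy()
    raise ValueError(f"unknown naive mode {mode!r}")


class NaiveModel:
    """Training-free baseline; predicts on the normalized glucose channel."""

    def __init__(self, spec: ModelSpec, mode: str = "hold"):
        self.spec = spec
        self.mode = mode

    def params(self):
        return []

    def forward(self, x, train=False):
        B, N, _ = x.shape
        return np.stack([naive_forecast(x[b, :, 0], self.spec.prediction_steps, self.mode)
                         for b in range(B)])


class LSTMForecaster(nn.Sequential):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        N = spec.window_length
        super().__init__(
            nn.LSTM(spec.n_features, N, rng, return_sequences=False),
            nn.Dense(N, spec.prediction_steps, rng),
        )
        self.spec = spec


class StackedLSTMForecaster(nn.Sequential):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        N = spec.window_length
        units = [N, N // 2, N // 2, N // 4, N // 4]
        layers: list[nn.Layer] = []
        c_in = spec.n_features
        for j, u in enumerate(units):
            last = j == len(units) - 1
            layers.append(nn.LSTM(c_in, u, rng, return_sequences=not last))
            layers.append(nn.Dropout(spec.dropout_rate, rng))
            c_in = u
        layers.append(nn.Dense(units[-1], spec.prediction_steps, rng))
        super().__init__(*layers)
        self.spec = spec


class DilUNet:
    """Four-stage 1-D encoder–decoder with skip connections.

    Encoder: conv(3, dilation 1) + ReLU + dropout, then stride-2 max-pooling,
    with filters 8, 16, 32, 64.  Bottleneck: two convolutions at 128.
    Decoder: nearest-neighbour upsampling + conv halving the filters, skip
    concatenation with the matching encoder feature map, and a merge conv.
    Head: flatten + dense to h outputs.
    """

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        self.spec = spec
        f = spec.base_filters
        d = spec.dilation_rate
        enc_ch = [f, 2 * f, 4 * f, 8 * f]          # 8, 16, 32, 64
        bott = 16 * f                               # 128
        c_in = spec.n_features
        self.enc_conv, self.enc_act, self.enc_drop, self.enc_pool = [], [], [], []
        for c in enc_ch:
            self.enc_conv.append(nn.Conv1D(c_in, c, rng, kernel=3, dilation=d))
            self.enc_act.append(nn.ReLU())
            self.enc_drop.append(nn.Dropout(spec.dropout_rate, rng))
            self.enc_pool.append(nn.MaxPool1D(2))
            c_in = c
        self.bott = nn.Sequential(
            nn.Conv1D(enc_ch[-1], bott, rng, kernel=3, dilation=d), nn.ReLU(),
            nn.Conv1D(bott, bott, rng, kernel=3, dilation=d), nn.ReLU(),
            nn.Dropout(spec.dropout_rate, rng),
        )
        self.dec_up, self.dec_conv, self.dec_act = [], [], []
        self.dec_merge, self.dec_merge_act = [], []
        c_in = bott
        for c in reversed(enc_ch):
            self.dec_up.append(nn.Upsample1D(2))
            self.dec_conv.append(nn.Conv1D(c_in, c, rng, kernel=3, dilation=d))
            self.dec_act.append(nn.ReLU())
            self.dec_merge.append(nn.Conv1D(2 * c, c, rng, kernel=3, dilation=d))
            self.dec_merge_act.append(nn.ReLU())
            c_in = c
        self.flatten = nn.Flatten()
        self.head = nn.Dense(spec.window_length * enc_ch[0], spec.prediction_steps, rng)

    def params(self):
        ps = []
        for conv in self.enc_conv:
            ps += conv.params()
        ps += self.bott.params()
        for conv, merge in zip(self.dec_conv, self.dec_merge):
            ps += conv.params() + merge.params()
        ps += self.head.params()
        return ps

    def forward(self, x, train=False):
        skips = []
        for conv, act, drop, pool in zip(self.enc_conv, self.enc_act, self.enc_drop, self.enc_pool):
            x = drop.forward(act.forward(conv.forward(x, train), train), train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bott.forward(x, train)
        self._skip_ch = []
        for up, conv, act, merge, mact, skip in zip(
                self.dec_up, self.dec_conv, self.dec_act,
                self.dec_merge, self.dec_merge_act, reversed(skips)):
            x = act.forward(conv.forward(up.forward(x, train), train), train)
            self._skip_ch.append(x.shape[2])
            x = np.concatenate([x, skip], axis=2)
            x = mact.forward(merge.forward(x, train), train)
        return self.head.forward(self.flatten.forward(x, train), train)

    def backward(self, grad):
        grad = self.flatten.backward(self.head.backward(grad))
        skip_grads = []
        for up, conv, act, merge, mact, ch in zip(
                reversed(self.dec_up), reversed(self.dec_conv), reversed(self.dec_act),
                reversed(self.dec_merge), reversed(self.dec_merge_act),
                reversed(self._skip_ch)):
            grad = merge.backward(mact.backward(grad))
            skip_grads.append(grad[:, :, ch:])
            grad = up.backward(conv.backward(act.backward(grad[:, :, :ch])))
        grad = self.bott.backward(grad)
        # skip_grads are in outermost-first order; encoder backward runs innermost-first
        for conv, act, drop, pool, sg in zip(
                reversed(self.enc_conv), reversed(self.enc_act),
                reversed(self.enc_drop), reversed(self.enc_pool),
                reversed(skip_grads)):
            grad = pool.backward(grad) + sg
            grad = conv.backward(act.backward(drop.backward(grad)))
        return grad


def build_model(spec: ModelSpec, seed: int = 0):
    """Instantiate an untrained forecaster with seeded weight initialization."""
    rng = np.random.default_rng(seed)
    if spec.architecture == "naive":
        return NaiveModel(spec)
    if spec.architecture == "lstm":
        return LSTMForecaster(spec, rng)
    if spec.architecture == "stacked_lstm":
        return StackedLSTMForecaster(spec, rng)
    return DilUNet(spec, rng)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    spec: ModelSpec
    model: object
    norm: Optional[NormalizationParams]
    history: TrainingHistory
    provenance: dict = field(default_factory=dict)


def _loss_and_grad(y_pred_n, y_true_n, w, norm: NormalizationParams, config: TrainingConfig,
                   iso_params: IsoLossParams):
    """Weighted loss and dL/dy_pred (normalized scale) for one batch."""
    B, h = y_pred_n.shape
    wcol = w[:, None]
    if config.loss == "mse":
        diff = y_pred_n - y_true_n
        loss = float(np.sum(wcol * diff ** 2) / (B * h))
        grad = 2.0 * wcol * diff / (B * h)
        return loss, grad
    s = norm.s_max - norm.s_min
    pred = y_pred_n * s + norm.s_min
    ref = np.maximum(y_true_n * s + norm.s_min, 1.0)
    err = pred - ref
    low = ref < iso_params.low_ref_bound
    scale = np.where(low, 1.0, 100.0 / ref)
    eps = err * scale
    gamma = iso_gamma(eps, iso_params)
    loss = float(np.sum(wcol * (eps ** 2 + gamma)) / (B * h))
    deps = 2.0 * eps + iso_gamma_grad(eps, iso_params)
    grad_pred = wcol * deps * scale / (B * h)
    grad_pred = np.clip(grad_pred, -config.grad_sample_clip, config.grad_sample_clip)
    return loss, grad_pred * s


def train(model, instances: InstanceSet, weights: Optional[np.ndarray] = None,
          config: TrainingConfig | None = None,
          iso_params: IsoLossParams | None = None,
          thresholds: GlycemicThresholds | None = None) -> TrainedModel:
    """Train a forecaster with per-instance weights and early stopping.

    ``instances`` must carry normalization params (from preprocessing); the
    instance order is taken as given (folds are shuffled upstream).  With
    ``weights=None`` all instances weigh 1.
    """
    config = config or TrainingConfig()
    iso_params = iso_params or IsoLossParams()
    if len(instances) == 0:
        raise ValueError("empty training set")
    if instances.norm is None:
        raise ValueError("instances must carry normalization parameters")
    X, Y, norm = instances.X, instances.Y, instances.norm
    if weights is None:
        weights = np.ones(len(instances))
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != len(instances):
        raise ValueError("weights must align with instances")

    if isinstance(model, NaiveModel):
        return TrainedModel(model.spec, model, norm, TrainingHistory([], 0, "untrained"),
                            provenance={"loss": None, "seed": None})

    opt = nn.Adam(model.params(), lr=config.learning_rate)
    stopper = EarlyStopping(config.early_stop_patience, config.early_stop_min_delta)
    history = TrainingHistory()
    n = X.shape[0]
    bs = config.batch_size
    stop_reason = "max_epochs"
    for epoch in range(1, config.max_epochs + 1):
        total, total_w = 0.0, 0
        for start in range(0, n, bs):
            xb = X[start:start + bs]
            yb = Y[start:start + bs]
            wb = weights[start:start + bs]
            opt.zero_grad()
            pred = model.forward(xb, train=True)
            loss, grad = _loss_and_grad(pred, yb, wb, norm, config, iso_params)
            model.backward(grad)
            opt.step()
            total += loss * xb.shape[0]
            total_w += xb.shape[0]
        epoch_loss = total / total_w
        history.losses.append(epoch_loss)
        history.stopped_epoch = epoch
        if stopper.update(epoch_loss):
            stop_reason = "early_stop"
            break
    history.stop_reason = stop_reason
    return TrainedModel(model.spec, model, norm, history,
                        provenance={"loss": config.loss, "seed": config.seed,
                                    "ph_minutes": model.spec.prediction_steps * 15})


def predict_window(trained: TrainedModel, window: np.ndarray) -> np.ndarray:
    """Predict h future values in mg/dl from one normalized N x 2 window."""
    x = np.asarray(window, dtype=float)
    if x.ndim == 2:
        x = x[None, ...]
    spec = trained.spec
    if x.shape[1:] != (spec.window_length, spec.n_features):
        raise ValueError(f"window must be (N, {spec.n_features}) = "
                         f"({spec.window_length}, {spec.n_features}), got {x.shape[1:]}")
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite values")
    out_n = trained.model.forward(x, train=False)
    out = denormalize(out_n, trained.norm)
    return out[0] if out.shape[0] == 1 else out


def predict_batch(trained: TrainedModel, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Predictions in mg/dl for an (n, N, 2) array of normalized windows."""
    outs = []
    for start in range(0, X.shape[0], batch_size):
        outs.append(trained.model.forward(X[start:start + batch_size], train=False))
    return denormalize(np.concatenate(outs, axis=0), trained.norm)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_model(trained: TrainedModel, directory: str | Path) -> Path:
    """Persist a trained model: a weights archive plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    params = trained.model.params()
    np.savez(directory / "weights.npz", **{f"p{i}": p.value for i, p in enumerate(params)})
    manifest = {
        "spec": asdict(trained.spec),
        "norm": {"s_min": trained.norm.s_min, "s_max": trained.norm.s_max} if trained.norm else None,
        "history": {"losses": trained.history.losses,
                    "stopped_epoch": trained.history.stopped_epoch,
                    "stop_reason": trained.history.stop_reason},
        "provenance": trained.provenance,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


def load_model(directory: str | Path) -> TrainedModel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    spec = ModelSpec(**manifest["spec"])
    model = build_model(spec, seed=0)
    with np.load(directory / "weights.npz") as archive:
        for i, p in enumerate(model.params()):
            p.value[...] = archive[f"p{i}"]
    norm = None
    if manifest["norm"]:
        norm = NormalizationParams(**manifest["norm"])
    hist = TrainingHistory(**manifest["history"])
    return TrainedModel(spec, model, norm, hist, manifest.get("provenance", {}))
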