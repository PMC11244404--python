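"""EEGNet and recurrent classifiers for the RH/ND decision.

EEGNet here is the compact convolutional stack of the driver-state
pipeline: a temporal convolution (1 -> 16 maps, kernel (1, 51), padding
(0, 25), so the time axis is preserved), batch norm, a depthwise
convolution (16 -> 32, kernel (1, 10), groups = 16, valid mode), batch
norm + ELU, average pooling (1, 4), then a pointwise 1x1 convolution with
batch norm + ELU, flatten, dropout and a dense 2-class head. For an
8 x 400-sample epoch the time axis evolves 400 -> 400 -> 391 -> 97, a shape
contract derivable from the configuration alone (see
:func:`eegnet_time_dims`).

The RNN and LSTM baselines are two-layer recurrent networks with input
size 1000 and hidden size 128. An 8 x 400 epoch does not factor into
1000-wide steps, so each time step consumes a channel-concatenated 100-
sample window (8 x 100 = 800 features) zero-padded to width 1000 — four
steps per epoch; the final hidden state feeds a dense 2-class head.

Training minimizes class-weighted softmax cross-entropy with Adam, early
stopping on validation accuracy. The positive class RH has index 0; exact
score ties resolve to ND.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from . import io as _io
from . import nn
from .errors import ConfigError, NumericalError, ValidationError
from .features import EpochSet, compute_psd
from .recording import CLASSES

RH, ND = 0, 1  # class indices; RH (road hypnosis) is the positive class


# ---------------------------------------------------------------------------
# configurations


@dataclass(frozen=True)
class EEGNetConfig:
    n_channels: int = 8
    n_samples: int = 400
    conv1_out: int = 16
    conv1_kernel: int = 51
    conv1_pad: int = 25
    depth_multiplier: int = 2  # 16 -> 32
    dw_kernel: int = 10
    pool: int = 4
    pointwise_out: int = 32
    dropout: float = 0.25
    n_classes: int = 2
    activation: str = "elu"
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1

    def __post_init__(self) -> None:
        if self.conv1_pad * 2 + 1 != self.conv1_kernel:
            raise ConfigError(
                "block-1 padding must preserve the time length "
                f"(kernel {self.conv1_kernel} needs pad {(self.conv1_kernel - 1) // 2})"
            )
        if self.depth_multiplier < 1:
            raise ConfigError("depth multiplier must be >= 1")

    @property
    def dw_out(self) -> int:
        return self.conv1_out * self.depth_multiplier


def eegnet_time_dims(config: EEGNetConfig, t_in: int | None = None) -> list[int]:
    """Time-axis lengths after block 1, depthwise block, and pooling."""
    t = config.n_samples if t_in is None else t_in
    t1 = t + 2 * config.conv1_pad - config.conv1_kernel + 1  # == t
    t2 = t1 - config.dw_kernel + 1
    t3 = t2 // config.pool
    return [t, t1, t2, t3]


@dataclass(frozen=True)
class RecurrentConfig:
    cell: str = "rnn"  # rnn | lstm
    num_layers: int = 2
    input_size: int = 1000
    hidden_size: int = 128
    n_classes: int = 2
    window: int = 100  # samples of each channel per sequence step

    def __post_init__(self) -> None:
        if self.cell not in ("rnn", "lstm"):
            raise ConfigError(f"unknown cell {self.cell!r}")
        if min(self.num_layers, self.input_size, self.hidden_size) < 1:
            raise ConfigError("recurrent sizes must be positive")


# ---------------------------------------------------------------------------
# model builders


def _activation(name: str) -> nn.Layer:
    if name == "elu":
        return nn.ELU()
    if name == "relu":
        return nn.ReLU()
    raise ConfigError(f"unknown activation {name!r}")


def build_eegnet(config: EEGNetConfig, seed: int = 0, dtype=None) -> nn.Sequential:
    rng = np.random.default_rng(seed)
    t3 = eegnet_time_dims(config)[-1]
    flat = config.pointwise_out * config.n_channels * t3
    conv1 = nn.TemporalConv2d(
        1, config.conv1_out, config.conv1_kernel, config.conv1_pad, rng, dtype
    )
    conv1.is_first = True
    return nn.Sequential(
        [
            conv1,
            nn.BatchNorm(config.conv1_out, config.bn_eps, config.bn_momentum, dtype),
            nn.DepthwiseTemporalConv2d(config.conv1_out, config.depth_multiplier, config.dw_kernel, rng, dtype),
            nn.BatchNorm(config.dw_out, config.bn_eps, config.bn_momentum, dtype),
            _activation(config.activation),
            nn.AvgPoolTime(config.pool),
            nn.TemporalConv2d(config.dw_out, config.pointwise_out, 1, 0, rng, dtype),
            nn.BatchNorm(config.pointwise_out, config.bn_eps, config.bn_momentum, dtype),
            _activation(config.activation),
            nn.Flatten(),
            nn.Dropout(config.dropout, rng),
            nn.Dense(flat, config.n_classes, rng, dtype),
        ]
    )


class RecurrentNet(nn.Layer):
    """Stacked vanilla-RNN or LSTM with a dense head, manual BPTT."""

    def __init__(self, config: RecurrentConfig, seed: int = 0, dtype=None):
        self.config = config
        rng = np.random.default_rng(seed)
        H = config.hidden_size
        gate = 4 * H if config.cell == "lstm" else H
        self.Wih, self.Whh, self.bias = [], [], []
        for layer in range(config.num_layers):
            d_in = config.input_size if layer == 0 else H
            s = 1.0 / np.sqrt(H)
            self.Wih.append(nn.Param(rng.uniform(-s, s, (gate, d_in)), f"Wih{layer}", dtype))
            self.Whh.append(nn.Param(rng.uniform(-s, s, (gate, H)), f"Whh{layer}", dtype))
            self.bias.append(nn.Param(np.zeros(gate), f"b{layer}", dtype))
        self.head = nn.Dense(H, config.n_classes, rng, dtype)

    def params(self):
        out = []
        for w_ih, w_hh, b in zip(self.Wih, self.Whh, self.bias):
            out += [w_ih, w_hh, b]
        return out + self.head.params()

    def forward(self, x, train):
        n, T, d = x.shape
        if T == 0:
            raise ValidationError("sequence length must be >= 1")
        if d != self.config.input_size:
            raise ValidationError(
                f"input size {d} != configured {self.config.input_size}"
            )
        cfg = self.config
        H = cfg.hidden_size
        self._caches = []
        for layer in range(cfg.num_layers):
            w_ih, w_hh, b = self.Wih[layer], self.Whh[layer], self.bias[layer]
            h = np.zeros((n, H))
            c = np.zeros((n, H))
            hs, cache_t = [], []
            for t in range(T):
                z = x[:, t] @ w_ih.value.T + h @ w_hh.value.T + b.value
                if cfg.cell == "rnn":
                    h_new = np.tanh(z)
                    cache_t.append((x[:, t], h, h_new))
                    h = h_new
                else:
                    i, f, g_, o = np.split(np.clip(z, -60.0, 60.0), 4, axis=1)
                    i, f, o = 1 / (1 + np.exp(-i)), 1 / (1 + np.exp(-f)), 1 / (1 + np.exp(-o))
                    g_ = np.tanh(g_)
                    c_new = f * c + i * g_
                    tc = np.tanh(c_new)
                    h_new = o * tc
                    cache_t.append((x[:, t], h, c, i, f, g_, o, c_new, tc))
                    h, c = h_new, c_new
                hs.append(h)
            self._caches.append(cache_t)
            x = np.stack(hs, axis=1)  # input to next layer
        self._top = x
        return self.head.forward(x[:, -1], train)

    def backward(self, g):
        cfg = self.config
        n, T, H = self._top.shape
        g_top = np.zeros((n, T, H))
        g_top[:, -1] = self.head.backward(g)
        for layer in reversed(range(cfg.num_layers)):
            w_ih, w_hh, b = self.Wih[layer], self.Whh[layer], self.bias[layer]
            cache_t = self._caches[layer]
            d_in = w_ih.value.shape[1]
            gx = np.zeros((n, T, d_in))
            dh_next = np.zeros((n, H))
            dc_next = np.zeros((n, H))
            for t in reversed(range(T)):
                dh = g_top[:, t] + dh_next
                if cfg.cell == "rnn":
                    x_t, h_prev, h_t = cache_t[t]
                    dz = dh * (1 - h_t**2)
                else:
                    x_t, h_prev, c_prev, i, f, g_, o, c_new, tc = cache_t[t]
                    do = dh * tc
                    dc = dh * o * (1 - tc**2) + dc_next
                    di = dc * g_
                    df = dc * c_prev
                    dg = dc * i
                    dz = np.concatenate(
                        [
                            di * i * (1 - i),
                            df * f * (1 - f),
                            dg * (1 - g_**2),
                            do * o * (1 - o),
                        ],
                        axis=1,
                    )
                    dc_next = dc * f
                w_ih.grad += dz.T @ x_t
                w_hh.grad += dz.T @ h_prev
                b.grad += dz.sum(axis=0)
                dh_next = dz @ w_hh.value
                gx[:, t] = dz @ w_ih.value
            g_top = gx  # becomes the hidden-grad of the layer below
        return g_top


# ---------------------------------------------------------------------------
# input representations


def epochs_to_time_batch(data: np.ndarray) -> np.ndarray:
    """(n, channels, samples) -> (n, 1, channels, samples)."""
    return np.asarray(data, dtype=float)[:, None, :, :]


def epochs_to_seq_batch(data: np.ndarray, config: RecurrentConfig) -> np.ndarray:
    """Chunk epochs into channel-concatenated windows, pad to input_size.

    (n, c, t) -> (n, ceil(t / window), input_size) where each step holds the
    c * window samples of that window (zero-padded / truncated to
    ``input_size``).
    """
    data = np.asarray(data, dtype=float)
    n, c, t = data.shape
    w = config.window
    n_steps = int(np.ceil(t / w))
    padded = np.zeros((n, c, n_steps * w))
    padded[:, :, :t] = data
    steps = padded.reshape(n, c, n_steps, w).transpose(0, 2, 1, 3).reshape(
        n, n_steps, c * w
    )
    out = np.zeros((n, n_steps, config.input_size))
    keep = min(c * w, config.input_size)
    out[:, :, :keep] = steps[:, :, :keep]
    return out


def epochs_to_psd_batch(epochs: EpochSet) -> np.ndarray:
    """Log-PSD maps, (n, 1, channels, bins) — the spectral representation."""
    psd = compute_psd(epochs)
    return np.log10(psd.values + 1e-12)[:, None, :, :]


# ---------------------------------------------------------------------------
# functional op wrappers


def eegnet_forward(batch: np.ndarray, model: nn.Sequential, mode: str = "eval") -> np.ndarray:
    """Class scores for a (n, 1, channels, samples) batch."""
    if mode not in ("train", "eval"):
        raise ConfigError(f"mode must be train or eval, got {mode!r}")
    return model.forward(np.asarray(batch, dtype=float), train=mode == "train")


def recurrent_forward(batch: np.ndarray, model: RecurrentNet, mode: str = "eval") -> np.ndarray:
    """Class scores for a (n, seq, input_size) batch."""
    return model.forward(np.asarray(batch, dtype=float), train=mode == "train")


@dataclass
class BatchNormParams:
    gamma: np.ndarray
    beta: np.ndarray
    eps: float = 1e-5
    momentum: float = 0.1
    running_mean: np.ndarray | None = None
    running_var: np.ndarray | None = None


def batch_norm(x: np.ndarray, params: BatchNormParams, mode: str = "train") -> np.ndarray:
    """Standalone batch normalization over (batch, features)."""
    layer = nn.BatchNorm(len(np.atleast_1d(params.gamma)), params.eps, params.momentum)
    layer.gamma.value = np.atleast_1d(np.asarray(params.gamma, dtype=float))
    layer.beta.value = np.atleast_1d(np.asarray(params.beta, dtype=float))
    if params.running_mean is not None:
        layer.running_mean = np.asarray(params.running_mean, dtype=float)
    if params.running_var is not None:
        layer.running_var = np.asarray(params.running_var, dtype=float)
    out = layer.forward(np.asarray(x, dtype=float), train=mode == "train")
    params.running_mean = layer.running_mean
    params.running_var = layer.running_var
    return out


# ---------------------------------------------------------------------------
# dataset splitting


def split_dataset(
    labels: np.ndarray,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    stratify: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hold-out split into train/validation/test index arrays.

    Counts use largest-remainder rounding so the three splits partition the
    index set exactly and hit the stated proportions as closely as integer
    counts allow (100 samples at 60/20/20 gives exactly 60/20/20). With
    ``stratify`` the allocation is done per class.
    """
    ratios = tuple(float(r) for r in ratios)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigError(f"split ratios must sum to 1, got {ratios}")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)

    def allocate(n: int) -> list[int]:
        exact = [r * n for r in ratios]
        counts = [int(np.floor(e)) for e in exact]
        rem = n - sum(counts)
        order = np.argsort([c - e for c, e in zip(counts, exact)])
        for i in range(rem):
            counts[order[i]] += 1
        return counts

    groups = (
        [np.flatnonzero(labels == cls) for cls in np.unique(labels)]
        if stratify
        else [np.arange(labels.size)]
    )
    parts: list[list[np.ndarray]] = [[], [], []]
    for idx in groups:
        if stratify and idx.size < 5:
            raise ValidationError(
                f"stratified split needs >=5 samples per class, got {idx.size}"
            )
        perm = rng.permutation(idx)
        n_tr, n_va, n_te = allocate(idx.size)
        parts[0].append(perm[:n_tr])
        parts[1].append(perm[n_tr : n_tr + n_va])
        parts[2].append(perm[n_tr + n_va :])
    return tuple(np.sort(np.concatenate(p)) for p in parts)


# ---------------------------------------------------------------------------
# training


@dataclass
class Hyperparams:
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 40
    patience: int = 8
    class_weighting: bool = True
    clip_norm: float = 5.0  # global gradient-norm clip (stabilizes the RNN)


@dataclass
class TrainedModel:
    kind: str  # eegnet | rnn | lstm
    config: object
    model: nn.Layer
    norm_mean: np.ndarray
    norm_sd: np.ndarray
    history: list = field(default_factory=list)
    seed: int = 0
    representation: str = "time"


def encode_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype="U2")
    bad = set(labels) - set(CLASSES)
    if bad:
        raise ValidationError(f"unknown labels {sorted(bad)}")
    return np.where(labels == "RH", RH, ND)


def _make_batch(kind: str, data: np.ndarray, config) -> np.ndarray:
    if kind == "eegnet":
        return epochs_to_time_batch(data)
    return epochs_to_seq_batch(data, config)


def _accuracy(model, kind, X, y, batch_size=256) -> float:
    correct = 0
    for lo in range(0, X.shape[0], batch_size):
        logits = model.forward(X[lo : lo + batch_size], train=False)
        pred = np.where(logits[:, RH] > logits[:, ND], RH, ND)
        correct += int(np.sum(pred == y[lo : lo + batch_size]))
    return correct / X.shape[0]


def train_model(
    kind: str,
    train_data: np.ndarray,
    train_labels: np.ndarray,
    val_data: np.ndarray,
    val_labels: np.ndarray,
    config=None,
    hyper: Hyperparams | None = None,
    seed: int = 0,
    representation: str = "time",
) -> TrainedModel:
    """Train one classifier on (n, channels, samples) epoch arrays.

    Epochs are standardized per channel with training-set statistics (the
    statistics travel with the model). Training stops early when validation
    accuracy has not improved for ``patience`` epochs and the best-epoch
    weights are restored.
    """
    if kind not in ("eegnet", "rnn", "lstm"):
        raise ConfigError(f"unknown model kind {kind!r}")
    if train_data.shape[0] == 0:
        raise ValidationError("training set is empty")
    hyper = hyper or Hyperparams()
    if config is None:
        config = (
            EEGNetConfig(
                n_channels=train_data.shape[1], n_samples=train_data.shape[2]
            )
            if kind == "eegnet"
            else RecurrentConfig(cell=kind)
        )
    y_tr = encode_labels(train_labels)
    y_va = encode_labels(val_labels)

    mean = train_data.mean(axis=(0, 2), keepdims=True)
    sd = train_data.std(axis=(0, 2), keepdims=True)
    sd[sd == 0] = 1.0
    X_tr = _make_batch(kind, (train_data - mean) / sd, config).astype(np.float32)
    X_va = _make_batch(kind, (val_data - mean) / sd, config).astype(np.float32)

    model = (
        build_eegnet(config, seed=seed, dtype=np.float32)
        if kind == "eegnet"
        else RecurrentNet(config, seed=seed, dtype=np.float32)
    )
    class_weights = None
    if hyper.class_weighting:
        counts = np.bincount(y_tr, minlength=2).astype(float)
        counts[counts == 0] = 1.0
        class_weights = counts.sum() / (2.0 * counts)

    opt = nn.Adam(model.params(), lr=hyper.lr)
    rng = np.random.default_rng(seed + 1)
    n = X_tr.shape[0]
    history: list[dict] = []
    best_acc, best_weights, since_best = -1.0, None, 0

    for epoch in range(1, hyper.max_epochs + 1):
        perm = rng.permutation(n)
        losses = []
        for lo in range(0, n, hyper.batch_size):
            idx = perm[lo : lo + hyper.batch_size]
            if idx.size < 2:
                continue  # batch norm needs >= 2 samples
            opt.zero_grad()
            logits = model.forward(X_tr[idx], train=True)
            loss, grad = nn.cross_entropy(logits, y_tr[idx], class_weights)
            if not np.isfinite(loss):
                raise NumericalError(
                    f"{kind} training diverged at epoch {epoch} (loss={loss})"
                )
            model.backward(grad)
            if hyper.clip_norm:
                gnorm = np.sqrt(sum(float((p.grad**2).sum()) for p in model.params()))
                if gnorm > hyper.clip_norm:
                    for p in model.params():
                        p.grad *= hyper.clip_norm / gnorm
            opt.step()
            losses.append(loss)
        val_acc = _accuracy(model, kind, X_va, y_va)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_acc": val_acc}
        )
        if val_acc > best_acc:
            best_acc, since_best = val_acc, 0
            best_weights = nn.get_weights(model)
        else:
            since_best += 1
            if since_best >= hyper.patience:
                break
    if best_weights is not None:
        nn.set_weights(model, best_weights)

    return TrainedModel(
        kind=kind,
        config=config,
        model=model,
        norm_mean=mean,
        norm_sd=sd,
        history=history,
        seed=seed,
        representation=representation,
    )


def predict(trained: TrainedModel, data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted RH/ND labels and softmax scores for (n, c, t) epochs.

    Exact score ties resolve to ND (the negative class).
    """
    data = np.asarray(data, dtype=float)
    X = _make_batch(
        trained.kind, (data - trained.norm_mean) / trained.norm_sd, trained.config
    ).astype(np.float32)
    scores = []
    for lo in range(0, X.shape[0], 256):
        logits = trained.model.forward(X[lo : lo + 256], train=False)
        scores.append(nn.softmax(logits))
    scores = np.concatenate(scores, axis=0)
    pred_idx = np.where(scores[:, RH] > scores[:, ND], RH, ND)
    labels = np.asarray(CLASSES, dtype="U2")[pred_idx]
    return labels, scores


# ---------------------------------------------------------------------------
# checkpointing


def save_model(trained: TrainedModel, path) -> None:
    """Serialize a trained classifier (weights + config + normalization)."""
    weights = nn.get_weights(trained.model)
    arrays = {f"w{i}": w for i, w in enumerate(weights)}
    arrays["norm_mean"] = trained.norm_mean
    arrays["norm_sd"] = trained.norm_sd
    _io.save_array_group(
        path,
        arrays,
        {
            "kind": trained.kind,
            "config": asdict(trained.config),
            "representation": trained.representation,
            "seed": trained.seed,
            "history": trained.history,
            "n_weights": len(weights),
        },
    )


def load_model(path) -> TrainedModel:
    arrays, attrs = _io.load_array_group(path)
    kind = attrs["kind"]
    dtype = np.float32
    if kind == "eegnet":
        config = EEGNetConfig(**attrs["config"])
        model = build_eegnet(config, seed=attrs["seed"], dtype=dtype)
    else:
        config = RecurrentConfig(**attrs["config"])
        model = RecurrentNet(config, seed=attrs["seed"], dtype=dtype)
    weights = [arrays[f"w{i}"] for i in range(attrs["n_weights"])]
    nn.set_weights(model, weights)
    return TrainedModel(
        kind=kind,
        config=config,
        model=model,
        norm_mean=arrays["norm_mean"],
        norm_sd=arrays["norm_sd"],
        history=attrs["history"],
        seed=attrs["seed"],
        representation=attrs["representation"],
    )
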