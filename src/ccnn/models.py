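"""Neural network classifiers for connectome matrices.

Three architectures, all trained with softmax cross-entropy:

* ``ccnn`` — the connectome-convolutional network. The input is a
  C x N x N stack of connectivity matrices (one channel per metric).
  The first convolutional layer slides 64 filters of shape C x 1 x N
  along the rows: each filter produces one scalar per ROI by weighting
  that ROI's whole connectivity fingerprint across all channels, and
  the weights are shared across ROIs. The second layer applies 128
  filters of shape 64 x N x 1 across the resulting 64 x N feature map,
  collapsing it to a 128-vector, followed by a 96-unit dense layer
  (ReLU, dropout) and a 2-way softmax. Because the per-fingerprint
  weights are shared, adding a channel grows the model by only C*N*64
  weights (<1% at N=499).

* ``simple`` — flattened upper-triangle features -> 128 sigmoid units
  -> softmax; trained with plain SGD.

* ``deep`` — flattened features -> 128 ReLU -> 96 ReLU (dropout) ->
  softmax; trained like the CCNN (Adam, dropout) so that the
  convolutional weight sharing is the main difference between the two.

The forward/backward passes are written directly in NumPy: the row/
column "fingerprint" convolutions reduce to dense matrix products, so
nothing beyond BLAS is needed, and training stays bit-reproducible for
a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import ConnectomeDataset

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "build",
    "count_trainable_weights",
    "flatten_features",
    "train",
    "predict_proba",
]

_KINDS = ("ccnn", "simple", "deep")


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    ``optimizer`` and ``learning_rate`` default per kind when left as
    None: Adam at 1e-3 for ``ccnn``/``deep``, SGD at 0.05 for
    ``simple``. ``keep_prob`` is the dropout keeping probability
    applied after the 96-unit dense layer (ccnn/deep only).
    """

    kind: str
    n_rois: int
    n_channels: int = 1
    conv1_filters: int = 64
    conv2_filters: int = 128
    hidden_units: int = 128
    dense_units: int = 96
    n_classes: int = 2
    keep_prob: float = 0.6
    optimizer: str | None = None
    learning_rate: float | None = None
    epochs: int = 100
    batch_size: int = 16
    seed: int = 0
    standardize: bool = True
    early_stop_patience: int = 20
    early_stop_min_delta: float = 1e-4

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.n_rois < 2:
            raise ValueError("n_rois must be >= 2")
        for name in ("n_channels", "conv1_filters", "conv2_filters",
                     "hidden_units", "dense_units", "n_classes",
                     "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.keep_prob <= 1:
            raise ValueError("keep_prob must be in (0, 1]")
        if self.optimizer is None:
            self.optimizer = "sgd" if self.kind == "simple" else "adam"
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")
        if self.learning_rate is None:
            self.learning_rate = 0.05 if self.optimizer == "sgd" else 1e-3

    @property
    def n_features(self) -> int:
        """Flattened feature count C*N*(N-1)/2 used by the dense nets."""
        return self.n_channels * self.n_rois * (self.n_rois - 1) // 2


@dataclass
class TrainedModel:
    """A (possibly still untrained) model: config, parameters, log."""

    config: ModelConfig
    weights: dict = field(default_factory=dict)
    biases: dict = field(default_factory=dict)
    channel_mean: np.ndarray | None = None
    channel_std: np.ndarray | None = None
    training_log: list = field(default_factory=list)
    trained: bool = False

    def parameter_counts(self) -> tuple[int, int]:
        """(n_weights, n_biases) actually held in the arrays."""
        nw = int(sum(w.size for w in self.weights.values()))
        nb = int(sum(b.size for b in self.biases.values()))
        return nw, nb


def count_trainable_weights(config: ModelConfig) -> tuple[int, int]:
    """Closed-form (weights, biases) count for an architecture.

    ccnn: C*N*f1 + N*f1*f2 + f2*d + d*k weights, f1+f2+d+k biases;
    simple: F*h + h*k weights, h+k biases;
    deep: F*h + h*d + d*k weights, h+d+k biases; F = C*N(N-1)/2.
    """
    n, c = config.n_rois, config.n_channels
    f1, f2 = config.conv1_filters, config.conv2_filters
    h, d, k = config.hidden_units, config.dense_units, config.n_classes
    if config.kind == "ccnn":
        weights = c * n * f1 + n * f1 * f2 + f2 * d + d * k
        biases = f1 + f2 + d + k
    elif config.kind == "simple":
        weights = config.n_features * h + h * k
        biases = h + k
    else:  # deep
        weights = config.n_features * h + h * d + d * k
        biases = h + d + k
    return weights, biases


def _truncated_normal(rng: np.random.Generator, shape, std: float) -> np.ndarray:
    """Normal(0, std) truncated at two standard deviations."""
    out = rng.standard_normal(shape)
    for _ in range(10):
        mask = np.abs(out) > 2.0
        if not mask.any():
            break
        out[mask] = rng.standard_normal(int(mask.sum()))
    return np.clip(out, -2.0, 2.0) * std


def build(config: ModelConfig) -> TrainedModel:
    """Initialize a model with seeded truncated-normal weights.

    Weight std scales as 1/sqrt(fan-in); biases start at zero.
    """
    rng = np.random.default_rng(config.seed)
    n, c = config.n_rois, config.n_channels
    f1, f2 = config.conv1_filters, config.conv2_filters
    h, d, k = config.hidden_units, config.dense_units, config.n_classes
    weights: dict[str, np.ndarray] = {}
    biases: dict[str, np.ndarray] = {}

    def layer(name: str, shape, fan_in: int, n_out: int) -> None:
        weights[name] = _truncated_normal(rng, shape, 1.0 / np.sqrt(fan_in))
        biases[name] = np.zeros(n_out)

    if config.kind == "ccnn":
        layer("conv1", (f1, c, n), c * n, f1)          # filter spans C channels x 1 row x N cols
        layer("conv2", (f2, n, f1), n * f1, f2)        # filter spans the 64 x N feature map
        layer("dense", (f2, d), f2, d)
        layer("out", (d, k), d, k)
    elif config.kind == "simple":
        layer("hidden", (config.n_features, h), config.n_features, h)
        layer("out", (h, k), h, k)
    else:
        layer("hidden", (config.n_features, h), config.n_features, h)
        layer("dense", (h, d), h, d)
        layer("out", (d, k), d, k)

    model = TrainedModel(config=config, weights=weights, biases=biases)
    expected = count_trainable_weights(config)
    actual = model.parameter_counts()
    if expected != actual:
        raise AssertionError(f"parameter bookkeeping mismatch: {actual} != {expected}")
    return model


def flatten_features(dataset: ConnectomeDataset, tol: float = 1e-6) -> np.ndarray:
    """Vectorize each instance: strict upper triangle per channel.

    Row-major upper-triangle order within a channel, channels
    concatenated; yields F = C*N(N-1)/2 features per instance (the
    independent pairwise connectivity values of symmetric matrices).
    """
    data = dataset.data
    asym = np.abs(data - np.swapaxes(data, -1, -2)).max(initial=0.0)
    if asym > tol:
        raise ValueError(f"asymmetric matrix slice (max deviation {asym:.3g})")
    n = dataset.n_rois
    iu, ju = np.triu_indices(n, k=1)
    feats = data[:, :, iu, ju]  # (instances, channels, N(N-1)/2)
    return feats.reshape(dataset.n_instances, -1)


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def conv1_forward(x: np.ndarray, w1: np.ndarray, b1: np.ndarray) -> np.ndarray:
    """First fingerprint convolution: (B,C,N,N) -> (B,N,f1) pre-activation.

    out[b, r, f] = sum_{c,j} w1[f, c, j] * x[b, c, r, j] + b1[f]; one
    scalar per ROI per filter, with the filter shared across all rows.
    """
    b, c, n, _ = x.shape
    f1 = w1.shape[0]
    xr = x.transpose(0, 2, 1, 3).reshape(b, n, c * n)
    return xr @ w1.reshape(f1, c * n).T + b1


def _ccnn_forward(model: TrainedModel, x: np.ndarray, dropout_rng=None):
    cfg = model.config
    w, bias = model.weights, model.biases
    bsz, _, n, _ = x.shape
    z1 = conv1_forward(x, w["conv1"], bias["conv1"])          # (B, N, f1)
    a1 = np.maximum(z1, 0.0)
    z2 = a1.reshape(bsz, -1) @ w["conv2"].reshape(cfg.conv2_filters, -1).T + bias["conv2"]
    a2 = np.maximum(z2, 0.0)                                   # (B, f2)
    z3 = a2 @ w["dense"] + bias["dense"]
    a3 = np.maximum(z3, 0.0)                                   # (B, d)
    if dropout_rng is not None and cfg.keep_prob < 1.0:
        mask = (dropout_rng.random(a3.shape) < cfg.keep_prob) / cfg.keep_prob
    else:
        mask = np.ones_like(a3)
    a3d = a3 * mask
    logits = a3d @ w["out"] + bias["out"]
    probs = _softmax(logits)
    cache = (x, z1, a1, z2, a2, z3, a3, mask, a3d, probs)
    return probs, cache


def _ccnn_backward(model: TrainedModel, cache, y_onehot: np.ndarray) -> dict:
    cfg = model.config
    w = model.weights
    x, z1, a1, z2, a2, z3, a3, mask, a3d, probs = cache
    bsz, c = x.shape[0], cfg.n_channels
    n, f1, f2 = cfg.n_rois, cfg.conv1_filters, cfg.conv2_filters
    dlogits = (probs - y_onehot) / bsz
    grads = {"w_out": a3d.T @ dlogits, "b_out": dlogits.sum(axis=0)}
    da3 = (dlogits @ w["out"].T) * mask
    dz3 = da3 * (z3 > 0)
    grads["w_dense"] = a2.T @ dz3
    grads["b_dense"] = dz3.sum(axis=0)
    da2 = dz3 @ w["dense"].T
    dz2 = da2 * (z2 > 0)
    grads["w_conv2"] = (dz2.T @ a1.reshape(bsz, -1)).reshape(f2, n, f1)
    grads["b_conv2"] = dz2.sum(axis=0)
    da1 = (dz2 @ w["conv2"].reshape(f2, -1)).reshape(bsz, n, f1)
    dz1 = da1 * (z1 > 0)
    xr = x.transpose(0, 2, 1, 3).reshape(bsz * n, c * n)
    grads["w_conv1"] = (dz1.reshape(bsz * n, f1).T @ xr).reshape(f1, c, n)
    grads["b_conv1"] = dz1.sum(axis=(0, 1))
    return grads


def _dense_forward(model: TrainedModel, feats: np.ndarray, dropout_rng=None):
    cfg = model.config
    w, bias = model.weights, model.biases
    zh = feats @ w["hidden"] + bias["hidden"]
    if cfg.kind == "simple":
        ah = 1.0 / (1.0 + np.exp(-zh))
        logits = ah @ w["out"] + bias["out"]
        probs = _softmax(logits)
        return probs, (feats, zh, ah, None, None, None, None, probs)
    ah = np.maximum(zh, 0.0)
    zd = ah @ w["dense"] + bias["dense"]
    ad = np.maximum(zd, 0.0)
    if dropout_rng is not None and cfg.keep_prob < 1.0:
        mask = (dropout_rng.random(ad.shape) < cfg.keep_prob) / cfg.keep_prob
    else:
        mask = np.ones_like(ad)
    add = ad * mask
    logits = add @ w["out"] + bias["out"]
    probs = _softmax(logits)
    return probs, (feats, zh, ah, zd, ad, mask, add, probs)


def _dense_backward(model: TrainedModel, cache, y_onehot: np.ndarray) -> dict:
    cfg = model.config
    w = model.weights
    feats, zh, ah, zd, ad, mask, add, probs = cache
    bsz = feats.shape[0]
    dlogits = (probs - y_onehot) / bsz
    grads: dict[str, np.ndarray] = {}
    if cfg.kind == "simple":
        grads["w_out"] = ah.T @ dlogits
        grads["b_out"] = dlogits.sum(axis=0)
        dah = dlogits @ w["out"].T
        dzh = dah * ah * (1.0 - ah)
    else:
        grads["w_out"] = add.T @ dlogits
        grads["b_out"] = dlogits.sum(axis=0)
        dad = (dlogits @ w["out"].T) * mask
        dzd = dad * (zd > 0)
        grads["w_dense"] = ah.T @ dzd
        grads["b_dense"] = dzd.sum(axis=0)
        dah = dzd @ w["dense"].T
        dzh = dah * (zh > 0)
    grads["w_hidden"] = feats.T @ dzh
    grads["b_hidden"] = dzh.sum(axis=0)
    return grads


class _Adam:
    def __init__(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for key, g in grads.items():
            m = self.m.setdefault(key, np.zeros_like(g))
            v = self.v.setdefault(key, np.zeros_like(g))
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, lr: float):
        self.lr = lr

    def step(self, params: dict, grads: dict) -> None:
        for key, g in grads.items():
            params[key] -= self.lr * g


def _standardize_stats(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/std over all training matrix entries."""
    mean = data.mean(axis=(0, 2, 3))
    std = data.std(axis=(0, 2, 3))
    std = np.where(std == 0, 1.0, std)
    return mean, std


def _model_input(model: TrainedModel, dataset: ConnectomeDataset, indices) -> np.ndarray:
    cfg = model.config
    data = dataset.data[np.asarray(indices, dtype=int)]
    if data.shape[1] != cfg.n_channels or data.shape[2] != cfg.n_rois:
        raise ValueError(
            f"dataset shape {data.shape[1:]} incompatible with model config "
            f"(C={cfg.n_channels}, N={cfg.n_rois})"
        )
    if cfg.standardize and model.channel_mean is not None:
        data = (data - model.channel_mean[None, :, None, None]) / \
            model.channel_std[None, :, None, None]
    if cfg.kind == "ccnn":
        return data
    sub = ConnectomeDataset(
        data=data, labels=np.zeros(len(data), dtype=int),
        group_ids=list(range(len(data))), channel_names=dataset.channel_names,
    )
    return flatten_features(sub)


def train(model: TrainedModel, dataset: ConnectomeDataset, train_indices) -> TrainedModel:
    """Train in place on the given instances; returns the model.

    Minimizes softmax cross-entropy with minibatches; dropout is active
    only here. Per-channel standardization statistics are computed on
    the training instances only and stored with the model, so held-out
    data is scaled by training statistics at prediction time. Stops
    early when the epoch loss has not improved by more than
    ``early_stop_min_delta`` for ``early_stop_patience`` epochs.
    Deterministic given ``config.seed``.
    """
    cfg = model.config
    train_indices = np.asarray(train_indices, dtype=int)
    if train_indices.size == 0:
        raise ValueError("train_indices is empty")
    y = dataset.labels[train_indices]
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"training set contains a single class ({classes.tolist()})")

    if cfg.standardize:
        mean, std = _standardize_stats(dataset.data[train_indices])
        model.channel_mean, model.channel_std = mean, std
    else:
        model.channel_mean = model.channel_std = None

    x_all = _model_input(model, dataset, train_indices)
    y_onehot = np.eye(cfg.n_classes)[y]

    rng = np.random.default_rng(cfg.seed + 1)
    opt = _Adam(cfg.learning_rate) if cfg.optimizer == "adam" else _SGD(cfg.learning_rate)
    params = {}
    for name in model.weights:
        params[f"w_{name}"] = model.weights[name]
    for name in model.biases:
        params[f"b_{name}"] = model.biases[name]

    n_train = train_indices.size
    best_loss = np.inf
    stale = 0
    model.training_log = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n_train)
        epoch_loss = 0.0
        for start in range(0, n_train, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x_all[idx], y_onehot[idx]
            if cfg.kind == "ccnn":
                probs, cache = _ccnn_forward(model, xb, dropout_rng=rng)
                grads = _ccnn_backward(model, cache, yb)
            else:
                probs, cache = _dense_forward(model, xb, dropout_rng=rng)
                grads = _dense_backward(model, cache, yb)
            epoch_loss += -np.sum(yb * np.log(probs + 1e-12))
            opt.step(params, grads)
        epoch_loss /= n_train
        model.training_log.append(float(epoch_loss))
        if epoch_loss < best_loss - cfg.early_stop_min_delta:
            best_loss = epoch_loss
            stale = 0
        else:
            stale += 1
            if stale >= cfg.early_stop_patience:
                break
    model.trained = True
    return model


def predict_proba(model: TrainedModel, dataset: ConnectomeDataset, indices) -> np.ndarray:
    """Class probabilities for the given instances (dropout disabled)."""
    if not model.trained:
        raise ValueError("model is not trained")
    x = _model_input(model, dataset, indices)
    if model.config.kind == "ccnn":
        probs, _ = _ccnn_forward(model, x, dropout_rng=None)
    else:
        probs, _ = _dense_forward(model, x, dropout_rng=None)
    return probs
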