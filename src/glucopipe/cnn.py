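"""A 2-D CNN glucose-concentration classifier, implemented in numpy.

Architecture (16-way classification of 100 x 100 grayscale well images)::

    input -> [conv -> ReLU -> batchnorm] x 2
          -> (optional channel-wise softmax normalization stage)
          -> flatten -> dense (+ dropout) -> dense(16) -> softmax

The channel-wise softmax between the convolutional stack and the dense head
rescales the feature maps so that, at every spatial location, channel
activations form a probability vector; it is on by default and can be
disabled (the small desk-scale profile disables it).

Training uses mini-batch Adam on the cross-entropy loss.  All convolution
arithmetic is im2col + matrix multiplication; backpropagation is written
out layer by layer.  Every source of randomness (weight init, shuffling,
dropout, splits, folds) is derived from explicit integer seeds, so a run is
bit-reproducible.

Four conditioning measures make short training schedules work on the
near-duplicate images this assay produces (every capture is the same well
scene; the between-class signal is a small intensity shift): inputs are
centered by the training set's mean image, the learning rate follows a
warmup + cosine-decay schedule, gradients are clipped by global norm, and
after the last epoch the batch-norm running statistics are recalibrated
with one exact pass over the training set.  Without centering, the shared
background pattern dominates every activation and most dense rectifier
units die within the first epoch.

The trainable-parameter count has a closed form,

    sum over conv layers of (kh*kw*c_in + 1)*c_out
  + sum over batchnorm layers of 2*c
  + sum over dense layers of (n_in + 1)*n_out,

exposed as :func:`parameter_count`; a built model independently reports the
total size of its allocated parameter arrays, and the two must agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from glucopipe.synthetic_imaging import CONCENTRATIONS, ConcentrationClass

# ---------------------------------------------------------------------------
# dataset container


@dataclass
class LabeledImages:
    """A stack of same-size grayscale images with integer class labels.

    ``labels`` are class indices into ``class_values`` (mg/dL).
    """

    images: np.ndarray  # (N, H, W) uint8
    labels: np.ndarray  # (N,) int
    class_values: tuple[int, ...] = CONCENTRATIONS

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.images.ndim != 3:
            raise ValueError("images must be a (N, H, W) stack")
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels length mismatch")
        if len(self.labels) and (
            self.labels.min() < 0 or self.labels.max() >= len(self.class_values)
        ):
            raise ValueError("label index outside the configured class set")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray | Sequence[int]) -> "LabeledImages":
        idx = np.asarray(idx)
        return LabeledImages(self.images[idx], self.labels[idx], self.class_values)


# ---------------------------------------------------------------------------
# specs and configs


@dataclass(frozen=True)
class ConvBlockSpec:
    """One conv -> ReLU -> batchnorm block."""

    filters: int
    kernel_size: int = 3
    stride: int = 1
    padding: str = "same"

    def __post_init__(self) -> None:
        if self.filters <= 0 or self.kernel_size <= 0 or self.stride <= 0:
            raise ValueError("filters, kernel_size and stride must be positive")
        if self.padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")


@dataclass(frozen=True)
class CNNSpec:
    """Hyperparameters of the classifier network.

    The default profile takes 100 x 100 inputs through 16- and 32-filter
    3 x 3 blocks into a 256-unit dense layer; its closed-form trainable
    count exceeds 75 million (the flatten edge dominates).  ``small()``
    is a desk-scale profile (~270 k parameters, 32 x 32 inputs, strided
    convs, normalization stage off) for fast experiments and tests.
    """

    input_size: tuple[int, int, int] = (100, 100, 1)
    conv_blocks: tuple[ConvBlockSpec, ...] = (
        ConvBlockSpec(16, 3, 1),
        ConvBlockSpec(32, 3, 1),
    )
    inter_block_normalization: bool = True
    dense_units: tuple[int, ...] = (256,)
    dropout_rate: float = 0.5
    class_count: int = 16

    def __post_init__(self) -> None:
        if self.class_count <= 0:
            raise ValueError("class_count must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if len(self.conv_blocks) == 0:
            raise ValueError("at least one conv block is required")

    @classmethod
    def small(cls, input_side: int = 32) -> "CNNSpec":
        return cls(
            input_size=(input_side, input_side, 1),
            conv_blocks=(ConvBlockSpec(16, 3, 2), ConvBlockSpec(32, 3, 2)),
            inter_block_normalization=False,
            dense_units=(128,),
            dropout_rate=0.0,
        )


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization and data-partition settings."""

    epochs: int = 35
    train_fraction: float = 0.8
    folds: int = 10
    seed: int = 0
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    grad_clip: float | None = 1.0  # global gradient-norm ceiling
    warmup_steps: int = 20  # linear learning-rate warmup
    lr_schedule: str = "cosine"  # 'cosine' or 'constant'
    restarts: int = 1  # independent inits; keep lowest final training loss

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


# ---------------------------------------------------------------------------
# layers


def _same_padding(in_size: int, k: int, stride: int) -> tuple[int, int, int]:
    """(out_size, pad_begin, pad_end) for 'same' convolution."""
    out = -(-in_size // stride)  # ceil
    pad_total = max((out - 1) * stride + k - in_size, 0)
    return out, pad_total // 2, pad_total - pad_total // 2


class Conv2D:
    """2-D convolution, im2col implementation, float32 parameters."""

    def __init__(self, cin: int, cout: int, k: int, stride: int, padding: str, rng):
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = (rng.standard_normal((cout, cin, k, k)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k, self.stride, self.padding = k, stride, padding
        self.params = {"W": self.W, "b": self.b}
        self.grads: dict[str, np.ndarray] = {}

    def _geometry(self, h: int, w: int) -> tuple[int, int, tuple, tuple]:
        if self.padding == "same":
            ho, pt, pb = _same_padding(h, self.k, self.stride)
            wo, pl, pr = _same_padding(w, self.k, self.stride)
        else:
            ho = (h - self.k) // self.stride + 1
            wo = (w - self.k) // self.stride + 1
            pt = pb = pl = pr = 0
        return ho, wo, (pt, pb), (pl, pr)

    def _im2col(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        n, c, _, _ = xp.shape
        k, s = self.k, self.stride
        cols = np.empty((n, c, k, k, ho, wo), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i : i + ho * s : s, j : j + wo * s : s]
        return cols.reshape(n, c * k * k, ho * wo)

    def forward(self, x: np.ndarray, training: bool, rng) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo, (pt, pb), (pl, pr) = self._geometry(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        cols = self._im2col(xp, ho, wo)
        out = self.W.reshape(self.W.shape[0], -1) @ cols  # (n, cout, ho*wo)
        out = out + self.b[:, None]
        self._cache = (x.shape, xp.shape, cols, (ho, wo), (pt, pl))
        return out.reshape(n, -1, ho, wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, xp_shape, cols, (ho, wo), (pt, pl) = self._cache
        n = x_shape[0]
        cout = self.W.shape[0]
        d = dout.reshape(n, cout, ho * wo)
        self.grads["W"] = (
            np.einsum("ncl,nkl->ck", d, cols).reshape(self.W.shape).astype(np.float32)
        )
        self.grads["b"] = d.sum(axis=(0, 2)).astype(np.float32)
        dcols = np.einsum("ck,ncl->nkl", self.W.reshape(cout, -1), d)
        # col2im scatter-add
        k, s = self.k, self.stride
        c = x_shape[1]
        dxp = np.zeros(xp_shape, dtype=np.float32)
        dcols = dcols.reshape(n, c, k, k, ho, wo)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + ho * s : s, j : j + wo * s : s] += dcols[:, :, i, j]
        h, w = x_shape[2], x_shape[3]
        return dxp[:, :, pt : pt + h, pl : pl + w]


class ReLU:
    """Rectifier f(x) = max(0, x)."""

    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, training: bool, rng) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class BatchNorm2D:
    """Per-channel batch normalization with running inference statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": self.gamma, "beta": self.beta}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool, rng) -> np.ndarray:
        axes = (0, 2, 3)
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None]) / std[:, None, None]
        self._cache = (xhat, std, x.shape)
        return self.gamma[:, None, None] * xhat + self.beta[:, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std, shape = self._cache
        axes = (0, 2, 3)
        m = shape[0] * shape[2] * shape[3]
        self.grads["gamma"] = (dout * xhat).sum(axis=axes).astype(np.float32)
        self.grads["beta"] = dout.sum(axis=axes).astype(np.float32)
        dxhat = dout * self.gamma[:, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=axes)[:, None, None]
            - xhat * (dxhat * xhat).mean(axis=axes)[:, None, None]
        ) / std[:, None, None]
        return dx


class ChannelSoftmax:
    """Normalized-exponential stage across channels at each spatial location."""

    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, training: bool, rng) -> np.ndarray:
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=1, keepdims=True)
        return self._p

    def backward(self, dout: np.ndarray) -> np.ndarray:
        p = self._p
        return p * (dout - (dout * p).sum(axis=1, keepdims=True))


class Flatten:
    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, training: bool, rng) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense:
    def __init__(self, nin: int, nout: int, rng):
        scale = np.sqrt(2.0 / nin)
        self.W = (rng.standard_normal((nin, nout)) * scale).astype(np.float32)
        self.b = np.zeros(nout, dtype=np.float32)
        self.params = {"W": self.W, "b": self.b}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool, rng) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = (self._x.T @ dout).astype(np.float32)
        self.grads["b"] = dout.sum(axis=0).astype(np.float32)
        return dout @ self.W.T


class Dropout:
    """Inverted dropout; identity at inference."""

    params: dict = {}
    grads: dict = {}

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x: np.ndarray, training: bool, rng) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# model


@dataclass
class LossHistory:
    """Per-epoch training and validation cross-entropy."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)


class TrainedModel:
    """A (possibly untrained) CNN with its spec and class mapping."""

    def __init__(self, spec: CNNSpec, seed: int = 0, class_values: Sequence[int] = CONCENTRATIONS):
        if len(class_values) != spec.class_count:
            raise ValueError("class mapping length must equal spec.class_count")
        self.spec = spec
        self.class_values = tuple(int(v) for v in class_values)
        # centering offset subtracted from 8-bit inputs; train_model replaces
        # the scalar default with the training set's mean image
        self.input_mean: np.ndarray | float = np.float32(127.5)
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0FFEE)))
        h, w, cin = spec.input_size
        layers: list = []
        c = cin
        for block in spec.conv_blocks:
            layers.append(Conv2D(c, block.filters, block.kernel_size, block.stride, block.padding, rng))
            layers.append(ReLU())
            layers.append(BatchNorm2D(block.filters))
            c = block.filters
            if block.padding == "same":
                h = -(-h // block.stride)
                w = -(-w // block.stride)
            else:
                h = (h - block.kernel_size) // block.stride + 1
                w = (w - block.kernel_size) // block.stride + 1
        if spec.inter_block_normalization:
            layers.append(ChannelSoftmax())
        layers.append(Flatten())
        n = h * w * c
        for units in spec.dense_units:
            layers.append(Dense(n, units, rng))
            layers.append(ReLU())
            if spec.dropout_rate > 0:
                layers.append(Dropout(spec.dropout_rate))
            n = units
        layers.append(Dense(n, spec.class_count, rng))
        self.layers = layers

    @property
    def trainable_parameter_count(self) -> int:
        """Total size of the allocated parameter arrays."""
        return int(sum(p.size for layer in self.layers for p in layer.params.values()))

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        """Logits for a (N, 1, H, W) float batch."""
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Class probabilities for a (N, H, W) uint8/float stack."""
        x = _as_batch(images, self.spec.input_size, self.input_mean)
        return softmax(self.forward(x, training=False))


def _as_batch(
    images: np.ndarray,
    input_size: tuple[int, int, int],
    input_mean: np.ndarray | float = np.float32(127.5),
) -> np.ndarray:
    """Center 8-bit images and scale them to the network input range.

    Centering matters: with raw [0, 1] inputs the shared bright-background
    pattern dominates every activation and gradient, and the few-percent
    between-class intensity differences take far longer to resolve.
    """
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    h, w, cin = input_size
    if x.shape[1:] != (h, w):
        raise ValueError(f"expected {h}x{w} inputs, got {x.shape[1:]}")
    return ((x - input_mean) / 255.0)[:, None, :, :]


def parameter_count(spec: CNNSpec) -> int:
    """Closed-form trainable-parameter count of a spec.

    Conv: (kh*kw*c_in + 1)*c_out;  batchnorm: 2*c;  dense: (n_in + 1)*n_out.
    """
    h, w, c = spec.input_size
    total = 0
    for block in spec.conv_blocks:
        k = block.kernel_size
        total += (k * k * c + 1) * block.filters + 2 * block.filters
        c = block.filters
        if block.padding == "same":
            h = -(-h // block.stride)
            w = -(-w // block.stride)
        else:
            h = (h - k) // block.stride + 1
            w = (w - k) // block.stride + 1
    n = h * w * c
    for units in spec.dense_units:
        total += (n + 1) * units
        n = units
    total += (n + 1) * spec.class_count
    return total


def build_model(
    spec: CNNSpec, seed: int = 0, class_values: Sequence[int] = CONCENTRATIONS
) -> TrainedModel:
    """Instantiate an untrained model from a spec (seeded initialization)."""
    return TrainedModel(spec, seed=seed, class_values=class_values)


# ---------------------------------------------------------------------------
# data partitioning


def split_dataset(
    dataset: LabeledImages, config: TrainingConfig
) -> tuple[LabeledImages, LabeledImages]:
    """Stratified, seeded train/test split at ``config.train_fraction``."""
    counts = np.bincount(dataset.labels, minlength=len(dataset.class_values))
    present = counts[np.unique(dataset.labels)]
    if len(dataset) == 0 or (present < 2).any():
        raise ValueError("every class present must have at least 2 items to stratify")
    idx = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=config.train_fraction,
        stratify=dataset.labels,
        random_state=config.seed,
        shuffle=True,
    )
    return dataset.subset(np.sort(train_idx)), dataset.subset(np.sort(test_idx))


# ---------------------------------------------------------------------------
# training, prediction, cross-validation


def _epoch_loss(model: TrainedModel, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    """Mean cross-entropy in inference mode."""
    total = 0.0
    for s in range(0, len(y), batch):
        logits = model.forward(x[s : s + batch], training=False)
        p = softmax(logits)
        total += -np.log(np.clip(p[np.arange(len(p)), y[s : s + batch]], 1e-12, None)).sum()
    return float(total / len(y))


def train_model(
    model: TrainedModel,
    train_set: LabeledImages,
    val_set: LabeledImages,
    config: TrainingConfig,
) -> tuple[TrainedModel, LossHistory]:
    """Mini-batch Adam training; returns the model and per-epoch loss curves.

    With ``config.restarts > 1`` the optimization is run from several
    seeded initializations and the run with the lowest final training loss
    is kept — multi-start selection on the training objective only, the
    same guard against bad basins that clustering tools apply.  The history
    holds exactly ``config.epochs`` entries per curve.  A non-finite loss
    aborts with a diagnostic rather than silently diverging.
    """
    if config.restarts > 1:
        best: tuple[TrainedModel, LossHistory] | None = None
        for r in range(config.restarts):
            run_seed = int(
                np.random.SeedSequence((config.seed, 0x5A, r)).generate_state(1)[0]
                & 0x7FFFFFFF
            )
            candidate = TrainedModel(model.spec, seed=run_seed, class_values=model.class_values)
            cfg_r = replace(config, seed=run_seed, restarts=1)
            candidate, hist = train_model(candidate, train_set, val_set, cfg_r)
            if best is None or hist.train_loss[-1] < best[1].train_loss[-1]:
                best = (candidate, hist)
        model.layers = best[0].layers
        model.input_mean = best[0].input_mean
        return model, best[1]
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    if config.optimizer_name != "adam":
        raise ValueError(f"unsupported optimizer {config.optimizer_name!r}")
    if config.lr_schedule not in ("cosine", "constant"):
        raise ValueError(f"unknown lr_schedule {config.lr_schedule!r}")
    model.input_mean = train_set.images.astype(np.float32).mean(axis=0)
    xtr = _as_batch(train_set.images, model.spec.input_size, model.input_mean)
    xva = _as_batch(val_set.images, model.spec.input_size, model.input_mean)
    ytr, yva = train_set.labels, val_set.labels

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x7EA)))
    params = [
        (layer, name) for layer in model.layers for name in layer.params
    ]
    m1 = [np.zeros_like(layer.params[n]) for layer, n in params]
    m2 = [np.zeros_like(layer.params[n]) for layer, n in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    steps_per_epoch = -(-len(ytr) // config.batch_size)
    total_steps = config.epochs * steps_per_epoch
    history = LossHistory()
    for epoch in range(config.epochs):
        order = rng.permutation(len(ytr))
        running, seen = 0.0, 0
        for s in range(0, len(order), config.batch_size):
            sel = order[s : s + config.batch_size]
            xb, yb = xtr[sel], ytr[sel]
            logits = model.forward(xb, training=True, rng=rng)
            p = softmax(logits)
            loss = -np.log(np.clip(p[np.arange(len(yb)), yb], 1e-12, None)).mean()
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch + 1}"
                )
            running += float(loss) * len(yb)
            seen += len(yb)
            dlogits = p.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            model.backward(dlogits / len(yb))
            t += 1
            warm = min(1.0, t / config.warmup_steps) if config.warmup_steps else 1.0
            decay = (
                0.5 * (1.0 + np.cos(np.pi * t / total_steps))
                if config.lr_schedule == "cosine"
                else 1.0
            )
            lr_t = (
                config.learning_rate
                * warm
                * decay
                * np.sqrt(1 - beta2**t)
                / (1 - beta1**t)
            )
            scale = 1.0
            if config.grad_clip is not None:
                gnorm = np.sqrt(
                    sum(float((layer.grads[n] ** 2).sum()) for layer, n in params)
                )
                scale = min(1.0, config.grad_clip / max(gnorm, 1e-12))
            for i, (layer, name) in enumerate(params):
                g = layer.grads[name] * scale
                m1[i] = beta1 * m1[i] + (1 - beta1) * g
                m2[i] = beta2 * m2[i] + (1 - beta2) * g * g
                layer.params[name] -= lr_t * m1[i] / (np.sqrt(m2[i]) + eps)
        history.train_loss.append(running / seen)
        history.val_loss.append(_epoch_loss(model, xva, yva, config.batch_size))
    _recalibrate_batchnorm(model, xtr)
    return model, history


def _recalibrate_batchnorm(model: TrainedModel, x: np.ndarray) -> None:
    """Replace batch-norm running statistics with exact training-set moments.

    The momentum-averaged running statistics lag behind the weights on
    short schedules; one full forward pass pins them to the statistics the
    trained network actually produces.
    """
    for layer in model.layers:
        if isinstance(layer, BatchNorm2D):
            layer.running_mean[...] = x.mean(axis=(0, 2, 3))
            layer.running_var[...] = x.var(axis=(0, 2, 3))
        x = layer.forward(x, False, None)


def save_model(model: TrainedModel, model_dir) -> None:
    """Persist spec (YAML), weights (npz) and class mapping (CSV)."""
    import dataclasses
    from pathlib import Path

    import pandas as pd
    import yaml

    model_dir = Path(model_dir)
    model_dir.mkdir(parents=True, exist_ok=True)
    with open(model_dir / "spec.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(model.spec), fh)
    arrays: dict[str, np.ndarray] = {"input_mean": np.asarray(model.input_mean)}
    for i, layer in enumerate(model.layers):
        for name, arr in layer.params.items():
            arrays[f"layer{i}.{name}"] = arr
        if isinstance(layer, BatchNorm2D):
            arrays[f"layer{i}.running_mean"] = layer.running_mean
            arrays[f"layer{i}.running_var"] = layer.running_var
    np.savez(model_dir / "weights.npz", **arrays)
    pd.DataFrame(
        {"index": range(len(model.class_values)), "concentration": model.class_values}
    ).to_csv(model_dir / "classes.csv", index=False)


def load_model(model_dir) -> TrainedModel:
    """Rebuild a model saved by :func:`save_model`."""
    from pathlib import Path

    import pandas as pd
    import yaml

    model_dir = Path(model_dir)
    with open(model_dir / "spec.yaml") as fh:
        raw = yaml.safe_load(fh)
    raw["input_size"] = tuple(raw["input_size"])
    raw["conv_blocks"] = tuple(ConvBlockSpec(**b) for b in raw["conv_blocks"])
    raw["dense_units"] = tuple(raw["dense_units"])
    spec = CNNSpec(**raw)
    classes = pd.read_csv(model_dir / "classes.csv")["concentration"].tolist()
    model = TrainedModel(spec, seed=0, class_values=classes)
    with np.load(model_dir / "weights.npz") as arrays:
        mean = arrays["input_mean"]
        model.input_mean = np.float32(mean) if mean.ndim == 0 else mean.astype(np.float32)
        for i, layer in enumerate(model.layers):
            for name in layer.params:
                layer.params[name][...] = arrays[f"layer{i}.{name}"]
            if isinstance(layer, BatchNorm2D):
                layer.running_mean[...] = arrays[f"layer{i}.running_mean"]
                layer.running_var[...] = arrays[f"layer{i}.running_var"]
    return model


def predict(
    model: TrainedModel, img: np.ndarray
) -> tuple[np.ndarray, ConcentrationClass]:
    """Class probabilities and argmax concentration for one processed image.

    Inference is deterministic (dropout disabled, running batch-norm
    statistics); argmax ties break toward the lowest class index.
    """
    probs = model.predict_proba(img)[0]
    idx = int(np.argmax(probs))
    return probs, ConcentrationClass(model.class_values[idx])


def predict_labels(model: TrainedModel, images: np.ndarray, batch: int = 64) -> np.ndarray:
    """Argmax class indices for an image stack (batched inference)."""
    out = []
    for s in range(0, len(images), batch):
        out.append(np.argmax(model.predict_proba(images[s : s + batch]), axis=1))
    return np.concatenate(out) if out else np.empty(0, dtype=int)


def cross_validate(
    dataset: LabeledImages,
    spec: CNNSpec,
    config: TrainingConfig,
) -> tuple[np.ndarray, list[dict]]:
    """Stratified k-fold cross-validation pooling one confusion matrix.

    Each item is predicted exactly once, by the model trained on the folds
    excluding it.  Returns the pooled (class_count x class_count) confusion
    matrix and per-fold summaries (fold, test size, accuracy, final losses).
    """
    k = config.folds
    class_sizes = np.bincount(dataset.labels, minlength=spec.class_count)
    smallest = class_sizes[class_sizes > 0].min()
    if k > smallest:
        raise ValueError(f"folds={k} exceeds the smallest class size {smallest}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    pooled = np.zeros((spec.class_count, spec.class_count), dtype=int)
    fold_reports: list[dict] = []
    for fold, (tr, te) in enumerate(skf.split(dataset.images, dataset.labels)):
        fold_seed = int(
            np.random.SeedSequence((config.seed, fold)).generate_state(1)[0] & 0x7FFFFFFF
        )
        model = build_model(spec, seed=fold_seed, class_values=dataset.class_values)
        fold_cfg = replace(config, seed=fold_seed)
        model, history = train_model(
            model, dataset.subset(tr), dataset.subset(te), fold_cfg
        )
        pred = predict_labels(model, dataset.images[te])
        true = dataset.labels[te]
        np.add.at(pooled, (true, pred), 1)
        fold_reports.append(
            {
                "fold": fold,
                "n_test": int(len(te)),
                "accuracy": float((pred == true).mean()),
                "final_train_loss": history.train_loss[-1],
                "final_val_loss": history.val_loss[-1],
            }
        )
    return pooled, fold_reports
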