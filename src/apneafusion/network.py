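"""The residual CNN classifier: declaration, forward/backward, training.

The default architecture is a stem convolution (3x3, 32 filters) followed
by four residual blocks with 32, 64, 96 and 128 filters. Each block runs
two 3x3 convolutions on the main path, a 1x1 convolution on the skip path
(to match channel width), adds the two, applies ReLU and a 2x2 max pool.
A 0.1 dropout, a 256-unit dense layer with ReLU, a final dense layer and
softmax complete the network: 13 convolutions and 4 pooling layers in all.

Everything is evaluated with NumPy/BLAS GEMMs over channels-last tensors;
training uses Adam on the summed cross-entropy of each mini-batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._nnops import maxpool2_bwd, maxpool2_fwd, pack_cols3, unpack_cols3_add

_XENT_EPS = 1e-12


# ---------------------------------------------------------------------------
# declarative specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LayerSpec:
    """One layer in the declarative network description."""

    kind: str  # conv | relu | maxpool | add | dropout | flatten | dense | softmax
    kernel: int | None = None
    stride: int | None = None
    filters: int | None = None
    pool: int | None = None
    rate: float | None = None
    units: int | None = None
    skip: bool = False  # marks the 1x1 skip-path convolution of a residual block


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative description of the residual CNN.

    ``block_filters`` lists the filter count of each residual block;
    ``layers`` expands the structure into an ordered flat layer list.
    """

    input_shape: tuple[int, int, int] = (128, 128, 3)
    num_classes: int = 2
    stem_filters: int = 32
    block_filters: tuple[int, ...] = (32, 64, 96, 128)
    dropout_rate: float = 0.1
    dense_units: int = 256

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        h, w, _ = self.input_shape
        n_blocks = len(self.block_filters)
        if h // 2**n_blocks < 1 or w // 2**n_blocks < 1:
            raise ValueError(
                f"input {h}x{w} collapses to an empty feature map after "
                f"{n_blocks} pooling layers"
            )

    @property
    def layers(self) -> list[LayerSpec]:
        out = [LayerSpec("conv", kernel=3, stride=1, filters=self.stem_filters), LayerSpec("relu")]
        for f in self.block_filters:
            out += [
                LayerSpec("conv", kernel=3, stride=1, filters=f),
                LayerSpec("relu"),
                LayerSpec("conv", kernel=3, stride=1, filters=f),
                LayerSpec("conv", kernel=1, stride=1, filters=f, skip=True),
                LayerSpec("add"),
                LayerSpec("relu"),
                LayerSpec("maxpool", pool=2, stride=2),
            ]
        out += [
            LayerSpec("dropout", rate=self.dropout_rate),
            LayerSpec("flatten"),
            LayerSpec("dense", units=self.dense_units),
            LayerSpec("relu"),
            LayerSpec("dense", units=self.num_classes),
            LayerSpec("softmax"),
        ]
        return out

    def layer_census(self) -> dict[str, int]:
        """Count layers by kind (skip convolutions count as convolutions)."""
        census: dict[str, int] = {}
        for layer in self.layers:
            census[layer.kind] = census.get(layer.kind, 0) + 1
        return census

    @property
    def feature_map_shape(self) -> tuple[int, int, int]:
        """Shape (H, W, C) entering the dropout/flatten stage."""
        h, w, _ = self.input_shape
        for _ in self.block_filters:
            h, w = h // 2, w // 2
        return h, w, self.block_filters[-1]


def build_network(num_classes: int = 2, spec_overrides: dict | None = None) -> NetworkSpec:
    """Return the default network specification (final dense sized ``num_classes``).

    ``spec_overrides`` may replace any :class:`NetworkSpec` field; unknown
    keys raise. Shape incompatibilities (e.g. inputs that collapse before
    the last pool) are rejected at build time.
    """
    overrides = dict(spec_overrides or {})
    unknown = set(overrides) - set(NetworkSpec.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown spec overrides: {sorted(unknown)}")
    return replace(NetworkSpec(num_classes=num_classes), **overrides)


# ---------------------------------------------------------------------------
# numerical ops
# ---------------------------------------------------------------------------


def softmax(activations: np.ndarray) -> np.ndarray:
    """Row-wise softmax, computed shift-invariantly."""
    a = np.asarray(activations, dtype=np.float64)
    if not np.all(np.isfinite(a)):
        raise ValueError("softmax input must be finite")
    a = a - a.max(axis=-1, keepdims=True)
    e = np.exp(a)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(predicted: np.ndarray, targets: np.ndarray) -> float:
    """Summed cross-entropy E = -sum_n sum_k t_nk log y_nk over the mini-batch.

    ``predicted`` rows must sum to 1 (within 1e-6); ``targets`` are one-hot.
    Zero predicted probability at the target class is clamped at 1e-12.
    """
    y = np.atleast_2d(np.asarray(predicted, dtype=np.float64))
    t = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    if y.shape != t.shape:
        raise ValueError("predicted and targets must share shape")
    if not np.allclose(y.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("predicted rows must sum to 1")
    return float(-(t * np.log(np.maximum(y, _XENT_EPS))).sum())


# ---------------------------------------------------------------------------
# executable layers
# ---------------------------------------------------------------------------


class _Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


_SCRATCH: dict[tuple, np.ndarray] = {}


def _get_scratch(shape: tuple, dtype) -> np.ndarray:
    """Shared transient buffer (backward patch-packing). Layers run strictly
    sequentially, so one buffer per shape/dtype can be reused across the
    whole network instead of each convolution caching its own."""
    key = (shape, np.dtype(dtype).str)
    buf = _SCRATCH.get(key)
    if buf is None:
        buf = np.empty(shape, dtype)
        _SCRATCH[key] = buf
    return buf


def clear_workspaces() -> None:
    """Release all cached convolution workspaces."""
    _SCRATCH.clear()


def _he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class _Conv3:
    """3x3 same-padding stride-1 convolution via im2col GEMM.

    ``need_input_grad=False`` (the stem layer) skips the input-gradient
    half of the backward pass.
    """

    def __init__(self, cin, cout, rng, dtype, need_input_grad=True):
        self.cin, self.cout, self.dtype = cin, cout, dtype
        self.need_input_grad = need_input_grad
        self.w = _Param(_he_uniform(rng, (9 * cin, cout), 9 * cin, dtype))
        self.b = _Param(np.zeros(cout, dtype))
        self._cols = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        n, h, w, _ = x.shape
        xp = np.zeros((n, h + 2, w + 2, self.cin), self.dtype)
        xp[:, 1:-1, 1:-1, :] = x
        if self._cols is None or self._cols.shape[:3] != (n, h, w):
            self._cols = np.empty((n, h, w, 9, self.cin), self.dtype)
        pack_cols3(xp, self._cols)
        out = self._cols.reshape(n * h * w, 9 * self.cin) @ self.w.value
        out += self.b.value
        return out.reshape(n, h, w, self.cout)

    def backward(self, dout):
        n, h, w, _ = dout.shape
        dflat = dout.reshape(n * h * w, self.cout)
        cols2 = self._cols.reshape(n * h * w, 9 * self.cin)
        self.w.grad[...] = cols2.T @ dflat
        self.b.grad[...] = dflat.sum(axis=0)
        if not self.need_input_grad:
            return None
        # gradient w.r.t. input: correlate dout with the flipped kernel
        wb = (
            self.w.value.reshape(9, self.cin, self.cout)[::-1]
            .transpose(0, 2, 1)
            .reshape(9 * self.cout, self.cin)
        )
        dop = np.zeros((n, h + 2, w + 2, self.cout), self.dtype)
        dop[:, 1:-1, 1:-1, :] = dout
        dcols = _get_scratch((n, h, w, 9, self.cout), self.dtype)
        pack_cols3(dop, dcols)
        dx = dcols.reshape(n * h * w, 9 * self.cout) @ np.ascontiguousarray(wb)
        return dx.reshape(n, h, w, self.cin)


class _Conv1:
    """1x1 convolution (pure channel mixing)."""

    def __init__(self, cin, cout, rng, dtype):
        self.cin, self.cout = cin, cout
        self.w = _Param(_he_uniform(rng, (cin, cout), cin, dtype))
        self.b = _Param(np.zeros(cout, dtype))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        out = x.reshape(-1, self.cin) @ self.w.value + self.b.value
        return out.reshape(*x.shape[:3], self.cout)

    def backward(self, dout):
        dflat = dout.reshape(-1, self.cout)
        xflat = self._x.reshape(-1, self.cin)
        self.w.grad[...] = xflat.T @ dflat
        self.b.grad[...] = dflat.sum(axis=0)
        return (dflat @ self.w.value.T).reshape(self._x.shape)


class _ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _MaxPool2:
    def __init__(self, dtype):
        self.dtype = dtype
        self._arg = None
        self._in_shape = None

    def params(self):
        return []

    def forward(self, x):
        n, h, w, c = x.shape
        self._in_shape = x.shape
        out = np.empty((n, h // 2, w // 2, c), self.dtype)
        self._arg = np.empty(out.shape, np.int8)
        maxpool2_fwd(np.ascontiguousarray(x[:, : h // 2 * 2, : w // 2 * 2, :]), out, self._arg)
        return out

    def backward(self, dout):
        dx = np.zeros(self._in_shape, self.dtype)
        maxpool2_bwd(np.ascontiguousarray(dout), self._arg, dx)
        return dx


class _ResidualBlock:
    """conv3-relu-conv3 main path, conv1 skip path, add, relu, maxpool."""

    def __init__(self, cin, f, rng, dtype):
        self.conv1 = _Conv3(cin, f, rng, dtype)
        self.relu1 = _ReLU()
        self.conv2 = _Conv3(f, f, rng, dtype)
        self.skip = _Conv1(cin, f, rng, dtype)
        self.relu2 = _ReLU()
        self.pool = _MaxPool2(dtype)

    def params(self):
        return self.conv1.params() + self.conv2.params() + self.skip.params()

    def forward(self, x):
        main = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        merged = self.relu2.forward(main + self.skip.forward(x))
        return self.pool.forward(merged)

    def backward(self, dout):
        d = self.relu2.backward(self.pool.backward(dout))
        dx = self.skip.backward(d)
        dx += self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        return dx


class _Dropout:
    def __init__(self, rate):
        self.rate = rate
        self._mask = None

    def params(self):
        return []

    def forward(self, x, train=False, rng=None):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class _Dense:
    def __init__(self, din, dout, rng, dtype):
        self.din, self.dout = din, dout
        self.w = _Param(_he_uniform(rng, (din, dout), din, dtype))
        self.b = _Param(np.zeros(dout, dtype))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        self.w.grad[...] = self._x.T @ dout
        self.b.grad[...] = dout.sum(axis=0)
        return dout @ self.w.value.T


class Network:
    """Executable network compiled from a :class:`NetworkSpec`.

    ``forward`` returns pre-softmax logits; pair with
    :func:`softmax_cross_entropy_grad` for training or :func:`softmax`
    for probabilities.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        h, w, cin = spec.input_shape
        #: per-channel offsets subtracted from inputs (zero-center
        #: normalization); set from the training set by :func:`train`
        self.input_mean = np.zeros(cin, dtype)
        self.stem = _Conv3(cin, spec.stem_filters, rng, dtype, need_input_grad=False)
        self.stem_relu = _ReLU()
        self.blocks = []
        c = spec.stem_filters
        for f in spec.block_filters:
            self.blocks.append(_ResidualBlock(c, f, rng, dtype))
            c = f
        self.dropout = _Dropout(spec.dropout_rate)
        fh, fw, fc = spec.feature_map_shape
        self.fc1 = _Dense(fh * fw * fc, spec.dense_units, rng, dtype)
        self.fc_relu = _ReLU()
        self.fc2 = _Dense(spec.dense_units, spec.num_classes, rng, dtype)
        self._flat_shape = None

    def parameters(self) -> list[_Param]:
        ps = self.stem.params()
        for b in self.blocks:
            ps += b.params()
        return ps + self.fc1.params() + self.fc2.params()

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            p.value[...] = w

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=self.dtype)
        if x.shape[1:] != self.spec.input_shape:
            raise ValueError(f"expected input {self.spec.input_shape}, got {x.shape[1:]}")
        x = x - self.input_mean
        h = self.stem_relu.forward(self.stem.forward(x))
        for b in self.blocks:
            h = b.forward(h)
        h = self.dropout.forward(h, train=train, rng=rng)
        self._flat_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        return self.fc2.forward(self.fc_relu.forward(self.fc1.forward(h)))

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc1.backward(self.fc_relu.backward(self.fc2.backward(dlogits)))
        d = self.dropout.backward(d.reshape(self._flat_shape))
        for b in reversed(self.blocks):
            d = b.backward(d)
        self.stem.backward(self.stem_relu.backward(d))


def softmax_cross_entropy_grad(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Summed cross-entropy loss and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = len(labels)
    loss = float(-np.log(np.maximum(probs[np.arange(n), labels], _XENT_EPS)).sum())
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits.astype(logits.dtype)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainingConfig:
    """Optimization settings: Adam at 0.001, mini-batches of 128, up to 48
    epochs, evaluation every 256 iterations."""

    batch_size: int = 128
    learning_rate: float = 0.001
    max_epochs: int = 48
    eval_interval: int = 256
    seed: int = 0
    deterministic: bool = True
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if min(self.batch_size, self.max_epochs, self.eval_interval) < 1:
            raise ValueError("batch_size, max_epochs and eval_interval must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class EvalRecord:
    iteration: int
    train_loss: float
    val_loss: float
    val_accuracy: float
    checkpoint_id: int


@dataclass
class TrainingHistory:
    """Per-evaluation training metrics plus stored checkpoints."""

    records: list[EvalRecord] = field(default_factory=list)
    checkpoints: dict[int, list[np.ndarray]] = field(default_factory=dict)

    def add(self, record: EvalRecord, weights: list[np.ndarray]) -> None:
        if self.records and record.iteration <= self.records[-1].iteration:
            raise ValueError("history records must be strictly increasing in iteration")
        self.records.append(record)
        self.checkpoints[record.checkpoint_id] = weights


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, params: list[_Param], config: TrainingConfig):
        self.params = params
        self.cfg = config
        self.t = 0
        self.m = [np.zeros_like(p.value, dtype=np.float32) for p in params]
        self.v = [np.zeros_like(p.value, dtype=np.float32) for p in params]

    def step(self) -> None:
        self.t += 1
        c = self.cfg
        bc1 = 1.0 - c.beta1**self.t
        bc2 = 1.0 - c.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= c.beta1
            m += (1 - c.beta1) * g
            v *= c.beta2
            v += (1 - c.beta2) * np.square(g)
            p.value -= (c.learning_rate * (m / bc1) / (np.sqrt(v / bc2) + c.eps)).astype(
                p.value.dtype
            )


def _evaluate(net: Network, images: np.ndarray, labels: np.ndarray, batch: int = 16):
    total_loss = 0.0
    correct = 0
    for i in range(0, len(images), batch):
        logits = net.forward(images[i : i + batch], train=False)
        loss, _ = softmax_cross_entropy_grad(logits, labels[i : i + batch])
        total_loss += loss
        correct += int((logits.argmax(axis=1) == labels[i : i + batch]).sum())
    return total_loss / len(images), correct / len(images)


def train(
    spec: NetworkSpec,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    val_images: np.ndarray,
    val_labels: np.ndarray,
    config: TrainingConfig | None = None,
    augment_fn=None,
    dtype=np.float32,
) -> tuple[Network, TrainingHistory]:
    """Train the network with Adam on summed mini-batch cross-entropy.

    Validation loss/accuracy are recorded (and weights checkpointed) every
    ``eval_interval`` iterations and once more after the final iteration.
    ``augment_fn(batch, rng) -> batch`` is applied to every training batch,
    so augmentation is re-drawn each epoch. With ``deterministic`` seeding,
    two runs produce identical histories.
    """
    config = config or TrainingConfig()
    if len(train_images) == 0 or len(val_images) == 0:
        raise ValueError("training and validation sets must be non-empty")
    train_labels = np.asarray(train_labels)
    val_labels = np.asarray(val_labels)

    ss = np.random.SeedSequence(config.seed)
    init_seed = int(ss.generate_state(1)[0] % (2**31))
    shuffle_rng, drop_rng, aug_rng = (np.random.default_rng(c) for c in ss.spawn(3))

    net = Network(spec, seed=init_seed, dtype=dtype)
    # zero-center normalization: per-channel training-set means, applied
    # to every input the network sees from here on
    net.input_mean = train_images.mean(axis=(0, 1, 2)).astype(dtype)
    adam = Adam(net.parameters(), config)
    history = TrainingHistory()

    iteration = 0
    running_loss = 0.0
    running_n = 0
    next_ckpt = 0

    def record():
        nonlocal next_ckpt, running_loss, running_n
        val_loss, val_acc = _evaluate(net, val_images, val_labels, batch=config.batch_size)
        train_loss = running_loss / max(running_n, 1)
        history.add(
            EvalRecord(iteration, train_loss, val_loss, val_acc, next_ckpt), net.get_weights()
        )
        next_ckpt += 1
        running_loss = 0.0
        running_n = 0

    for _epoch in range(config.max_epochs):
        order = shuffle_rng.permutation(len(train_images))
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = train_images[idx]
            if augment_fn is not None:
                xb = augment_fn(xb, aug_rng)
            logits = net.forward(xb, train=True, rng=drop_rng)
            loss, dlogits = softmax_cross_entropy_grad(logits, train_labels[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at iteration {iteration + 1}"
                )
            net.backward(dlogits)
            adam.step()
            iteration += 1
            running_loss += loss / len(idx)
            running_n += 1
            if iteration % config.eval_interval == 0:
                record()
    if not history.records or history.records[-1].iteration < iteration:
        record()
    return net, history


def select_best_checkpoint(history: TrainingHistory) -> int:
    """Checkpoint id with maximal validation accuracy; earliest wins ties."""
    if not history.records:
        raise ValueError("empty training history")
    best = max(history.records, key=lambda r: (r.val_accuracy, -r.iteration))
    return best.checkpoint_id


def save_network(net: Network, path) -> None:
    """Serialize spec fields and weights to an .npz file."""
    spec = net.spec
    meta = dict(
        input_shape=np.array(spec.input_shape),
        num_classes=np.array(spec.num_classes),
        stem_filters=np.array(spec.stem_filters),
        block_filters=np.array(spec.block_filters),
        dropout_rate=np.array(spec.dropout_rate),
        dense_units=np.array(spec.dense_units),
    )
    weights = {f"w{i}": w for i, w in enumerate(net.get_weights())}
    np.savez(path, input_mean=net.input_mean, **meta, **weights)


def load_network(path) -> Network:
    """Rebuild a network (spec + weights) from :func:`save_network` output."""
    data = np.load(path)
    spec = NetworkSpec(
        input_shape=tuple(int(v) for v in data["input_shape"]),
        num_classes=int(data["num_classes"]),
        stem_filters=int(data["stem_filters"]),
        block_filters=tuple(int(v) for v in data["block_filters"]),
        dropout_rate=float(data["dropout_rate"]),
        dense_units=int(data["dense_units"]),
    )
    net = Network(spec)
    net.input_mean = data["input_mean"].astype(net.dtype)
    n = len(net.parameters())
    net.set_weights([data[f"w{i}"] for i in range(n)])
    return net


def predict(net: Network, images: np.ndarray, batch: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels for a stack of images."""
    probs = []
    for i in range(0, len(images), batch):
        probs.append(softmax(net.forward(images[i : i + batch], train=False)))
    p = np.concatenate(probs) if probs else np.zeros((0, net.spec.num_classes))
    return p, p.argmax(axis=1)
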