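"""Dice-trained U-Net-style encoder-decoder for thyroid segmentation.

The network is the canonical U-Net pattern: ``depth`` encoder levels of two
(3x3 convolution -> batch normalization -> ReLU) blocks followed by 2x2
max-pooling, a two-block bottleneck, and a mirrored decoder of 2x nearest
upsampling + 3x3 convolution, concatenation with the skip connection from
the matching encoder level, and two further conv blocks; a final 1x1
convolution with a sigmoid yields a per-pixel foreground probability map of
the same spatial size as the input (one grayscale channel in, one channel
out; spatial dims must be divisible by ``2**depth``).

Everything — convolution via im2col, batch-norm, pooling, Adam, and the
soft-Dice loss — is implemented directly on numpy arrays in float32, sized
for CPU training of desk-scale models (64x64 inputs, 8 base channels); the
faithful 256x256 / 64-channel configuration is expressible but slow.

The Dice similarity coefficient between a ground-truth mask ``y`` and a
prediction ``y'`` is ``2|y ∩ y'| / (|y| + |y'|)`` and the training loss is
``1 - DSC`` computed on the soft (sigmoid) prediction with a smoothing term
``eps`` in numerator and denominator, so the loss is defined (and zero)
when both masks are empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentationConfig, augment_pair
from .io import CTVolume, MaskVolume

__all__ = [
    "NetworkConfig",
    "TrainingHistory",
    "UNet",
    "dice_coefficient",
    "dice_loss",
    "build_network",
    "train",
    "infer_volume",
]

DICE_EPS = 1.0  # soft-Dice smoothing term, numerator and denominator


# ---------------------------------------------------------------------------
# Dice metric and loss
# ---------------------------------------------------------------------------


def _as_binary(arr) -> np.ndarray:
    a = arr.voxels if isinstance(arr, MaskVolume) else np.asarray(arr)
    vals = np.unique(a)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask must be binary {0, 1}")
    return a.astype(np.float64)


def dice_coefficient(y, y_prime) -> float:
    """Hard Dice similarity coefficient ``2|y ∩ y'| / (|y| + |y'|)``.

    Accepts :class:`MaskVolume` or binary arrays of any matching shape.
    Two empty masks are in perfect agreement, so 1.0 is returned.
    """
    a = _as_binary(y)
    b = _as_binary(y_prime)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a * b).sum() / denom)


def dice_loss(y, y_prime, eps: float = DICE_EPS) -> float:
    """Soft-Dice loss ``1 - (2|y ∩ y'| + eps) / (|y| + |y'| + eps)``.

    ``y`` is a binary target, ``y_prime`` a soft prediction in [0, 1]
    (a hard 0/1 prediction recovers ``1 - dice_coefficient`` as eps -> 0).
    """
    a = _as_binary(y)
    b = y_prime.voxels if isinstance(y_prime, MaskVolume) else np.asarray(y_prime, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if b.min() < 0.0 or b.max() > 1.0:
        raise ValueError("soft prediction values must lie in [0, 1]")
    num = 2.0 * (a * b).sum() + eps
    den = a.sum() + b.sum() + eps
    return float(1.0 - num / den)


# ---------------------------------------------------------------------------
# Layers (numpy, NCHW, float32)
# ---------------------------------------------------------------------------


class _Conv2D:
    """Same-padding convolution as a sum of per-offset GEMMs (NHWC layout).

    ``w`` is ``(k*k, c_in, c_out)``: one GEMM per kernel offset against the
    correspondingly shifted input window, which keeps every copy a plain
    block copy instead of a strided im2col gather.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.w = (rng.standard_normal((k * k, c_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self._cols = None
        self._shape = None

    def params(self):
        return [("w", self), ("b", self)]

    def num_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, h, w, c = x.shape
        k, p, f = self.k, self.k // 2, self.c_out
        if k == 1:
            x2 = np.ascontiguousarray(x).reshape(-1, c)
            if training:
                self._xp = x2
                self._shape = (n, h, w, c)
            return (x2 @ self.w[0] + self.b).reshape(n, h, w, f)
        # one GEMM per kernel offset against the shifted window; each window
        # copy is a plain block copy, not a strided im2col gather
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = [
            np.ascontiguousarray(xp[:, di : di + h, dj : dj + w, :]).reshape(-1, c)
            for di in range(k)
            for dj in range(k)
        ]
        out = cols[0] @ self.w[0]
        for o in range(1, len(cols)):
            out += cols[o] @ self.w[o]
        out += self.b
        if training:
            self._cols = cols
            self._shape = (n, h, w, c)
        return out.reshape(n, h, w, f)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        k, p, f = self.k, self.k // 2, self.c_out
        g2 = np.ascontiguousarray(grad).reshape(-1, f)
        self.db = g2.sum(axis=0).astype(np.float32)
        if k == 1:
            self.dw = (self._xp.T @ g2)[None].astype(np.float32)
            self._xp = None
            return (g2 @ self.w[0].T).reshape(n, h, w, c)
        cols = self._cols
        self._cols = None
        offsets = [(i, j) for i in range(k) for j in range(k)]
        dw = np.empty((k * k, c, f), dtype=np.float32)
        for o in range(k * k):
            dw[o] = cols[o].T @ g2
        self.dw = dw
        # dX: one GEMM against the (F, k*k*C) unfolded kernel, then scatter
        wb = np.ascontiguousarray(self.w.transpose(2, 0, 1)).reshape(f, k * k * c)
        dmap = (g2 @ wb).reshape(n, h, w, k * k, c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        for o, (di, dj) in enumerate(offsets):
            dxp[:, di : di + h, dj : dj + w, :] += dmap[:, :, :, o, :]
        return np.ascontiguousarray(dxp[:, p : p + h, p : p + w, :])


class _BatchNorm2D:
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [("gamma", self), ("beta", self)]

    def num_params(self) -> int:
        return self.gamma.size + self.beta.size

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        # NHWC: normalize over (batch, rows, cols) per channel
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if training:
            self._xhat = xhat.astype(np.float32)
            self._inv = inv.astype(np.float32)
        return (self.gamma * xhat + self.beta).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dgamma = (grad * self._xhat).sum(axis=(0, 1, 2)).astype(np.float32)
        self.dbeta = grad.sum(axis=(0, 1, 2)).astype(np.float32)
        dxhat = grad * self.gamma
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 1, 2), keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=(0, 1, 2), keepdims=True)
        ) * self._inv
        self._xhat = None
        return dx.astype(np.float32)


class _ReLU:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


def _maxpool2(x: np.ndarray):
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(
        n, h // 2, w // 2, c, 4
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool2_backward(grad: np.ndarray, idx: np.ndarray, in_shape) -> np.ndarray:
    n, h, w, c = in_shape
    gr = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
    np.put_along_axis(gr, idx[..., None], grad[..., None], axis=-1)
    return (
        gr.reshape(n, h // 2, w // 2, c, 2, 2)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, h, w, c)
    )


def _upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2)


def _upsample2_backward(grad: np.ndarray) -> np.ndarray:
    n, h, w, c = grad.shape
    return grad.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------


@dataclass
class NetworkConfig:
    """Architecture and training hyper-parameters.

    Defaults are the faithful configuration (256x256 single-channel input,
    4 encoder levels, 64 base channels, batch 16); :meth:`desk` returns the
    reduced configuration used for CPU-scale experiments.  Optimizer and
    learning rate are exposed because they are not dictated by the method.
    """

    input_size: tuple[int, int] = (256, 256)
    depth: int = 4
    base_channels: int = 64
    batch_size: int = 16
    max_epochs: int = 100
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        h, w = self.input_size
        if h % (1 << self.depth) or w % (1 << self.depth):
            raise ValueError(
                f"input size {self.input_size} not divisible by 2**depth = {1 << self.depth}"
            )
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")

    @classmethod
    def desk(cls, seed: int = 0, max_epochs: int = 10) -> "NetworkConfig":
        """Reduced configuration: 64x64 input, depth 2, 8 base channels.

        The higher learning rate suits the small model and the easy
        synthetic contrast; it reaches a stable validation plateau within
        a handful of epochs.
        """
        return cls(
            input_size=(64, 64),
            depth=2,
            base_channels=8,
            batch_size=16,
            max_epochs=max_epochs,
            learning_rate=3e-3,
            seed=seed,
        )


@dataclass
class TrainingHistory:
    """Per-epoch records; ``best_epoch`` is 1-based and attains the maximum
    recorded validation DSC."""

    train_dsc: list[float] = field(default_factory=list)
    val_dsc: list[float] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    best_epoch: int = 0

    @property
    def best_val_dsc(self) -> float:
        return self.val_dsc[self.best_epoch - 1]


class UNet:
    """Encoder-decoder with skip concatenations, built from numpy layers."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, b = config.depth, config.base_channels

        def block(c_in, c_out):
            return [_Conv2D(c_in, c_out, 3, rng), _BatchNorm2D(c_out), _ReLU()]

        self.enc: list[list] = []
        c_in = 1
        for i in range(d):
            c_out = b << i
            self.enc.append(block(c_in, c_out) + block(c_out, c_out))
            c_in = c_out
        self.bottleneck = block(c_in, c_in * 2) + block(c_in * 2, c_in * 2)
        self.dec: list[dict] = []
        c = c_in * 2
        for i in reversed(range(d)):
            c_skip = b << i
            self.dec.append(
                {
                    "up": block(c, c_skip),  # upsample then 3x3 conv halving channels
                    "body": block(2 * c_skip, c_skip) + block(c_skip, c_skip),
                }
            )
            c = c_skip
        self.head = _Conv2D(c, 1, 1, rng)

    # -- plumbing ----------------------------------------------------------

    def _layers(self):
        for blk in self.enc:
            yield from blk
        yield from self.bottleneck
        for lev in self.dec:
            yield from lev["up"]
            yield from lev["body"]
        yield self.head

    def parameters(self):
        out = []
        for layer in self._layers():
            if hasattr(layer, "params"):
                out.extend(layer.params())
        return out

    def num_params(self) -> int:
        return sum(l.num_params() for l in self._layers() if hasattr(l, "num_params"))

    def state_dict(self):
        state = []
        for obj in self._layers():
            if isinstance(obj, _Conv2D):
                state.append({k: getattr(obj, k).copy() for k in ("w", "b")})
            elif isinstance(obj, _BatchNorm2D):
                state.append(
                    {
                        k: getattr(obj, k).copy()
                        for k in ("gamma", "beta", "running_mean", "running_var")
                    }
                )
        return state

    def load_state_dict(self, state):
        stateful = [l for l in self._layers() if isinstance(l, (_Conv2D, _BatchNorm2D))]
        for layer, st in zip(stateful, state, strict=True):
            for k, v in st.items():
                setattr(layer, k, v.copy())

    def save(self, path) -> None:
        """Write weights + architecture to an ``.npz`` checkpoint."""
        cfg = self.config
        arrays = {
            "meta": np.array(
                [cfg.input_size[0], cfg.input_size[1], cfg.depth, cfg.base_channels,
                 cfg.batch_size, cfg.seed],
                dtype=np.int64,
            )
        }
        for i, st in enumerate(self.state_dict()):
            for k, v in st.items():
                arrays[f"l{i:03d}.{k}"] = v
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "UNet":
        with np.load(path) as data:
            h, w, depth, base, batch, seed = (int(v) for v in data["meta"])
            model = cls(
                NetworkConfig(
                    input_size=(h, w), depth=depth, base_channels=base,
                    batch_size=batch, seed=seed,
                )
            )
            state: list[dict] = []
            for key in sorted(k for k in data.files if k != "meta"):
                idx, name = key.split(".", 1)
                i = int(idx[1:])
                while len(state) <= i:
                    state.append({})
                state[i][name] = data[key]
        model.load_state_dict(state)
        return model

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Input ``(N, 1, H, W)`` float32 in [0, 1] -> sigmoid map, same size.

        Internally the tensors are channels-last; input and output keep the
        channels-first public convention.
        """
        h, w = self.config.input_size
        if x.shape[2:] != (h, w):
            raise ValueError(f"expected spatial size {(h, w)}, got {x.shape[2:]}")
        x = np.ascontiguousarray(x.transpose(0, 2, 3, 1), dtype=np.float32)
        self._tape = tape = []
        skips = []
        for blk in self.enc:
            for layer in blk:
                x = layer.forward(x, training)
            skips.append(x)
            shape = x.shape
            x, idx = _maxpool2(x)
            tape.append(("pool", idx, shape))
        for layer in self.bottleneck:
            x = layer.forward(x, training)
        for lev, skip in zip(self.dec, reversed(skips)):
            x = _upsample2(x)
            for layer in lev["up"]:
                x = layer.forward(x, training)
            c_up = x.shape[3]
            x = np.concatenate([skip, x], axis=3)
            tape.append(("concat", c_up, None))
            for layer in lev["body"]:
                x = layer.forward(x, training)
        z = self.head.forward(x, training)
        return (1.0 / (1.0 + np.exp(-z))).transpose(0, 3, 1, 2)

    def backward(self, dprob_times_sigmoid_grad: np.ndarray) -> None:
        """Backprop from dL/dz (sigmoid gradient already folded in)."""
        tape = self._tape
        grad = np.ascontiguousarray(
            dprob_times_sigmoid_grad.transpose(0, 2, 3, 1), dtype=np.float32
        )
        grad = self.head.backward(grad)
        skip_grads = []
        t = len(tape) - 1
        for lev in reversed(self.dec):
            for layer in reversed(lev["body"]):
                grad = layer.backward(grad)
            kind, c_up, _ = tape[t]
            assert kind == "concat"
            t -= 1
            skip_grads.append(np.ascontiguousarray(grad[..., : grad.shape[3] - c_up]))
            grad = np.ascontiguousarray(grad[..., grad.shape[3] - c_up :])
            for layer in reversed(lev["up"]):
                grad = layer.backward(grad)
            grad = _upsample2_backward(grad)
        for layer in reversed(self.bottleneck):
            grad = layer.backward(grad)
        # skip_grads were collected shallowest-first; the encoder unwinds
        # deepest-first
        for blk, sg in zip(reversed(self.enc), reversed(skip_grads)):
            kind, idx, shape = tape[t]
            assert kind == "pool"
            t -= 1
            grad = _maxpool2_backward(grad, idx, shape) + sg
            for layer in reversed(blk):
                grad = layer.backward(grad)
        self._tape = None


def build_network(config: NetworkConfig) -> UNet:
    """Construct the encoder-decoder for ``config`` (validates divisibility)."""
    return UNet(config)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(getattr(obj, name)) for name, obj in params]
        self.v = [np.zeros_like(getattr(obj, name)) for name, obj in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (name, obj) in enumerate(self.params):
            g = getattr(obj, "d" + name)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p = getattr(obj, name)
            setattr(obj, name, (p - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32))


# ---------------------------------------------------------------------------
# Training and inference
# ---------------------------------------------------------------------------


def _soft_dice_batch(prob: np.ndarray, target: np.ndarray, eps: float = DICE_EPS):
    """Per-sample soft DSC and dL/dprob for loss = 1 - mean(DSC)."""
    n = prob.shape[0]
    p = prob.reshape(n, -1).astype(np.float64)
    y = target.reshape(n, -1).astype(np.float64)
    num = 2.0 * (p * y).sum(axis=1) + eps
    den = p.sum(axis=1) + y.sum(axis=1) + eps
    dsc = num / den
    # d(dsc)/dp = (2y*den - num) / den^2 ; loss gradient averages over batch
    dprob = -((2.0 * y * den[:, None] - num[:, None]) / den[:, None] ** 2) / n
    return dsc, dprob.reshape(prob.shape).astype(np.float32)


def _volume_slices(volume: CTVolume, mask: MaskVolume):
    img = volume.normalized().astype(np.float32)
    return [(img[i], mask.voxels[i]) for i in range(volume.n_slices)]


def train(
    model: UNet,
    train_pairs: list[tuple[CTVolume, MaskVolume]],
    val_pairs: list[tuple[CTVolume, MaskVolume]],
    config: NetworkConfig | None = None,
    augmentation: AugmentationConfig | None = None,
    threshold: float = 0.5,
) -> tuple[UNet, TrainingHistory]:
    """Train with soft-Dice loss; return the best-validation-epoch snapshot.

    Every slice of every training volume is re-augmented at each epoch with
    the configured scheme, shuffled and fed in batches.  After each epoch
    the mean per-volume hard DSC on the validation volumes is recorded and
    the model snapshot from the epoch with the highest validation DSC is
    restored before returning.  ``train_dsc`` in the history is the mean
    soft DSC over that epoch's (augmented) training batches.  Fully seeded
    through ``config.seed``.
    """
    if config is None:
        config = model.config
    if not train_pairs or not val_pairs:
        raise ValueError("train and validation splits must be nonempty")
    if augmentation is None:
        augmentation = AugmentationConfig()
    rng = np.random.default_rng(config.seed + 1)
    slices = []
    for vol, mask in train_pairs:
        slices.extend(_volume_slices(vol, mask))

    opt = _Adam(model.parameters(), config.learning_rate)
    history = TrainingHistory()
    best_state = None
    for epoch in range(1, config.max_epochs + 1):
        augmented = [augment_pair(img, msk, augmentation, rng) for img, msk in slices]
        order = rng.permutation(len(augmented))
        epoch_dsc, epoch_loss, n_batches = 0.0, 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            x = np.stack([augmented[i][0] for i in idx])[:, None].astype(np.float32)
            y = np.stack([augmented[i][1] for i in idx])[:, None].astype(np.float32)
            prob = model.forward(x, training=True)
            dsc, dprob = _soft_dice_batch(prob, y)
            model.backward(dprob * prob * (1.0 - prob))
            opt.step()
            epoch_dsc += float(dsc.mean())
            epoch_loss += float(1.0 - dsc.mean())
            n_batches += 1
        val_scores = [
            dice_coefficient(mask, infer_volume(model, vol, threshold))
            for vol, mask in val_pairs
        ]
        history.train_dsc.append(epoch_dsc / n_batches)
        history.loss.append(epoch_loss / n_batches)
        history.val_dsc.append(float(np.mean(val_scores)))
        if history.best_epoch == 0 or history.val_dsc[-1] > history.best_val_dsc:
            history.best_epoch = epoch
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return model, history


def infer_volume(model: UNet, volume: CTVolume, threshold: float = 0.5) -> MaskVolume:
    """Slice-wise inference: sigmoid maps thresholded to a binary mask.

    ``threshold`` partitions probabilities as ``p > threshold -> 1``, so 0
    maps every strictly positive sigmoid output to foreground.
    """
    h, w = model.config.input_size
    if volume.shape[1:] != (h, w):
        raise ValueError(
            f"volume in-plane size {volume.shape[1:]} != network input {(h, w)}; "
            "center-crop or regenerate at the network size"
        )
    img = volume.normalized().astype(np.float32)
    out = np.empty(volume.shape, dtype=np.uint8)
    bs = max(1, model.config.batch_size)
    for start in range(0, volume.n_slices, bs):
        x = img[start : start + bs][:, None]
        prob = model.forward(x, training=False)
        out[start : start + bs] = (prob[:, 0] > threshold).astype(np.uint8)
    return MaskVolume(out, volume.pixel_spacing_mm, volume.slice_thickness_mm, "thyroid")
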