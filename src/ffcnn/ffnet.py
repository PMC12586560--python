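"""Forward-Forward training core for stacks of convolutional layers.

The algorithm trains each layer with a purely local objective.  For a layer
with post-rectifier activations ``y_1..y_N`` the *goodness* is
``g = sum_i y_i**2`` and the layer assigns the sample the probability
``sigma(g - theta)`` of belonging to the positive (correctly labeled) set,
with threshold ``theta = N`` (the number of activations).  Positive samples
are trained toward probability 1 of being positive, negatives toward
probability 1 of being negative (``sigma(theta - g)``), under binary
cross-entropy.  Between layers only the *orientation* of the activation
vector is passed on: each sample's activations are divided by their root
mean square (layer normalization), and the result is treated as a constant
by the next layer, so no gradient ever crosses a layer boundary.

A batch-norm variant (for the deeper configuration) replaces the inter-layer
RMS normalization with per-channel batch normalization placed before each
convolution; its affine parameters receive gradients from the same local
loss, which is exact because the preceding layer's output is detached.

Because each layer's loss depends only on its own parameters, all gradients
are closed-form and computed directly (im2col convolution algebra); the
cumulative network loss (sum of per-layer losses, first layer excluded by
default) then decomposes into independent per-layer steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

from .errors import ConfigurationError, ConsistencyError
from .labels import LabelBank

__all__ = [
    "goodness",
    "layer_probability",
    "combined_loss",
    "layer_normalize",
    "lr_schedule",
    "ConvLayer",
    "LayerCache",
    "FFNetwork",
    "TrainConfig",
    "TrainHistory",
    "Adam",
    "ff_train_step",
    "train_ff",
    "save_checkpoint",
    "load_checkpoint",
]

_EPS_LAYER_NORM = 1e-8
_EPS_BATCH_NORM = 1e-5


# --------------------------------------------------------------------------
# the scalar pieces
# --------------------------------------------------------------------------

def goodness(activations: np.ndarray) -> np.ndarray:
    """Per-sample sum of squared activations.

    ``activations`` is ``(N, ...)``; all trailing axes are reduced.
    """
    a = np.asarray(activations, dtype=np.float64)
    return (a.reshape(len(a), -1) ** 2).sum(axis=1)


def layer_probability(g, theta: float, polarity: str) -> np.ndarray:
    """Probability that a sample belongs to its designated set.

    ``sigma(g - theta)`` for positive samples, ``sigma(theta - g)`` for
    negative ones.
    """
    g = np.asarray(g, dtype=np.float64)
    if polarity == "positive":
        return expit(g - theta)
    if polarity == "negative":
        return expit(theta - g)
    raise ValueError(f"polarity must be 'positive' or 'negative', got {polarity!r}")


def combined_loss(layer_probabilities: Sequence[np.ndarray]) -> float:
    """Cumulative binary cross-entropy against target 1.

    Each element is one included layer's per-sample probability of its
    designated set; losses are summed over layers and averaged over the
    batch.
    """
    probs = [np.atleast_1d(np.asarray(p, dtype=np.float64)) for p in layer_probabilities]
    if not probs:
        raise ConfigurationError("no layers are included in the loss")
    total = np.zeros_like(probs[0])
    for p in probs:
        total = total - np.log(np.clip(p, 1e-300, 1.0))
    return float(total.mean())


def layer_normalize(activations: np.ndarray, eps: float = _EPS_LAYER_NORM) -> np.ndarray:
    """Divide each sample's activation vector by its root mean square.

    The normalized vector has RMS 1, so only the orientation of the
    activity pattern is passed to the next layer.  ``eps`` guards the
    all-zero vector.
    """
    a = np.asarray(activations, dtype=np.float64)
    flat = a.reshape(len(a), -1)
    rms = np.sqrt((flat ** 2).mean(axis=1) + eps)
    return a / rms.reshape((-1,) + (1,) * (a.ndim - 1))


def lr_schedule(e: int, E: int, lr: float) -> float:
    """Linear learning-rate cooldown starting halfway through training.

    Returns ``lr`` for epochs ``e <= E/2`` and ``(2*lr/E) * (1 + E - e)``
    afterwards; continuous at the halfway point and decaying to ``2*lr/E``
    at the final epoch.
    """
    if not 1 <= e <= E:
        raise ValueError(f"epoch {e} outside [1, {E}]")
    if e <= E / 2:
        return lr
    return (2.0 * lr / E) * (1 + E - e)


# --------------------------------------------------------------------------
# im2col convolution plumbing
# --------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """``(N, C, H, W) -> (N, H*W, C*k*k)`` patches, same padding, stride 1."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    return np.ascontiguousarray(
        win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)
    )


def _col2im(dcols: np.ndarray, shape: tuple, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter patch gradients back to the input."""
    n, c, h, w = shape
    p = k // 2
    d6 = dcols.reshape(n, h, w, c, k, k)
    dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float64)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += d6[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dxp[:, :, p : p + h, p : p + w]


# --------------------------------------------------------------------------
# layers and network
# --------------------------------------------------------------------------

@dataclass
class LayerCache:
    """Intermediates of one layer's forward pass needed for its local gradient."""

    cols: np.ndarray          # im2col patches of the (possibly batch-normed) input
    z: np.ndarray             # pre-activation, (N, HW, out_channels)
    y: np.ndarray             # post-ReLU activations, (N, out_channels, H, W)
    g: np.ndarray             # per-sample goodness
    xhat: np.ndarray | None   # normalized BN input (batch-norm mode only)
    out_shape: tuple          # (out_channels, H, W)


class ConvLayer:
    """One FF-trained convolutional layer.

    Same padding, stride 1, odd kernel, so the spatial size is preserved and
    the goodness threshold ``theta = out_channels * H * W`` is constant.
    ``norm`` selects the inter-layer normalization contract: ``layer_norm``
    (RMS normalization applied to this layer's output before it is passed
    on) or ``batch_norm`` (per-channel batch normalization of this layer's
    *input*, applied before the convolution).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 norm: str = "layer_norm", include_in_loss: bool = True,
                 rng: np.random.Generator | None = None):
        if kernel % 2 == 0:
            raise ConfigurationError("kernel size must be odd (same padding)")
        if norm not in ("layer_norm", "batch_norm"):
            raise ConfigurationError(f"unknown normalization mode {norm!r}")
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel * kernel
        limit = np.sqrt(6.0 / fan_in)  # He-style fan-in uniform init
        self.W = rng.uniform(-limit, limit, (out_channels, in_channels, kernel, kernel))
        self.b = np.zeros(out_channels)
        self.kernel = kernel
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.norm = norm
        self.include_in_loss = include_in_loss
        if norm == "batch_norm":
            self.gamma = np.ones(in_channels)
            self.beta = np.zeros(in_channels)
            self.running_mean = np.zeros(in_channels)
            self.running_var = np.ones(in_channels)
            self.bn_momentum = 0.1

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        params = {"W": self.W, "b": self.b}
        if self.norm == "batch_norm":
            params["gamma"] = self.gamma
            params["beta"] = self.beta
        return params

    def theta(self, height: int, width: int) -> float:
        """Goodness threshold: the number of activations this layer emits."""
        return float(self.out_channels * height * width)

    # -- forward ------------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> LayerCache:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ConsistencyError(
                f"layer expects {self.in_channels} input channels, got {c}"
            )
        xhat = None
        if self.norm == "batch_norm":
            if training:
                mu = x.mean(axis=(0, 2, 3))
                var = x.var(axis=(0, 2, 3))
                self.running_mean = (
                    (1 - self.bn_momentum) * self.running_mean + self.bn_momentum * mu
                )
                self.running_var = (
                    (1 - self.bn_momentum) * self.running_var + self.bn_momentum * var
                )
            else:
                mu, var = self.running_mean, self.running_var
            xhat = (x - mu[None, :, None, None]) / np.sqrt(
                var[None, :, None, None] + _EPS_BATCH_NORM
            )
            u = self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]
        else:
            u = x
        cols = _im2col(u, self.kernel)
        wflat = self.W.reshape(self.out_channels, -1)
        z = cols @ wflat.T + self.b
        y = np.maximum(z, 0.0)
        y = y.transpose(0, 2, 1).reshape(n, self.out_channels, h, w)
        return LayerCache(
            cols=cols, z=z, y=y, g=goodness(y), xhat=xhat,
            out_shape=(self.out_channels, h, w),
        )

    def output_for_next(self, cache: LayerCache) -> np.ndarray:
        """What the next layer consumes (gradient-detached by construction)."""
        if self.norm == "layer_norm":
            return layer_normalize(cache.y)
        return cache.y

    # -- local gradient -----------------------------------------------------

    def local_gradients(self, cache: LayerCache, dloss_dg: np.ndarray) -> dict:
        """Gradients of a loss with per-sample derivative ``dloss_dg`` w.r.t. g.

        ``dloss_dg`` must already include any batch averaging.  The chain is
        g -> y (2y) -> z (ReLU mask) -> {W, b, and BN affine parameters}.
        """
        n, hw, _ = cache.cols.shape
        grad_z = (2.0 * np.maximum(cache.z, 0.0)) * (cache.z > 0)
        grad_z = grad_z * dloss_dg[:, None, None]
        wflat = self.W.reshape(self.out_channels, -1)
        grads = {
            "W": np.einsum("nho,nhc->oc", grad_z, cache.cols).reshape(self.W.shape),
            "b": grad_z.sum(axis=(0, 1)),
        }
        if self.norm == "batch_norm":
            dcols = grad_z @ wflat  # (N, HW, C*k*k)
            c, h, w = self.in_channels, *cache.out_shape[1:]
            du = _col2im(dcols, (n, c, h, w), self.kernel)
            grads["gamma"] = (du * cache.xhat).sum(axis=(0, 2, 3))
            grads["beta"] = du.sum(axis=(0, 2, 3))
        return grads


class FFNetwork:
    """An ordered stack of FF-trained convolutional layers.

    The first layer is excluded from the cumulative loss and from goodness
    inference by default (``include_first_in_loss=False``): after the first
    normalization the activity-vector length already separates positive
    from negative data, so later layers are forced to learn new features.

    ``forward_passes`` counts whole-network forward calls (one per batch),
    which makes the M-fold inference cost of goodness classification
    observable.
    """

    def __init__(self, input_shape: tuple, n_layers: int = 3, filters: int = 8,
                 kernel: int = 3, norm: str = "layer_norm", n_classes: int = 10,
                 seed: int = 0, include_first_in_loss: bool = False):
        c, h, w = input_shape
        self.input_shape = (int(c), int(h), int(w))
        self.n_classes = int(n_classes)
        self.norm = norm
        self.seed = int(seed)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        self.layers: list[ConvLayer] = []
        in_ch = c
        for i in range(n_layers):
            self.layers.append(
                ConvLayer(
                    in_ch, filters, kernel, norm=norm,
                    include_in_loss=(i > 0 or include_first_in_loss), rng=rng,
                )
            )
            in_ch = filters
        self.forward_passes = 0

    # -- geometry -----------------------------------------------------------

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def thetas(self) -> list[float]:
        _, h, w = self.input_shape
        return [layer.theta(h, w) for layer in self.layers]

    def loss_layer_indices(self) -> list[int]:
        return [i for i, layer in enumerate(self.layers) if layer.include_in_loss]

    # -- forward ------------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> list[LayerCache]:
        """Run a ``(N, C, H, W)`` batch through all layers.

        Returns one :class:`LayerCache` per layer.  Goodness is computed on
        the pre-normalization, post-rectifier activations; each layer
        consumes the normalized output of its predecessor as a constant.
        """
        if x.ndim != 4 or x.shape[1:] != self.input_shape:
            raise ConsistencyError(
                f"batch shape {x.shape} does not match input shape {self.input_shape}"
            )
        self.forward_passes += 1
        caches = []
        h = np.asarray(x, dtype=np.float64)
        for layer in self.layers:
            cache = layer.forward(h, training=training)
            caches.append(cache)
            h = layer.output_for_next(cache)
        return caches

    def forward_images(self, images: np.ndarray, training: bool = False) -> list[LayerCache]:
        """Convenience wrapper accepting ``(N, H, W, C)`` image batches."""
        return self.forward(
            np.asarray(images, dtype=np.float64).transpose(0, 3, 1, 2), training=training
        )

    def features(self, images: np.ndarray, chunk: int = 256) -> np.ndarray:
        """Concatenated flattened activations of all layers except the first.

        Processed in chunks so the im2col caches stay bounded.
        """
        images = np.asarray(images, dtype=np.float64)
        blocks = []
        for start in range(0, len(images), chunk):
            caches = self.forward_images(images[start : start + chunk])
            blocks.append(
                np.concatenate([c.y.reshape(len(c.y), -1) for c in caches[1:]], axis=1)
            )
        return np.concatenate(blocks, axis=0)

    def feature_layout(self) -> list[tuple]:
        """Shapes ``(channels, H, W)`` of the feature blocks, layers 2..L."""
        _, h, w = self.input_shape
        return [(layer.out_channels, h, w) for layer in self.layers[1:]]


# --------------------------------------------------------------------------
# optimization
# --------------------------------------------------------------------------

class Adam:
    """Adam with default moment coefficients, one instance per layer."""

    def __init__(self, params: dict[str, np.ndarray],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainConfig:
    """Hyperparameters of one FF training run.

    ``calibrate_init`` rescales each layer's filters once, before training,
    so that the mean initial goodness equals the threshold ``theta``.  The
    rescaling is exact and purely local: ReLU is positively homogeneous, so
    scaling filters by ``c`` scales goodness by ``c**2``, while the
    inter-layer normalization makes downstream layers invariant to it.
    Without it, early epochs are spent inflating activations through a
    saturated sigmoid before any discrimination can be learned.
    """

    epochs: int = 30
    lr: float = 1e-3
    batch_size: int = 50
    K: float = 0.35
    seed: int = 0
    cooldown: bool = True
    track_accuracy: bool = True
    calibrate_init: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.lr <= 0:
            raise ConfigurationError("lr must be > 0")
        if not 0.0 <= self.K <= 1.0:
            raise ConfigurationError("K must lie in [0, 1]")


@dataclass
class TrainHistory:
    """Per-epoch training curves (combined loss, per-layer discrimination)."""

    epochs: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    combined_loss: list = field(default_factory=list)
    train_accuracy: list = field(default_factory=list)
    layer_loss: dict = field(default_factory=dict)      # layer index -> list
    layer_accuracy: dict = field(default_factory=dict)  # layer index -> list

    def to_csv(self, path) -> None:
        lines = ["epoch,layer,metric,value"]
        for i, e in enumerate(self.epochs):
            lines.append(f"{e},,lr,{self.lr[i]}")
            lines.append(f"{e},,combined_loss,{self.combined_loss[i]}")
            if self.train_accuracy[i] is not None:
                lines.append(f"{e},,train_accuracy,{self.train_accuracy[i]}")
            for layer in sorted(self.layer_loss):
                lines.append(f"{e},{layer},discrimination_loss,{self.layer_loss[layer][i]}")
                lines.append(
                    f"{e},{layer},discrimination_accuracy,{self.layer_accuracy[layer][i]}"
                )
        Path(path).write_text("\n".join(lines) + "\n")


def _dloss_dg(g: np.ndarray, theta: float, polarity: str) -> np.ndarray:
    """d(BCE against target 1)/dg for one sample.

    Positive samples: loss = -log sigma(g - theta), derivative sigma(g-theta) - 1.
    Negative samples: loss = -log sigma(theta - g), derivative sigma(g-theta).
    """
    s = expit(g - theta)
    return s - 1.0 if polarity == "positive" else s


def ff_train_step(network: FFNetwork, optimizers: list[Adam], pos: np.ndarray,
                  neg: np.ndarray, lr: float, layer_subset: list[int] | None = None,
                  apply_update: bool = True) -> dict:
    """One combined positive+negative FF step on a ``(N, C, H, W)`` batch pair.

    Every layer receives only its local gradient (the combined loss
    decomposes exactly).  ``layer_subset`` restricts which layers are
    stepped, which is useful for verifying that the combined step equals
    stepping each layer separately.  Returns per-layer diagnostics.
    """
    n = len(pos)
    caches_p = network.forward(pos, training=True)
    caches_n = network.forward(neg, training=True)
    _, h, w = network.input_shape
    stats: dict = {"layers": {}, "gradients": {}}
    indices = range(network.n_layers) if layer_subset is None else layer_subset
    for li in indices:
        layer = network.layers[li]
        theta = layer.theta(h, w)
        cp, cn = caches_p[li], caches_n[li]
        ep = _dloss_dg(cp.g, theta, "positive") / n
        en = _dloss_dg(cn.g, theta, "negative") / n
        gp = layer.local_gradients(cp, ep)
        gn = layer.local_gradients(cn, en)
        grads = {k: gp[k] + gn[k] for k in gp}
        stats["gradients"][li] = grads
        p_pos = layer_probability(cp.g, theta, "positive")
        p_neg = layer_probability(cn.g, theta, "negative")
        loss = float(
            np.mean(
                np.logaddexp(0.0, -(cp.g - theta)))
            + np.mean(np.logaddexp(0.0, -(theta - cn.g)))
        )
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite discrimination loss in layer {li}"
            )
        acc = float(np.mean(np.concatenate([p_pos > 0.5, p_neg > 0.5])))
        stats["layers"][li] = {"loss": loss, "accuracy": acc}
        if apply_update:
            optimizers[li].step(layer.parameters(), grads, lr)
    return stats


def train_ff(network: FFNetwork, data, bank: LabelBank, config: TrainConfig):
    """Train a network with the two-pass local FF procedure.

    Each epoch re-embeds the data: every image gets its true label
    (positive) and a freshly drawn wrong label (negative).  Batches take
    one Adam step per layer on the local gradients of the combined
    positive+negative loss.  Deterministic given ``config.seed``.

    Returns ``(network, TrainHistory)``.
    """
    from .datasets import build_pos_neg  # local import avoids a cycle

    if bank.n_classes != data.n_classes:
        raise ConsistencyError(
            f"bank has {bank.n_classes} labels, data has {data.n_classes} classes"
        )
    optimizers = [Adam(layer.parameters()) for layer in network.layers]
    history = TrainHistory()
    for li in range(network.n_layers):
        history.layer_loss[li] = []
        history.layer_accuracy[li] = []
    loss_layers = network.loss_layer_indices()
    if not loss_layers:
        raise ConfigurationError("no layer is included in the loss")

    n = len(data)
    if config.calibrate_init:
        calib_seed = int(
            np.random.SeedSequence([config.seed, 0]).generate_state(1)[0] % (2 ** 31)
        )
        calib = build_pos_neg(data, bank, config.K, seed=calib_seed)
        n_cal = min(256, n)
        x = calib.positives[:n_cal].transpose(0, 3, 1, 2)
        _, h, w = network.input_shape
        for li, layer in enumerate(network.layers):
            caches = network.forward(x)
            mean_g = float(caches[li].g.mean())
            if mean_g > 0:
                layer.W *= np.sqrt(layer.theta(h, w) / mean_g)

    for e in range(1, config.epochs + 1):
        lr_e = lr_schedule(e, config.epochs, config.lr) if config.cooldown else config.lr
        epoch_seed = int(
            np.random.SeedSequence([config.seed, e]).generate_state(1)[0] % (2 ** 31)
        )
        pairs = build_pos_neg(data, bank, config.K, seed=epoch_seed)
        order = np.random.default_rng(epoch_seed + 1).permutation(n)
        pos = pairs.positives[order].transpose(0, 3, 1, 2)
        neg = pairs.negatives[order].transpose(0, 3, 1, 2)

        sums: dict = {li: {"loss": 0.0, "acc": 0.0} for li in range(network.n_layers)}
        n_batches = 0
        for start in range(0, n, config.batch_size):
            bp = pos[start : start + config.batch_size]
            bn = neg[start : start + config.batch_size]
            try:
                stats = ff_train_step(network, optimizers, bp, bn, lr_e)
            except FloatingPointError as exc:
                raise FloatingPointError(f"{exc} at epoch {e}") from exc
            n_batches += 1
            for li, rec in stats["layers"].items():
                sums[li]["loss"] += rec["loss"]
                sums[li]["acc"] += rec["accuracy"]

        history.epochs.append(e)
        history.lr.append(lr_e)
        for li in range(network.n_layers):
            history.layer_loss[li].append(sums[li]["loss"] / n_batches)
            history.layer_accuracy[li].append(sums[li]["acc"] / n_batches)
        history.combined_loss.append(
            sum(sums[li]["loss"] / n_batches for li in loss_layers)
        )
        if config.track_accuracy:
            from .heads import infer_goodness

            pred, _ = infer_goodness(network, data.images, bank, config.K)
            history.train_accuracy.append(float(np.mean(pred == data.class_ids)))
        else:
            history.train_accuracy.append(None)
    return network, history


# --------------------------------------------------------------------------
# checkpointing
# --------------------------------------------------------------------------

def save_checkpoint(path, network: FFNetwork, bank: LabelBank,
                    config: TrainConfig | None = None, head=None) -> None:
    """Write a checkpoint directory: weights.npz + labels.txt + meta.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays: dict = {}
    for i, layer in enumerate(network.layers):
        arrays[f"layer{i}_W"] = layer.W
        arrays[f"layer{i}_b"] = layer.b
        if layer.norm == "batch_norm":
            arrays[f"layer{i}_gamma"] = layer.gamma
            arrays[f"layer{i}_beta"] = layer.beta
            arrays[f"layer{i}_running_mean"] = layer.running_mean
            arrays[f"layer{i}_running_var"] = layer.running_var
    if head is not None:
        arrays["head_W"] = head.W
        arrays["head_b"] = head.b
    np.savez(path / "weights.npz", **arrays)
    bank.save(path / "labels.txt")
    meta = {
        "input_shape": list(network.input_shape),
        "n_layers": network.n_layers,
        "filters": network.layers[0].out_channels,
        "kernel": network.layers[0].kernel,
        "norm": network.norm,
        "n_classes": network.n_classes,
        "seed": network.seed,
        "include_first_in_loss": network.layers[0].include_in_loss,
        "thetas": network.thetas(),
        "has_head": head is not None,
        "train_config": None if config is None else vars(config),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def load_checkpoint(path):
    """Load a checkpoint directory; returns ``(network, bank, config, head)``."""
    from .heads import LinearHead

    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    network = FFNetwork(
        tuple(meta["input_shape"]),
        n_layers=meta["n_layers"],
        filters=meta["filters"],
        kernel=meta["kernel"],
        norm=meta["norm"],
        n_classes=meta["n_classes"],
        seed=meta["seed"],
        include_first_in_loss=meta["include_first_in_loss"],
    )
    with np.load(path / "weights.npz") as arrays:
        for i, layer in enumerate(network.layers):
            layer.W = arrays[f"layer{i}_W"]
            layer.b = arrays[f"layer{i}_b"]
            if layer.norm == "batch_norm":
                layer.gamma = arrays[f"layer{i}_gamma"]
                layer.beta = arrays[f"layer{i}_beta"]
                layer.running_mean = arrays[f"layer{i}_running_mean"]
                layer.running_var = arrays[f"layer{i}_running_var"]
        head = None
        if meta.get("has_head"):
            head = LinearHead(W=arrays["head_W"].copy(), b=arrays["head_b"].copy())
    bank = LabelBank.load(path / "labels.txt")
    config = TrainConfig(**meta["train_config"]) if meta.get("train_config") else None
    return network, bank, config, head
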