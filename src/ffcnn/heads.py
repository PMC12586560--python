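"""Inference heads and explainability for FF-trained networks.

Two ways to classify with a trained stack:

* **Goodness inference** -- embed each candidate label in turn and pick the
  class whose forward pass yields the largest summed goodness over layers
  2..L (the first layer is excluded).  Costs one forward pass per class.
* **Linear head** -- a softmax classifier on the concatenated post-rectifier
  activations of layers 2..L, trained with cross-entropy while the FF
  weights stay frozen; inference uses a single forward pass with a neutral
  (class-agnostic) label.

Because the head is linear in the feature maps and the maps align 1:1 with
image pixels (same-padded convolutions), Class Activation Maps fall out of
the head weights directly: the per-pixel sum of weight-scaled activations
is a signed evidence map whose total, plus the class bias, reproduces the
class score exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CapabilityError, ConsistencyError
from .ffnet import FFNetwork, goodness, layer_probability
from .labels import LabelBank

__all__ = [
    "LinearHead",
    "CAMap",
    "infer_goodness",
    "fit_linear_head",
    "infer_linear",
    "compute_cam",
    "discrimination_report",
]

#: evaluation batches are chunked to bound the memory of the im2col caches
_EVAL_CHUNK = 256


@dataclass
class LinearHead:
    """Softmax classifier on concatenated layer-2..L activations."""

    W: np.ndarray  # (M, H_features)
    b: np.ndarray  # (M,)

    @property
    def n_classes(self) -> int:
        return self.W.shape[0]


# --------------------------------------------------------------------------
# goodness inference
# --------------------------------------------------------------------------

def infer_goodness(network: FFNetwork, images: np.ndarray, bank: LabelBank,
                   K: float):
    """Classify by maximal summed goodness over layers 2..L.

    Each image is embedded with every candidate label in turn and forward
    passed; ``f[:, m]`` is the goodness of label ``m`` summed over all
    layers except the first.  Prediction is the argmax (ties go to the
    smaller class index).

    Returns ``(predictions, f)``.
    """
    imgs = np.asarray(images, dtype=np.float64)
    if imgs.ndim == 3:
        imgs = imgs[None]
    n, m = len(imgs), bank.n_classes
    f = np.zeros((n, m))
    for cls in range(m):
        embedded = bank.embed(imgs, np.full(n, cls), K)
        # one conceptual forward pass per label; chunked to bound memory
        network.forward_passes += 1
        for start in range(0, n, _EVAL_CHUNK):
            caches = network.forward_images(embedded[start : start + _EVAL_CHUNK])
            network.forward_passes -= 1  # chunking is an implementation detail
            f[start : start + _EVAL_CHUNK, cls] = np.sum(
                [c.g for c in caches[1:]], axis=0
            )
    return f.argmax(axis=1), f


# --------------------------------------------------------------------------
# linear head
# --------------------------------------------------------------------------

def _softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def fit_linear_head(network: FFNetwork, data, bank: LabelBank, K: float,
                    epochs: int = 40, lr: float = 1e-3, batch_size: int = 64,
                    seed: int = 0) -> LinearHead:
    """Train the linear head by softmax cross-entropy; FF weights untouched.

    Inputs are embedded with the neutral label (the mean of all label
    patterns in Fourier mode, the untransformed image in morphology mode),
    so no class information leaks into the features.  The head starts from
    zeros, so zero-epoch training returns the zero head; the objective is
    convex, making the initialization immaterial for converged fits.
    """
    from .ffnet import Adam

    if bank.n_classes != data.n_classes:
        raise ConsistencyError(
            f"bank has {bank.n_classes} labels, data has {data.n_classes} classes"
        )
    embedded = bank.embed_neutral(data.images, K)
    feats = network.features(embedded)  # frozen network: features computed once
    n, h_feat = feats.shape
    m = data.n_classes
    onehot = np.eye(m)[data.class_ids]

    head = LinearHead(W=np.zeros((m, h_feat)), b=np.zeros(m))
    opt = Adam({"W": head.W, "b": head.b})
    rng = np.random.default_rng(seed)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            fb, yb = feats[idx], onehot[idx]
            probs = _softmax(fb @ head.W.T + head.b)
            delta = (probs - yb) / len(idx)
            grads = {"W": delta.T @ fb, "b": delta.sum(axis=0)}
            opt.step({"W": head.W, "b": head.b}, grads, lr)
    return head


def infer_linear(network: FFNetwork, head: LinearHead, images: np.ndarray,
                 bank: LabelBank, K: float):
    """Single forward pass with the neutral label; argmax of head scores.

    Returns ``(predictions, scores)``.
    """
    imgs = np.asarray(images, dtype=np.float64)
    if imgs.ndim == 3:
        imgs = imgs[None]
    embedded = bank.embed_neutral(imgs, K)
    feats = network.features(embedded)
    scores = feats @ head.W.T + head.b
    return scores.argmax(axis=1), scores


# --------------------------------------------------------------------------
# class activation maps
# --------------------------------------------------------------------------

@dataclass
class CAMap:
    """Signed per-layer evidence maps for one image and one class.

    ``per_layer`` maps the network layer index (2..L, 1-based position in
    the stack as index 1..L-1) to an ``(H, W)`` signed map; ``aggregate``
    is their pixel-wise sum.  The conservation identity
    ``aggregate.sum() + bias = class score`` holds for the unnormalized
    maps.
    """

    class_id: int
    per_layer: dict = field(default_factory=dict)
    aggregate: np.ndarray | None = None
    normalized: bool = False

    def normalized_maps(self) -> "CAMap":
        """Min-max display normalization of every map (identity no longer holds)."""
        from .labels import minmax_normalize

        return CAMap(
            class_id=self.class_id,
            per_layer={k: minmax_normalize(v) for k, v in self.per_layer.items()},
            aggregate=minmax_normalize(self.aggregate),
            normalized=True,
        )


def compute_cam(network: FFNetwork, head: LinearHead, image: np.ndarray,
                class_id: int, layer_selection=None) -> CAMap:
    """Class Activation Map from the linear head's weights.

    For each selected layer the map at pixel (r, c) is the sum over that
    layer's channels of ``head_weight(class, activation) * activation``.
    The first layer is not connected to the head and cannot be selected.
    """
    if not 0 <= class_id < head.n_classes:
        raise ConsistencyError(f"class {class_id} outside [0, {head.n_classes})")
    layout = network.feature_layout()
    available = list(range(1, network.n_layers))  # stack indices of head layers
    if layer_selection is None:
        layer_selection = available
    for li in layer_selection:
        if li == 0:
            raise CapabilityError("the first layer is not connected to the head")
        if li not in available:
            raise ConsistencyError(f"layer {li} outside the network (have {available})")

    feats_blocks = {}
    img = np.asarray(image, dtype=np.float64)
    caches = network.forward_images(img[None])
    offset = 0
    for pos, (ch, h, w) in zip(available, layout):
        size = ch * h * w
        feats_blocks[pos] = (
            caches[pos].y[0],                            # (ch, h, w)
            head.W[class_id, offset : offset + size].reshape(ch, h, w),
        )
        offset += size

    per_layer = {}
    for li in layer_selection:
        y, wts = feats_blocks[li]
        per_layer[li] = (wts * y).sum(axis=0)
    aggregate = np.sum([per_layer[li] for li in layer_selection], axis=0)
    return CAMap(class_id=class_id, per_layer=per_layer, aggregate=aggregate)


# --------------------------------------------------------------------------
# discrimination diagnostics
# --------------------------------------------------------------------------

def discrimination_report(network: FFNetwork, pairs) -> dict:
    """Per-layer positive/negative discrimination accuracy and BCE loss.

    A sample counts correct when its polarity-matched probability exceeds
    0.5 (exact ties count as incorrect).  Returns
    ``{layer_index: {"accuracy": ..., "loss": ...}}`` for every layer.
    """
    _, h, w = network.input_shape
    n = len(pairs)
    g_pos = [np.empty(n) for _ in network.layers]
    g_neg = [np.empty(n) for _ in network.layers]
    for start in range(0, n, _EVAL_CHUNK):
        sl = slice(start, start + _EVAL_CHUNK)
        caches_p = network.forward(pairs.positives[sl].transpose(0, 3, 1, 2))
        caches_n = network.forward(pairs.negatives[sl].transpose(0, 3, 1, 2))
        for li in range(network.n_layers):
            g_pos[li][sl] = caches_p[li].g
            g_neg[li][sl] = caches_n[li].g
    report = {}
    for li, layer in enumerate(network.layers):
        theta = layer.theta(h, w)
        p_pos = layer_probability(g_pos[li], theta, "positive")
        p_neg = layer_probability(g_neg[li], theta, "negative")
        correct = np.concatenate([p_pos > 0.5, p_neg > 0.5])
        losses = np.concatenate(
            [
                np.logaddexp(0.0, -(g_pos[li] - theta)),
                np.logaddexp(0.0, -(theta - g_neg[li])),
            ]
        )
        report[li] = {
            "accuracy": float(correct.mean()),
            "loss": float(losses.mean()),
            "include_in_loss": layer.include_in_loss,
        }
    return report
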