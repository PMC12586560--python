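"""Image-classification data: standard containers, synthetic images, pos/neg pairs.

Readers cover the MNIST IDX convention (raw or gzip), CIFAR-10/100 binary
batches and a PNG directory with a tab-separated manifest.  A synthetic
generator produces multi-class geometric-shape images so the whole training
stack can be exercised without any download.  ``build_pos_neg`` creates the
paired positive (true label embedded) / negative (random wrong label)
samples that Forward-Forward training consumes.

All images are ``(N, H, W, C)`` float arrays with intensities in [0, 1],
row-major with the origin at the top-left (IDX convention).
"""

from __future__ import annotations

import gzip
import struct
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator

import numpy as np

from .errors import CapabilityError, ConsistencyError, FormatError
from .labels import LabelBank

__all__ = [
    "ImageSet",
    "SyntheticConfig",
    "PosNegPair",
    "PosNegBatch",
    "read_idx",
    "read_cifar_binary",
    "read_png_dir",
    "generate_synthetic",
    "synthetic_primitive_names",
    "build_pos_neg",
]

IDX_IMAGE_MAGIC = 0x00000803
IDX_LABEL_MAGIC = 0x00000801


@dataclass
class ImageSet:
    """A split of an image-classification dataset.

    ``images``: ``(N, H, W, C)`` float64 in [0, 1]; ``class_ids``: ``(N,)``
    integers in ``[0, n_classes)``.
    """

    images: np.ndarray
    class_ids: np.ndarray
    n_classes: int
    split: str = "train"

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        self.class_ids = np.asarray(self.class_ids, dtype=np.int64)
        if self.images.ndim != 4:
            raise ConsistencyError(
                f"images must be (N, H, W, C), got shape {self.images.shape}"
            )
        if len(self.images) != len(self.class_ids):
            raise ConsistencyError(
                f"{len(self.images)} images but {len(self.class_ids)} class ids"
            )
        if self.images.size and (self.images.min() < 0 or self.images.max() > 1):
            raise ConsistencyError("image intensities must lie in [0, 1]")
        if self.class_ids.size and (
            self.class_ids.min() < 0 or self.class_ids.max() >= self.n_classes
        ):
            raise ConsistencyError("class ids must lie in [0, n_classes)")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def height(self) -> int:
        return self.images.shape[1]

    @property
    def width(self) -> int:
        return self.images.shape[2]

    @property
    def channels(self) -> int:
        return self.images.shape[3]


# --------------------------------------------------------------------------
# standard containers
# --------------------------------------------------------------------------

def _read_maybe_gzip(path) -> bytes:
    path = Path(path)
    raw = path.read_bytes()
    if raw[:2] == b"\x1f\x8b":
        return gzip.decompress(raw)
    return raw


def read_idx(images_path, labels_path) -> ImageSet:
    """Read an IDX image/label file pair (raw or gzip-compressed)."""
    img_bytes = _read_maybe_gzip(images_path)
    lab_bytes = _read_maybe_gzip(labels_path)
    if len(img_bytes) < 16 or len(lab_bytes) < 8:
        raise FormatError("IDX file too short for its header")
    magic, n, h, w = struct.unpack(">IIII", img_bytes[:16])
    if magic != IDX_IMAGE_MAGIC:
        raise FormatError(
            f"bad IDX image magic 0x{magic:08x} (expected 0x{IDX_IMAGE_MAGIC:08x})"
        )
    lmagic, ln = struct.unpack(">II", lab_bytes[:8])
    if lmagic != IDX_LABEL_MAGIC:
        raise FormatError(
            f"bad IDX label magic 0x{lmagic:08x} (expected 0x{IDX_LABEL_MAGIC:08x})"
        )
    if n != ln:
        raise ConsistencyError(f"IDX image count {n} != label count {ln}")
    if len(img_bytes) - 16 != n * h * w:
        raise FormatError("IDX image payload size does not match its header")
    pixels = np.frombuffer(img_bytes, dtype=np.uint8, offset=16).reshape(n, h, w, 1)
    labels = np.frombuffer(lab_bytes, dtype=np.uint8, offset=8).astype(np.int64)
    n_classes = int(labels.max()) + 1 if n else 0
    return ImageSet(pixels / 255.0, labels, n_classes)


def read_cifar_binary(path, variant: str = "cifar10") -> ImageSet:
    """Read a CIFAR-10/100 binary batch.

    CIFAR-10 records are 1 label byte + 3072 channel-major pixel bytes;
    CIFAR-100 records carry a coarse then a fine label byte (the fine label
    is used as the class id, the coarse one is ignored).
    """
    if variant not in ("cifar10", "cifar100"):
        raise ValueError(f"unknown CIFAR variant {variant!r}")
    raw = _read_maybe_gzip(path)
    header = 1 if variant == "cifar10" else 2
    record = header + 3072
    if len(raw) == 0 or len(raw) % record:
        raise FormatError(
            f"{variant} file length {len(raw)} is not a multiple of {record}"
        )
    data = np.frombuffer(raw, dtype=np.uint8).reshape(-1, record)
    labels = data[:, header - 1].astype(np.int64)  # fine label for cifar100
    pixels = data[:, header:].reshape(-1, 3, 32, 32).transpose(0, 2, 3, 1)
    n_classes = 10 if variant == "cifar10" else 100
    return ImageSet(pixels / 255.0, labels, n_classes)


def read_png_dir(directory, manifest_path=None) -> ImageSet:
    """Read a directory of PNGs with a ``filename<TAB>class_id`` manifest."""
    from PIL import Image

    directory = Path(directory)
    manifest = Path(manifest_path) if manifest_path else directory / "manifest.tsv"
    images, labels = [], []
    for line in manifest.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            name, cls = line.split("\t")
        except ValueError as exc:
            raise FormatError(f"malformed manifest line: {line!r}") from exc
        arr = np.asarray(Image.open(directory / name), dtype=np.float64) / 255.0
        if arr.ndim == 2:
            arr = arr[..., None]
        images.append(arr)
        labels.append(int(cls))
    if not images:
        raise FormatError(f"manifest {manifest} lists no images")
    shapes = {im.shape for im in images}
    if len(shapes) != 1:
        raise ConsistencyError(f"images have mixed shapes: {sorted(shapes)}")
    labels_arr = np.asarray(labels, dtype=np.int64)
    return ImageSet(np.stack(images), labels_arr, int(labels_arr.max()) + 1)


# --------------------------------------------------------------------------
# synthetic shapes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions for the synthetic multi-class shape generator.

    ``style`` selects the template family: ``"shapes"`` uses coarse,
    well-separated geometric primitives; ``"fine"`` builds classes that share
    a common outline and differ only in small-scale interior marks, which
    makes class identity a fine-feature problem.
    """

    n_classes: int = 4
    images_per_class: int = 200
    image_side: int = 16
    noise_sd: float = 0.05
    seed: int = 0
    style: str = "shapes"

    def __post_init__(self) -> None:
        if self.image_side < 8:
            raise ValueError("image_side must be >= 8")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.style not in ("shapes", "fine"):
            raise ValueError(f"unknown synthetic style {self.style!r}")


def _shape_templates(side: int) -> list[np.ndarray]:
    m = (side - 1) / 2.0
    r, c = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    dist = np.sqrt((r - m) ** 2 + (c - m) ** 2)
    w = max(1.0, 0.09 * side)
    templates = [
        (dist <= 0.30 * side),                                    # disk
        (np.abs(r - m) <= w) | (np.abs(c - m) <= w),              # cross
        (np.abs(r - m) <= 0.12 * side),                           # horizontal bar
        (dist >= 0.22 * side) & (dist <= 0.36 * side),            # ring
        (np.abs(r - c) <= w) | (np.abs(r + c - 2 * m) <= w),      # saltire
        (np.abs(c - m) <= 0.12 * side),                           # vertical bar
        (np.maximum(np.abs(r - m), np.abs(c - m)) >= 0.22 * side)
        & (np.maximum(np.abs(r - m), np.abs(c - m)) <= 0.36 * side),  # square ring
        ((r - m) >= np.abs(c - m)),                               # downward wedge
        (((r + c) % max(4, side // 4)) < max(2, side // 8)),      # diagonal stripes
        ((r % max(3, side // 5) <= 0) & (c % max(3, side // 5) <= 0)),  # dot grid
    ]
    return [t.astype(np.float64) for t in templates]


_SHAPE_NAMES = [
    "disk", "cross", "hbar", "ring", "saltire",
    "vbar", "square", "wedge", "stripes", "dots",
]


def _fine_templates(side: int, n_classes: int) -> list[np.ndarray]:
    """Classes share a ring outline; only a short central stroke differs."""
    m = (side - 1) / 2.0
    r, c = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    dist = np.sqrt((r - m) ** 2 + (c - m) ** 2)
    base = ((dist >= 0.34 * side) & (dist <= 0.44 * side)).astype(np.float64)
    out = []
    for k in range(n_classes):
        angle = k * np.pi / n_classes
        u = (c - m) * np.cos(angle) + (r - m) * np.sin(angle)
        v = -(c - m) * np.sin(angle) + (r - m) * np.cos(angle)
        stroke = (np.abs(v) <= 0.6) & (np.abs(u) <= 0.22 * side)
        out.append(np.clip(base + stroke.astype(np.float64), 0, 1))
    return out


def synthetic_primitive_names() -> list[str]:
    """Names of the available shape-class templates, in class-id order."""
    return list(_SHAPE_NAMES)


def generate_synthetic(config: SyntheticConfig, split: str = "train") -> ImageSet:
    """Generate a synthetic shape classification split.

    Each class is a distinct template with per-image random cyclic position
    jitter and additive Gaussian noise, clipped to [0, 1].  Deterministic
    given ``(config.seed, split)``.
    """
    side = config.image_side
    if config.style == "shapes":
        templates = _shape_templates(side)
        if config.n_classes > len(templates):
            raise CapabilityError(
                f"only {len(templates)} shape templates available, "
                f"{config.n_classes} classes requested"
            )
        templates = templates[: config.n_classes]
        max_jitter = side // 8
    else:
        templates = _fine_templates(side, config.n_classes)
        max_jitter = 1  # keep the fine marks away from wrap-around

    split_index = {"train": 0, "val": 1, "test": 2}.get(split)
    if split_index is None:
        raise ValueError(f"unknown split {split!r}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, split_index]))

    n = config.n_classes * config.images_per_class
    images = np.empty((n, side, side, 1), dtype=np.float64)
    class_ids = np.repeat(np.arange(config.n_classes), config.images_per_class)
    for i, cls in enumerate(class_ids):
        img = templates[cls]
        if max_jitter:
            dy, dx = rng.integers(-max_jitter, max_jitter + 1, size=2)
            img = np.roll(img, (dy, dx), axis=(0, 1))
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, img.shape)
        images[i, ..., 0] = np.clip(img, 0.0, 1.0)
    return ImageSet(images, class_ids, config.n_classes, split=split)


# --------------------------------------------------------------------------
# positive / negative pairing
# --------------------------------------------------------------------------

@dataclass
class PosNegPair:
    """One correctly labeled image and one wrongly labeled counterpart."""

    positive: np.ndarray
    negative: np.ndarray
    true_class: int
    negative_class: int


class PosNegBatch:
    """A stacked sequence of :class:`PosNegPair` (arrays shared, not copied)."""

    def __init__(self, positives, negatives, true_classes, negative_classes):
        self.positives = positives
        self.negatives = negatives
        self.true_classes = np.asarray(true_classes, dtype=np.int64)
        self.negative_classes = np.asarray(negative_classes, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.positives)

    def __getitem__(self, i: int) -> PosNegPair:
        return PosNegPair(
            self.positives[i],
            self.negatives[i],
            int(self.true_classes[i]),
            int(self.negative_classes[i]),
        )

    def __iter__(self) -> Iterator[PosNegPair]:
        for i in range(len(self)):
            yield self[i]


def build_pos_neg(data: ImageSet, bank: LabelBank, K: float, seed: int = 0) -> PosNegBatch:
    """Embed true and random-wrong labels into every image.

    The wrong class is drawn uniformly from the ``M - 1`` other classes,
    deterministically given ``seed``.
    """
    if bank.n_classes < 2:
        raise CapabilityError("need at least 2 classes to draw a wrong label")
    if bank.n_classes != data.n_classes:
        raise ConsistencyError(
            f"bank has {bank.n_classes} labels but data has {data.n_classes} classes"
        )
    rng = np.random.default_rng(seed)
    m = bank.n_classes
    offsets = rng.integers(1, m, size=len(data))
    neg_classes = (data.class_ids + offsets) % m
    positives = bank.embed(data.images, data.class_ids, K)
    negatives = bank.embed(data.images, neg_classes, K)
    return PosNegBatch(positives, negatives, data.class_ids.copy(), neg_classes)
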