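"""Spatially-extended class labels.

Forward-Forward training of convolutional layers needs the class label to be
visible at every filter position, not just in a corner of the image.  Two
label families provide that:

* **Fourier labels** -- each class is a sinusoidal grating with its own
  frequency, orientation and phase.  The grating is blended into the image.
* **Morphology labels** -- each class is a fixed, deterministic program of
  morphological transforms (rotations, flips, cyclic shifts, intensity
  inversion, grayscale dilation/erosion) applied to the input image itself.
  The transformed image is blended into the original, so the label carries
  no pattern of its own and forces the network to attend to image structure.

The blend weight ``K`` (label intensity) is the relative contribution of the
label component; after blending every image is min-max renormalized to
[0, 1].

For many-class problems a label bank can be assembled by generating a large
candidate pool and greedily selecting the subset that minimizes the maximal
pairwise |Pearson correlation| between rendered labels.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.morphology import dilation as _gray_dilation
from skimage.morphology import disk as _disk_footprint
from skimage.morphology import erosion as _gray_erosion
from skimage.transform import rotate as _sk_rotate

from .errors import CapabilityError, ConsistencyError

__all__ = [
    "FourierLabelSpec",
    "MorphOp",
    "MorphologyLabelSpec",
    "LabelBank",
    "render_fourier",
    "apply_morphology",
    "embed_label",
    "embed_batch",
    "minmax_normalize",
    "pairwise_correlation",
    "generate_candidates",
    "select_diverse_subset",
    "default_fourier_bank",
    "default_morphology_bank",
]


# --------------------------------------------------------------------------
# label specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FourierLabelSpec:
    """One class label as a gray-value wave.

    Parameters
    ----------
    frequency : float
        Cycles per image side (the longer side for non-square images).
    orientation : float
        Wave direction in radians, in ``[0, pi)``.
    phase : float
        Phase offset in radians, in ``[0, 2*pi)``.
    """

    frequency: float
    orientation: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise ValueError(f"frequency must be > 0, got {self.frequency}")
        if not 0.0 <= self.orientation < math.pi:
            raise ValueError(f"orientation must lie in [0, pi), got {self.orientation}")
        if not 0.0 <= self.phase < 2 * math.pi:
            raise ValueError(f"phase must lie in [0, 2*pi), got {self.phase}")


_MORPH_ARITY = {
    "rotate": 1,     # angle in degrees (counter-clockwise)
    "flip_h": 0,     # mirror columns
    "flip_v": 0,     # mirror rows
    "shift": 2,      # cyclic shift by (dx, dy) pixels
    "invert": 0,     # x -> 1 - x
    "dilate": 1,     # grayscale dilation, disk radius in pixels
    "erode": 1,      # grayscale erosion, disk radius in pixels
}


@dataclass(frozen=True)
class MorphOp:
    """A single deterministic morphological primitive."""

    name: str
    args: tuple = ()

    def __post_init__(self) -> None:
        if self.name not in _MORPH_ARITY:
            raise CapabilityError(
                f"unknown morphological primitive {self.name!r}; "
                f"known: {sorted(_MORPH_ARITY)}"
            )
        object.__setattr__(self, "args", tuple(self.args))
        if len(self.args) != _MORPH_ARITY[self.name]:
            raise ValueError(
                f"{self.name} takes {_MORPH_ARITY[self.name]} argument(s), "
                f"got {len(self.args)}"
            )


@dataclass(frozen=True)
class MorphologyLabelSpec:
    """One class label as an ordered program of morphological primitives."""

    ops: tuple

    def __post_init__(self) -> None:
        ops = tuple(self.ops)
        if not ops:
            raise ValueError("a morphology label needs at least one primitive")
        object.__setattr__(self, "ops", ops)


# --------------------------------------------------------------------------
# rendering / applying labels
# --------------------------------------------------------------------------

def render_fourier(spec: FourierLabelSpec, height: int, width: int) -> np.ndarray:
    """Render a Fourier label as an ``(height, width)`` image in [0, 1].

    Pixel (r, c) takes the value
    ``0.5 + 0.5 * sin(2*pi*f*(c*cos(a) + r*sin(a))/side + phi)`` with
    ``side = max(height, width)``, so ``frequency`` counts full cycles across
    the longer image side.
    """
    if height < 1 or width < 1:
        raise ValueError("pattern dimensions must be >= 1")
    side = max(height, width)
    r, c = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
    proj = c * math.cos(spec.orientation) + r * math.sin(spec.orientation)
    return 0.5 + 0.5 * np.sin(2.0 * math.pi * spec.frequency * proj / side + spec.phase)


def _apply_op(op: MorphOp, img: np.ndarray) -> np.ndarray:
    if op.name == "rotate":
        angle = float(op.args[0]) % 360.0
        if angle % 90.0 == 0.0:
            return np.rot90(img, int(angle // 90) % 4, axes=(0, 1))
        return _sk_rotate(img, angle, preserve_range=True, mode="edge")
    if op.name == "flip_h":
        return img[:, ::-1]
    if op.name == "flip_v":
        return img[::-1]
    if op.name == "shift":
        dx, dy = int(op.args[0]), int(op.args[1])
        return np.roll(img, (dy, dx), axis=(0, 1))
    if op.name == "invert":
        return 1.0 - img
    if op.name in ("dilate", "erode"):
        fn = _gray_dilation if op.name == "dilate" else _gray_erosion
        footprint = _disk_footprint(int(op.args[0]))
        if img.ndim == 2:
            return fn(img, footprint)
        return np.stack(
            [fn(img[..., ch], footprint) for ch in range(img.shape[-1])], axis=-1
        )
    raise CapabilityError(f"unknown morphological primitive {op.name!r}")


def apply_morphology(spec: MorphologyLabelSpec, image: np.ndarray) -> np.ndarray:
    """Apply the ordered transform program; output clipped to [0, 1]."""
    out = np.asarray(image, dtype=np.float64)
    for op in spec.ops:
        out = _apply_op(op, out)
    return np.clip(out, 0.0, 1.0)


# --------------------------------------------------------------------------
# embedding
# --------------------------------------------------------------------------

def minmax_normalize(images: np.ndarray) -> np.ndarray:
    """Min-max rescaling to [0, 1]; constant images map to 0.

    Arrays with 4 dimensions ``(N, H, W, C)`` are rescaled per image;
    anything else is treated as a single image.
    """
    x = np.asarray(images, dtype=np.float64)
    if x.ndim != 4:
        lo, hi = x.min(), x.max()
        if hi - lo < 1e-12:
            return np.zeros_like(x)
        return (x - lo) / (hi - lo)
    flat = x.reshape(x.shape[0], -1)
    lo = flat.min(axis=1).reshape((-1,) + (1,) * (x.ndim - 1))
    hi = flat.max(axis=1).reshape((-1,) + (1,) * (x.ndim - 1))
    rng = hi - lo
    safe = np.where(rng < 1e-12, 1.0, rng)
    out = (x - lo) / safe
    out[np.broadcast_to(rng < 1e-12, out.shape)] = 0.0
    return out


def embed_label(image: np.ndarray, label_component: np.ndarray, K: float) -> np.ndarray:
    """Blend a label component into one image and renormalize.

    ``blended = (1 - K) * image + K * label_component`` followed by per-image
    min-max normalization to [0, 1].  ``label_component`` is the rendered
    Fourier pattern (broadcast across channels) or the morphologically
    transformed image.
    """
    if not 0.0 <= K <= 1.0:
        raise ValueError(f"label intensity K must lie in [0, 1], got {K}")
    img = np.asarray(image, dtype=np.float64)
    comp = np.asarray(label_component, dtype=np.float64)
    if comp.ndim == 2 and img.ndim == 3:
        comp = comp[..., None]
    if comp.shape != img.shape and not (
        comp.ndim == img.ndim and comp.shape[:-1] == img.shape[:-1] and comp.shape[-1] == 1
    ):
        raise ConsistencyError(
            f"label component shape {comp.shape} does not match image {img.shape}"
        )
    blended = (1.0 - K) * img + K * comp
    return minmax_normalize(blended)


def embed_batch(images: np.ndarray, components: np.ndarray, K: float) -> np.ndarray:
    """Vectorized :func:`embed_label` over a batch ``(N, H, W, C)``."""
    if not 0.0 <= K <= 1.0:
        raise ValueError(f"label intensity K must lie in [0, 1], got {K}")
    imgs = np.asarray(images, dtype=np.float64)
    comp = np.asarray(components, dtype=np.float64)
    if comp.ndim == imgs.ndim - 1:
        comp = comp[..., None]
    if comp.shape[:-1] != imgs.shape[:-1]:
        raise ConsistencyError(
            f"component batch shape {comp.shape} does not match images {imgs.shape}"
        )
    blended = (1.0 - K) * imgs + K * comp
    flat = blended.reshape(blended.shape[0], -1)
    lo = flat.min(axis=1)[:, None, None, None]
    hi = flat.max(axis=1)[:, None, None, None]
    rng = hi - lo
    safe = np.where(rng < 1e-12, 1.0, rng)
    out = (blended - lo) / safe
    out[np.broadcast_to(rng < 1e-12, out.shape)] = 0.0
    return out


# --------------------------------------------------------------------------
# label banks
# --------------------------------------------------------------------------

class LabelBank:
    """An ordered set of per-class label specs (all-Fourier or all-morphology).

    Rendered Fourier patterns are cached per image shape.
    """

    def __init__(self, specs: Sequence, mode: str):
        if mode not in ("fourier", "morphology"):
            raise ValueError(f"unknown label mode {mode!r}")
        specs = list(specs)
        if not specs:
            raise ValueError("a label bank needs at least one spec")
        want = FourierLabelSpec if mode == "fourier" else MorphologyLabelSpec
        for s in specs:
            if not isinstance(s, want):
                raise ConsistencyError(
                    f"spec {s!r} does not match bank mode {mode!r}"
                )
        if len(set(specs)) != len(specs):
            raise ConsistencyError("label specs in a bank must be pairwise distinct")
        self.specs = specs
        self.mode = mode
        self._pattern_cache: dict = {}

    def __len__(self) -> int:
        return len(self.specs)

    @property
    def n_classes(self) -> int:
        return len(self.specs)

    # -- rendering ---------------------------------------------------------

    def patterns(self, height: int, width: int) -> np.ndarray:
        """All Fourier patterns stacked as ``(M, height, width)`` (cached)."""
        if self.mode != "fourier":
            raise CapabilityError("patterns() is only defined for Fourier banks")
        key = (height, width)
        if key not in self._pattern_cache:
            self._pattern_cache[key] = np.stack(
                [render_fourier(s, height, width) for s in self.specs]
            )
        return self._pattern_cache[key]

    def components_for(self, images: np.ndarray, class_ids: np.ndarray) -> np.ndarray:
        """Per-image label component for the given class of each image."""
        imgs = np.asarray(images, dtype=np.float64)
        ids = np.asarray(class_ids, dtype=int)
        if ids.max(initial=-1) >= len(self) or ids.min(initial=0) < 0:
            raise ConsistencyError("class id outside the bank")
        if self.mode == "fourier":
            return self.patterns(imgs.shape[1], imgs.shape[2])[ids]
        return np.stack(
            [apply_morphology(self.specs[c], img) for img, c in zip(imgs, ids)]
        )

    def neutral_components(self, images: np.ndarray) -> np.ndarray:
        """Class-agnostic label component (mean pattern / identity image)."""
        imgs = np.asarray(images, dtype=np.float64)
        if self.mode == "fourier":
            mean = self.patterns(imgs.shape[1], imgs.shape[2]).mean(axis=0)
            return np.broadcast_to(mean, (imgs.shape[0],) + mean.shape).copy()
        return imgs.copy()

    # -- embedding ---------------------------------------------------------

    def embed(self, images: np.ndarray, class_ids: np.ndarray, K: float) -> np.ndarray:
        return embed_batch(images, self.components_for(images, class_ids), K)

    def embed_neutral(self, images: np.ndarray, K: float) -> np.ndarray:
        return embed_batch(images, self.neutral_components(images), K)

    # -- plain-text sidecar ------------------------------------------------

    def save(self, path) -> None:
        lines = [f"mode\t{self.mode}"]
        for i, spec in enumerate(self.specs):
            if self.mode == "fourier":
                lines.append(
                    f"{i}\tfrequency={spec.frequency!r}\t"
                    f"orientation={spec.orientation!r}\tphase={spec.phase!r}"
                )
            else:
                ops = "|".join(
                    op.name + (":" + ",".join(str(a) for a in op.args) if op.args else "")
                    for op in spec.ops
                )
                lines.append(f"{i}\t{ops}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "LabelBank":
        lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
        header = lines[0].split("\t")
        if header[0] != "mode" or len(header) != 2:
            raise ValueError(f"malformed label bank file {path}")
        mode = header[1]
        specs: list = []
        for ln in lines[1:]:
            fields = ln.split("\t")
            if mode == "fourier":
                kv = dict(f.split("=", 1) for f in fields[1:])
                specs.append(
                    FourierLabelSpec(
                        frequency=float(kv["frequency"]),
                        orientation=float(kv["orientation"]),
                        phase=float(kv["phase"]),
                    )
                )
            else:
                ops = []
                for tok in fields[1].split("|"):
                    if ":" in tok:
                        name, raw = tok.split(":", 1)
                        args = tuple(
                            float(a) if re.search(r"[.eE]", a) else int(a)
                            for a in raw.split(",")
                        )
                    else:
                        name, args = tok, ()
                    ops.append(MorphOp(name, args))
                specs.append(MorphologyLabelSpec(tuple(ops)))
        return cls(specs, mode)


# --------------------------------------------------------------------------
# correlation and diversity selection
# --------------------------------------------------------------------------

def _spec_rows(specs: Sequence, mode: str, probe) -> np.ndarray:
    """Flattened rendered label per spec, as rows of a matrix."""
    if mode == "fourier":
        if isinstance(probe, np.ndarray):
            h, w = probe.shape[:2]
        else:
            h, w = probe
        return np.stack([render_fourier(s, h, w).ravel() for s in specs])
    probe_img = np.asarray(probe, dtype=np.float64)
    return np.stack([apply_morphology(s, probe_img).ravel() for s in specs])


def _correlation_matrix(rows: np.ndarray) -> np.ndarray:
    centered = rows - rows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    if np.any(norms < 1e-12):
        bad = int(np.argmin(norms))
        raise ValueError(
            f"label {bad} renders to a constant pattern; correlation is undefined"
        )
    corr = (centered @ centered.T) / np.outer(norms, norms)
    np.fill_diagonal(corr, 1.0)
    return corr


def pairwise_correlation(bank: LabelBank, probe) -> np.ndarray:
    """M x M Pearson correlations between rendered labels.

    ``probe`` is an ``(H, W)`` shape tuple (or an image, whose shape is used)
    for Fourier banks, and a probe image for morphology banks.
    """
    return _correlation_matrix(_spec_rows(bank.specs, bank.mode, probe))


def generate_candidates(mode: str, n_candidates: int, param_ranges: dict | None = None,
                        seed: int = 0) -> list:
    """Sample ``n_candidates`` unique label specs.

    Fourier mode draws (frequency, orientation, phase) uniformly from
    ``param_ranges`` (defaults: frequency (1, 8), orientation [0, pi),
    phase [0, 2*pi)).  Morphology mode samples random programs of 1-3
    primitives with random parameters.  Deterministic given ``seed``.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    rng = np.random.default_rng(seed)
    seen: set = set()
    out: list = []
    max_tries = 200 * n_candidates + 100

    if mode == "fourier":
        ranges = {
            "frequency": (1.0, 8.0),
            "orientation": (0.0, math.pi),
            "phase": (0.0, 2 * math.pi),
        }
        if param_ranges:
            ranges.update(param_ranges)
        for _ in range(max_tries):
            if len(out) == n_candidates:
                break
            f = round(float(rng.uniform(*ranges["frequency"])), 6)
            lo, hi = ranges["orientation"]
            o = round(float(rng.uniform(lo, max(lo, min(hi, math.pi) - 1e-9))), 6)
            lo, hi = ranges["phase"]
            p = round(float(rng.uniform(lo, max(lo, min(hi, 2 * math.pi) - 1e-9))), 6)
            if f <= 0:
                continue
            key = (f, o, p)
            if key in seen:
                continue
            seen.add(key)
            out.append(FourierLabelSpec(f, o, p))
    elif mode == "morphology":
        names = list(_MORPH_ARITY)
        for _ in range(max_tries):
            if len(out) == n_candidates:
                break
            length = int(rng.integers(1, 4))
            ops = []
            for _ in range(length):
                name = names[int(rng.integers(len(names)))]
                if name == "rotate":
                    args = (float(rng.choice([45, 90, 135, 180, 225, 270, 315])),)
                elif name == "shift":
                    dx, dy = 0, 0
                    while (dx, dy) == (0, 0):
                        dx, dy = (int(v) for v in rng.integers(-5, 6, size=2))
                    args = (dx, dy)
                elif name in ("dilate", "erode"):
                    args = (int(rng.integers(1, 3)),)
                else:
                    args = ()
                ops.append(MorphOp(name, args))
            spec = MorphologyLabelSpec(tuple(ops))
            if spec in seen:
                continue
            seen.add(spec)
            out.append(spec)
    else:
        raise ValueError(f"unknown label mode {mode!r}")

    if len(out) < n_candidates:
        raise CapabilityError(
            f"parameter ranges too small to yield {n_candidates} unique specs "
            f"(got {len(out)})"
        )
    return out


def select_diverse_subset(candidates: Sequence, n_select: int, probe):
    """Greedy min-max-|correlation| subset selection.

    Starts from the candidate pair with the lowest |correlation|, then
    repeatedly adds the candidate that minimizes the maximum |correlation|
    to the already-selected set (ties broken by lower candidate index).

    Returns ``(bank, achieved)`` where ``achieved`` is the maximal internal
    |correlation| of the selected set.
    """
    candidates = list(candidates)
    if not 1 <= n_select <= len(candidates):
        raise ValueError(
            f"n_select must lie in [1, {len(candidates)}], got {n_select}"
        )
    mode = "fourier" if isinstance(candidates[0], FourierLabelSpec) else "morphology"
    corr = np.abs(_correlation_matrix(_spec_rows(candidates, mode, probe)))

    n = len(candidates)
    if n_select == 1:
        return LabelBank([candidates[0]], mode), 0.0
    if n_select == n:
        selected = list(range(n))
    else:
        iu, ju = np.triu_indices(n, k=1)
        best = int(np.argmin(corr[iu, ju]))  # argmin returns first, i.e. lowest index pair
        selected = [int(iu[best]), int(ju[best])]
        while len(selected) < n_select:
            best_k, best_val = None, np.inf
            for k in range(n):
                if k in selected:
                    continue
                val = float(corr[k, selected].max())
                if val < best_val:
                    best_k, best_val = k, val
            selected.append(best_k)
    selected = sorted(selected)
    sub = corr[np.ix_(selected, selected)]
    achieved = float(np.max(sub - np.eye(len(selected)))) if len(selected) > 1 else 0.0
    return LabelBank([candidates[i] for i in selected], mode), achieved


# --------------------------------------------------------------------------
# default banks
# --------------------------------------------------------------------------

def default_fourier_bank(n_classes: int, phase: float = 0.0) -> LabelBank:
    """Default grating bank: frequencies {2,3,4,5} x orientations {0,45,90,135} deg.

    Enumeration is frequency-major (all four orientations of frequency 2
    first), taking the first ``n_classes`` combinations; phase 0 throughout.
    """
    freqs = [2.0, 3.0, 4.0, 5.0]
    orients = [0.0, math.pi / 4, math.pi / 2, 3 * math.pi / 4]
    combos = [(f, o) for f in freqs for o in orients]
    if n_classes > len(combos):
        raise CapabilityError(
            f"default Fourier bank supports at most {len(combos)} classes; "
            "use generate_candidates + select_diverse_subset for more"
        )
    return LabelBank(
        [FourierLabelSpec(f, o, phase) for f, o in combos[:n_classes]], "fourier"
    )


_DEFAULT_MORPH_PROGRAMS = [
    (MorphOp("rotate", (90.0,)),),
    (MorphOp("rotate", (180.0,)),),
    (MorphOp("rotate", (270.0,)),),
    (MorphOp("flip_h"),),
    (MorphOp("flip_v"),),
    (MorphOp("invert"),),
    (MorphOp("shift", (3, 5)),),
    (MorphOp("dilate", (1,)),),
    (MorphOp("erode", (1,)),),
    (MorphOp("flip_h"), MorphOp("rotate", (90.0,))),
]


def default_morphology_bank(n_classes: int) -> LabelBank:
    """Default 10-program morphology bank (fixed, documented order)."""
    if n_classes > len(_DEFAULT_MORPH_PROGRAMS):
        raise CapabilityError(
            f"default morphology bank supports at most "
            f"{len(_DEFAULT_MORPH_PROGRAMS)} classes; "
            "use generate_candidates + select_diverse_subset for more"
        )
    return LabelBank(
        [MorphologyLabelSpec(p) for p in _DEFAULT_MORPH_PROGRAMS[:n_classes]],
        "morphology",
    )
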