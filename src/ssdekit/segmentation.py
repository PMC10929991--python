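"""4-class semantic segmentation of axial thoracic CT.

Two segmenters share one output contract (a :class:`~ssdekit.geometry.TissueClassMap`
over {background, lung, other-tissue, bone}):

* :func:`threshold_segment` — a deterministic HU-threshold reference
  segmenter.  Body = pixels above −400 HU, hole-filled, largest connected
  component; within the body, lung below −300 HU, bone above +150 HU,
  other tissue in between.
* A trainable U-Net with a residual down-sampling encoder (five stages of
  residual convolution blocks with 2x2 max pooling), a symmetric 2x
  nearest-neighbour up-sampling path with skip concatenations, and a final
  1x1 convolution + softmax over the four classes.

Inputs to the network are normalised by clipping HU to [−1000, +1000] and
scaling to [0, 1] — a fixed physical window, so normalisation is
data-independent and reproducible.  Training is seeded end to end (split,
weight initialisation, shuffling) and, being pure NumPy, bit-for-bit
deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from skimage.transform import resize

from . import _nn
from .geometry import BACKGROUND, BONE, LUNG, TISSUE, TissueClassMap, extract_body_mask

__all__ = [
    "ThresholdConfig",
    "SegmenterConfig",
    "TrainingHistory",
    "IoUReport",
    "threshold_segment",
    "mean_iou",
    "build_segmenter",
    "train_segmenter",
    "predict_classmap",
    "save_checkpoint",
    "load_checkpoint",
    "UNetSegmenter",
]

_CLASS_ORDER = ("background", "lung", "tissue", "bone")


@dataclass(frozen=True)
class ThresholdConfig:
    """HU thresholds for the deterministic reference segmenter."""

    body_hu: float = -400.0  # body mask: HU above this
    lung_hu: float = -300.0  # within body: lung below this
    bone_hu: float = 150.0   # within body: bone above this


@dataclass(frozen=True)
class SegmenterConfig:
    """U-Net architecture and training hyper-parameters.

    Defaults are desk-scale: 128 px inputs, 30 epochs, no pre-trained
    encoder.  ``input_size`` must be divisible by 16 (four 2x2 poolings).
    """

    input_size: int = 128
    n_classes: int = 4
    encoder_depth: int = 5
    base_channels: int = 8
    epochs: int = 30
    holdout_fraction: float = 0.20
    learning_rate: float = 1e-3
    batch_size: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.input_size % 16 != 0:
            raise ValueError("input_size must be divisible by 16")
        if self.encoder_depth != 5:
            raise ValueError("encoder has five residual stages")


@dataclass
class TrainingHistory:
    """Per-epoch loss and mean IoU on the training and holdout splits."""

    train_loss: list[float] = field(default_factory=list)
    train_miou: list[float] = field(default_factory=list)
    holdout_loss: list[float] = field(default_factory=list)
    holdout_miou: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class IoUReport:
    """Per-class Jaccard index (intersection over union) and their mean.

    A class absent from both rasters scores 1.0 by convention, so images
    that genuinely lack a tissue (e.g. a slice without bone) do not zero
    the mean.
    """

    background: float
    lung: float
    tissue: float
    bone: float

    @property
    def mean(self) -> float:
        return (self.background + self.lung + self.tissue + self.bone) / 4.0

    def per_class(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in _CLASS_ORDER}


def threshold_segment(
    hu_image: np.ndarray,
    pixel_spacing: tuple[float, float],
    thresholds: ThresholdConfig | None = None,
) -> TissueClassMap:
    """Deterministic HU-threshold segmentation into the four tissue classes."""
    t = thresholds or ThresholdConfig()
    body = hu_image > t.body_hu
    labels = np.full(hu_image.shape, BACKGROUND, dtype=np.uint8)
    if body.any():
        from scipy import ndimage

        body = ndimage.binary_fill_holes(body)
        lab, n = ndimage.label(body)
        if n > 1:
            sizes = ndimage.sum_labels(body, lab, index=np.arange(1, n + 1))
            body = lab == (1 + int(np.argmax(sizes)))
        labels[body] = TISSUE
        labels[body & (hu_image < t.lung_hu)] = LUNG
        labels[body & (hu_image > t.bone_hu)] = BONE
    return TissueClassMap(labels=labels, pixel_spacing=tuple(pixel_spacing))


def mean_iou(pred: TissueClassMap | np.ndarray, truth: TissueClassMap | np.ndarray) -> IoUReport:
    """Per-class and mean IoU between two class maps of equal shape."""
    a = pred.labels if isinstance(pred, TissueClassMap) else np.asarray(pred)
    b = truth.labels if isinstance(truth, TissueClassMap) else np.asarray(truth)
    if a.shape != b.shape:
        raise ValueError("class maps have different shapes")
    scores = {}
    for cid, cname in zip((BACKGROUND, LUNG, TISSUE, BONE), _CLASS_ORDER):
        pa, pb = a == cid, b == cid
        union = np.logical_or(pa, pb).sum()
        scores[cname] = 1.0 if union == 0 else float(np.logical_and(pa, pb).sum() / union)
    return IoUReport(**scores)


class UNetSegmenter:
    """U-Net with a five-stage residual encoder and skip-concatenation decoder."""

    def __init__(self, config: SegmenterConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.base_channels
        widths = [c, 2 * c, 4 * c, 8 * c, 8 * c]
        self.enc = [_nn.ResBlock(rng, 1, widths[0])]
        for i in range(1, 5):
            self.enc.append(_nn.ResBlock(rng, widths[i - 1], widths[i]))
        self.pools = [_nn.MaxPool2() for _ in range(4)]
        self.ups = [_nn.Upsample2() for _ in range(4)]
        # decoder blocks, deepest first; input = upsampled + skip channels
        self.dec = [
            _nn.ResBlock(rng, widths[4] + widths[3], widths[2]),
            _nn.ResBlock(rng, widths[2] + widths[2], widths[1]),
            _nn.ResBlock(rng, widths[1] + widths[1], widths[0]),
            _nn.ResBlock(rng, widths[0] + widths[0], widths[0]),
        ]
        self.head = _nn.Conv2D(rng, widths[0], config.n_classes, 1)
        self._skip_channels = [widths[3], widths[2], widths[1], widths[0]]

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits (N, 4, H, W) for a normalised batch (N, 1, H, W)."""
        if x.shape[2] % 16 or x.shape[3] % 16:
            raise ValueError("spatial dimensions must be divisible by 16")
        skips = []
        h = x.astype(np.float32)
        for i in range(5):
            if i > 0:
                h = self.pools[i - 1].forward(h)
            h = self.enc[i].forward(h)
            if i < 4:
                skips.append(h)
        for i, dec in enumerate(self.dec):
            h = self.ups[i].forward(h)
            h = np.concatenate([h, skips[3 - i]], axis=1)
            h = dec.forward(h)
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        skip_grads: list[np.ndarray | None] = [None] * 4
        for i in reversed(range(4)):
            d = self.dec[i].backward(d)
            n_up = d.shape[1] - self._skip_channels[i]
            d, ds = d[:, :n_up], d[:, n_up:]
            skip_grads[3 - i] = ds
            d = self.ups[i].backward(d)
        for i in reversed(range(5)):
            d = self.enc[i].backward(d)
            if i > 0:
                d = self.pools[i - 1].backward(d)
                d = d + skip_grads[i - 1] if skip_grads[i - 1] is not None else d
        # ordering note: skip grad for stage i joins after unpooling into stage i's output
        return None

    def params(self):
        out = []
        for block in self.enc + self.dec:
            out += block.params()
        out += self.head.params()
        return out

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _nn.softmax(self.forward(x))


def build_segmenter(config: SegmenterConfig | None = None) -> UNetSegmenter:
    """Construct an (untrained) U-Net per the configuration."""
    return UNetSegmenter(config or SegmenterConfig())


def normalise_hu(hu_image: np.ndarray) -> np.ndarray:
    """Clip HU to [-1000, 1000] and scale to [0, 1]."""
    return ((np.clip(hu_image, -1000.0, 1000.0) + 1000.0) / 2000.0).astype(np.float32)


def _to_model_grid(hu_image: np.ndarray, size: int) -> np.ndarray:
    img = normalise_hu(hu_image)
    if img.shape != (size, size):
        img = resize(img, (size, size), order=1, preserve_range=True,
                     anti_aliasing=False).astype(np.float32)
    return img


def _labels_to_grid(labels: np.ndarray, size: int) -> np.ndarray:
    if labels.shape != (size, size):
        labels = resize(labels, (size, size), order=0, preserve_range=True,
                        anti_aliasing=False)
    return labels.astype(np.int64)


def train_segmenter(
    images: list[np.ndarray],
    masks: list[TissueClassMap | np.ndarray],
    config: SegmenterConfig | None = None,
) -> tuple[UNetSegmenter, TrainingHistory]:
    """Train the U-Net on HU images and their class-map labels.

    Splits off ``holdout_fraction`` of the pairs for evaluation, minimises
    per-pixel multi-class cross entropy with Adam, and records loss and
    mean IoU per epoch on both splits.  Deterministic for a fixed config
    seed.
    """
    config = config or SegmenterConfig()
    if len(images) < 10:
        raise ValueError("need at least 10 image/mask pairs")
    if len(images) != len(masks):
        raise ValueError("images and masks differ in length")
    size = config.input_size
    xs = np.stack([_to_model_grid(np.asarray(im, dtype=float), size) for im in images])
    ys = np.stack([
        _labels_to_grid(m.labels if isinstance(m, TissueClassMap) else np.asarray(m), size)
        for m in masks
    ])
    for im, m in zip(images, masks):
        lab = m.labels if isinstance(m, TissueClassMap) else np.asarray(m)
        if np.asarray(im).shape != lab.shape:
            raise ValueError("image/mask shape mismatch")

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(xs))
    n_hold = max(1, int(round(config.holdout_fraction * len(xs))))
    hold_idx, train_idx = order[:n_hold], order[n_hold:]
    x_tr, y_tr = xs[train_idx], ys[train_idx]
    x_ho, y_ho = xs[hold_idx], ys[hold_idx]

    model = UNetSegmenter(config)
    opt = _nn.Adam(model.params(), lr=config.learning_rate)
    history = TrainingHistory()

    def _eval(xb: np.ndarray, yb: np.ndarray) -> tuple[float, float]:
        losses, ious = [], []
        for i in range(0, len(xb), config.batch_size):
            x = xb[i:i + config.batch_size][:, None]
            y = yb[i:i + config.batch_size]
            logits = model.forward(x)
            loss, _ = _nn.softmax_cross_entropy(logits, y)
            losses.append(loss * len(y))
            pred = logits.argmax(axis=1)
            ious += [mean_iou(p, t).mean for p, t in zip(pred, y)]
        return float(np.sum(losses) / len(xb)), float(np.mean(ious))

    for _ in range(config.epochs):
        perm = rng.permutation(len(x_tr))
        ep_loss, ep_iou, n_seen = 0.0, [], 0
        for i in range(0, len(perm), config.batch_size):
            sel = perm[i:i + config.batch_size]
            x = x_tr[sel][:, None]
            y = y_tr[sel]
            logits = model.forward(x)
            loss, dlogits = _nn.softmax_cross_entropy(logits, y)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            ep_loss += loss * len(sel)
            n_seen += len(sel)
            pred = logits.argmax(axis=1)
            ep_iou += [mean_iou(p, t).mean for p, t in zip(pred, y)]
        history.train_loss.append(ep_loss / n_seen)
        history.train_miou.append(float(np.mean(ep_iou)))
        ho_loss, ho_iou = _eval(x_ho, y_ho)
        history.holdout_loss.append(ho_loss)
        history.holdout_miou.append(ho_iou)
    return model, history


def predict_classmap(
    model: UNetSegmenter,
    hu_image: np.ndarray,
    pixel_spacing: tuple[float, float],
) -> TissueClassMap:
    """Segment one HU image: softmax argmax, mapped back to native resolution."""
    hu_image = np.asarray(hu_image, dtype=float)
    if hu_image.ndim != 2:
        raise ValueError("expected a 2-D HU image")
    size = model.config.input_size
    x = _to_model_grid(hu_image, size)[None, None]
    labels = model.forward(x).argmax(axis=1)[0]
    if labels.shape != hu_image.shape:
        labels = resize(labels, hu_image.shape, order=0, preserve_range=True,
                        anti_aliasing=False)
    return TissueClassMap(labels=labels.astype(np.uint8), pixel_spacing=tuple(pixel_spacing))


def save_checkpoint(model: UNetSegmenter, path) -> None:
    """Persist weights + config to a single ``.npz`` file."""
    arrays = {f"p{i}": p for i, (p, _) in enumerate(model.params())}
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> UNetSegmenter:
    """Restore a model saved by :func:`save_checkpoint`."""
    data = np.load(path)
    cfg = SegmenterConfig(**json.loads(bytes(data["config_json"]).decode()))
    model = UNetSegmenter(cfg)
    for i, (p, _) in enumerate(model.params()):
        p[...] = data[f"p{i}"]
    return model
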