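"""Convolutional-feature weight maps for fusing structural image parts.

The fused structural (low-rank) image ``G`` is a per-pixel weighted
average of the two sources' low-rank parts, with weights derived from
multi-layer convolutional features:

1. each low-rank part is pushed through a frozen convolutional backbone
   and features are tapped at three depths ``k = 1, 2, 3`` whose spatial
   resolution is ``1 / 2^(k-1)`` of the input;
2. per tap, the channel l1 norm ``||F_k(x, y)||_1`` is box-averaged over
   a 3x3 neighborhood (fixed divisor 9, zero padding) to give an
   activity map;
3. the two sources' activities are ratio-normalized per pixel into
   weights summing to 1 (ties and all-zero pixels fall back to 1/2);
4. weights are upsampled back to image resolution by block replication;
5. per layer, a candidate fusion ``G_k = sum_i w_ik * I_i^r`` is formed
   and the final ``G`` is the pixel-wise maximum over layers.

Two backbones satisfy the same contract: a tiny seeded random network
(the default, self-contained) and an optional pretrained VGG-16 adapter
that requires torch/torchvision at call time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "ConvBackbone",
    "TinyBackbone",
    "VGG16Backbone",
    "FeatureStack",
    "ActivityMap",
    "WeightMapSet",
    "extract_features",
    "layer_activity",
    "normalize_weights",
    "upsample_weight",
    "compute_weight_maps",
    "fuse_low_rank",
]

N_TAPS = 3


class ConvBackbone:
    """Contract for a deterministic three-tap feature extractor.

    ``features(img)`` maps an H x W single-channel image to three
    feature stacks of shape ``channels(k) x ceil(H / 2^(k-1)) x
    ceil(W / 2^(k-1))`` for ``k`` in 1..3.  Extraction must be
    deterministic (evaluation mode, no dropout).
    """

    def channels(self, k: int) -> int:
        raise NotImplementedError

    @staticmethod
    def downsample_factor(k: int) -> int:
        if k not in (1, 2, 3):
            raise ValueError(f"tap index must be 1, 2 or 3, got {k}")
        return 2 ** (k - 1)

    def features(self, img: np.ndarray) -> list[np.ndarray]:
        raise NotImplementedError


def _conv_relu(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """3x3 stride-1 zero-padded multi-channel correlation + ReLU (no bias)."""
    c_out, c_in = w.shape[:2]
    out = np.zeros((c_out, x.shape[1], x.shape[2]))
    for o in range(c_out):
        acc = out[o]
        for i in range(c_in):
            acc += signal.correlate2d(x[i], w[o, i], mode="same", boundary="fill")
    return np.maximum(out, 0.0)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    """2x2 stride-2 max pool with ceiling semantics on odd sizes."""
    c, h, w = x.shape
    ph, pw = -h % 2, -w % 2
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, ph), (0, pw)), constant_values=-np.inf)
    h2, w2 = x.shape[1] // 2, x.shape[2] // 2
    return x.reshape(c, h2, 2, w2, 2).max(axis=(2, 4))


class TinyBackbone(ConvBackbone):
    """Small frozen random CNN used as the default feature extractor.

    Three stages of {3x3 conv (stride 1, zero pad, no bias), ReLU};
    stages 2 and 3 are preceded by a 2x2 max pool, so the taps have
    downsampling factors 1, 2, 4 and channel counts 4, 8, 16.  Weights
    are drawn once from a seeded standard normal and never change, which
    makes every extraction bit-reproducible.  The input is scaled to
    [0, 1] and grayscale is replicated to 3 channels.
    """

    _CHANNELS = (4, 8, 16)

    def __init__(self, seed: int = 0):
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        c_prev = 3
        self.weights: list[np.ndarray] = []
        for c in self._CHANNELS:
            self.weights.append(rng.standard_normal((c, c_prev, 3, 3)))
            c_prev = c

    def channels(self, k: int) -> int:
        self.downsample_factor(k)  # validates k
        return self._CHANNELS[k - 1]

    def features(self, img: np.ndarray) -> list[np.ndarray]:
        img = np.asarray(img, dtype=float)
        x = np.repeat((img / 255.0)[None], 3, axis=0)
        taps = []
        for k, w in enumerate(self.weights):
            if k > 0:
                x = _maxpool2(x)
            x = _conv_relu(x, w)
            taps.append(x)
        return taps


class VGG16Backbone(ConvBackbone):
    """Adapter tapping a pretrained VGG-16 at the last activation of
    convolutional blocks 1-3 (64, 128, 256 channels; factors 1, 2, 4).

    Requires ``torch`` and ``torchvision``; constructing the adapter
    without them raises ImportError.  The default backbone everywhere
    else in the package is :class:`TinyBackbone`, which has no such
    dependency.
    """

    _CHANNELS = (64, 128, 256)
    # feature-module indices of relu1_2, relu2_2, relu3_3 in torchvision VGG-16
    _TAP_INDICES = (3, 8, 15)
    _MEAN = (0.485, 0.456, 0.406)
    _STD = (0.229, 0.224, 0.225)

    def __init__(self, weights_path: str | None = None):
        try:
            import torch
            import torchvision
        except ImportError as exc:  # pragma: no cover - torch optional
            raise ImportError(
                "VGG16Backbone requires torch and torchvision; "
                "use TinyBackbone for a dependency-free extractor"
            ) from exc
        self._torch = torch
        if weights_path is not None:
            model = torchvision.models.vgg16()
            model.load_state_dict(torch.load(weights_path, map_location="cpu"))
        else:
            model = torchvision.models.vgg16(weights="IMAGENET1K_V1")
        self._features = model.features.eval()
        for p in self._features.parameters():
            p.requires_grad_(False)

    def channels(self, k: int) -> int:
        self.downsample_factor(k)
        return self._CHANNELS[k - 1]

    def features(self, img: np.ndarray) -> list[np.ndarray]:  # pragma: no cover
        torch = self._torch
        img = np.asarray(img, dtype=float) / 255.0
        x = np.repeat(img[None], 3, axis=0)
        x = (x - np.asarray(self._MEAN)[:, None, None]) / np.asarray(self._STD)[:, None, None]
        t = torch.from_numpy(x[None]).float()
        taps = []
        with torch.no_grad():
            for i, layer in enumerate(self._features):
                t = layer(t)
                if i in self._TAP_INDICES:
                    taps.append(t[0].numpy().astype(float))
                if len(taps) == N_TAPS:
                    break
        return taps


@dataclass(frozen=True)
class FeatureStack:
    """Features from one tap: ``maps`` is a C x h x w tensor at layer ``k``."""

    layer: int
    maps: np.ndarray


@dataclass(frozen=True)
class ActivityMap:
    """Box-averaged channel-l1 activity of one feature stack (values >= 0)."""

    layer: int
    values: np.ndarray


@dataclass(frozen=True)
class WeightMapSet:
    """Full-resolution fusion weights, shape (2 sources, n_layers, H, W).

    At every pixel and layer the two source weights sum to 1.
    """

    weights: np.ndarray
    layers: tuple[int, ...]


def extract_features(img: np.ndarray, backbone: ConvBackbone) -> list[FeatureStack]:
    """Run the backbone and validate the declared tap shapes."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("extract_features expects a single-channel image")
    h, w = img.shape
    if h < 8 or w < 8:
        raise ValueError(f"image must be at least 8x8 for three taps, got {img.shape}")
    stacks = []
    for k, maps in enumerate(backbone.features(img), start=1):
        f = backbone.downsample_factor(k)
        expect = (backbone.channels(k), -(-h // f), -(-w // f))
        if maps.shape != expect:
            raise ValueError(
                f"backbone tap {k} produced shape {maps.shape}, expected {expect}"
            )
        if not np.all(np.isfinite(maps)):
            raise ValueError(f"backbone tap {k} produced non-finite features")
        stacks.append(FeatureStack(layer=k, maps=maps))
    return stacks


def layer_activity(F: FeatureStack) -> ActivityMap:
    """Channel l1 norm followed by a 3x3 box sum with fixed divisor 9.

    The divisor stays 9 at the borders (zero padding outside the map),
    so corner activities are attenuated by the smaller in-bounds window.
    """
    l1 = np.abs(F.maps).sum(axis=0)
    vals = ndimage.correlate(l1, np.full((3, 3), 1.0 / 9.0), mode="constant", cval=0.0)
    return ActivityMap(layer=F.layer, values=np.maximum(vals, 0.0))


def normalize_weights(a1: ActivityMap, a2: ActivityMap) -> tuple[np.ndarray, np.ndarray]:
    """Ratio-normalize two activity maps into per-pixel weights.

    ``w_i = a_i / (a_1 + a_2)``; pixels where both activities are zero
    get (1/2, 1/2).
    """
    v1, v2 = a1.values, a2.values
    if v1.shape != v2.shape:
        raise ValueError(f"activity shapes differ: {v1.shape} vs {v2.shape}")
    denom = v1 + v2
    zero = denom == 0.0
    safe = np.where(zero, 1.0, denom)
    w1 = np.where(zero, 0.5, v1 / safe)
    w2 = np.where(zero, 0.5, v2 / safe)
    return w1, w2


def upsample_weight(w: np.ndarray, layer: int, target: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor block replication of a tap-resolution weight map.

    Each source cell fills its ``2^(k-1)`` square block; the result is
    cropped to exactly ``target`` (which handles odd image sizes).
    """
    H, W = target
    f = ConvBackbone.downsample_factor(layer)
    expect = (-(-H // f), -(-W // f))
    if w.shape != expect:
        raise ValueError(
            f"layer-{layer} weight map has shape {w.shape}, expected {expect} "
            f"for target {target}"
        )
    up = np.repeat(np.repeat(w, f, axis=0), f, axis=1)
    return up[:H, :W]


def compute_weight_maps(
    part1: np.ndarray,
    part2: np.ndarray,
    backbone: ConvBackbone,
    layers: tuple[int, ...] = (1, 2, 3),
) -> WeightMapSet:
    """Full weight-map pipeline for a pair of structural parts."""
    part1 = np.asarray(part1, dtype=float)
    part2 = np.asarray(part2, dtype=float)
    if part1.shape != part2.shape:
        raise ValueError(f"part shapes differ: {part1.shape} vs {part2.shape}")
    if not layers:
        raise ValueError("at least one layer is required")
    target = part1.shape
    f1 = extract_features(part1, backbone)
    f2 = extract_features(part2, backbone)
    out = np.empty((2, len(layers)) + target)
    for j, k in enumerate(layers):
        a1 = layer_activity(f1[k - 1])
        a2 = layer_activity(f2[k - 1])
        w1, w2 = normalize_weights(a1, a2)
        out[0, j] = upsample_weight(w1, k, target)
        out[1, j] = upsample_weight(w2, k, target)
    return WeightMapSet(weights=out, layers=tuple(layers))


def fuse_low_rank(
    parts: tuple[np.ndarray, np.ndarray], weights: WeightMapSet
) -> np.ndarray:
    """Weighted-average fusion of the structural parts, max over layers.

    Per layer ``k``, the candidate is ``G_k = w_1k * I_1^r + w_2k *
    I_2^r``; the fused part is the pixel-wise maximum of the candidates.
    Because weights sum to 1 each candidate is a convex combination, so
    ``G`` never exceeds the pixel-wise max of the two inputs.
    """
    p1 = np.asarray(parts[0], dtype=float)
    p2 = np.asarray(parts[1], dtype=float)
    if p1.shape != p2.shape:
        raise ValueError(f"part shapes differ: {p1.shape} vs {p2.shape}")
    if weights.weights.shape[2:] != p1.shape:
        raise ValueError(
            f"weight maps have shape {weights.weights.shape[2:]}, parts {p1.shape}"
        )
    candidates = weights.weights[0] * p1 + weights.weights[1] * p2
    return candidates.max(axis=0)
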