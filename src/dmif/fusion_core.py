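"""End-to-end fusion pipeline for a registered pair of medical images.

The pipeline has three stages: each source is split by latent low-rank
representation into a structural part and a salient part; the structural
parts are fused by convolutional-feature weight maps; the salient parts
are fused by a plain sum (they carry complementary local detail, so
addition preserves both).  The fused image is the clipped sum of the two
fused components — the sparse noise parts are deliberately dropped,
which gives an implicit denoising.

Color (PET/SPECT) sources are handled by fusing their BT.601 luma with
the grayscale source and re-attaching the chroma afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .deep_feature_weights import (
    ConvBackbone,
    TinyBackbone,
    WeightMapSet,
    compute_weight_maps,
    fuse_low_rank,
)
from .lrr_decomposition import (
    DEFAULT_LAMBDA,
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    DecomposedImage,
    decompose_image,
)

__all__ = [
    "FusionConfig",
    "FusedResult",
    "fuse_salient",
    "reconstruct",
    "split_color",
    "merge_color",
    "fuse_pair",
]

# ITU-R BT.601 full-range luma weights and the matching chroma rows
_BT601 = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168735892, -0.331264108, 0.5],
        [0.5, -0.418687589, -0.081312411],
    ]
)
_BT601_INV = np.linalg.inv(_BT601)
_CHROMA_OFFSET = 128.0


@dataclass(frozen=True)
class FusionConfig:
    """Knobs of the fusion pipeline.

    Parameters
    ----------
    lambda_:
        LatLRR trade-off between the nuclear-norm terms and the sparse
        noise penalty; larger values push more content out of the noise
        part.
    tol, max_iter:
        Solver stopping rule (relative equality residual / iteration cap).
    layers:
        Which backbone taps contribute fusion candidates.
    backbone:
        ``"tiny"`` (seeded random CNN, self-contained) or ``"vgg16"``
        (pretrained adapter, requires torch).
    backbone_seed:
        Seed of the tiny backbone weights.
    color_mode:
        ``"luma"`` fuses the BT.601 luma of a color source and restores
        its chroma; ``"grayscale"`` averages its channels and returns a
        grayscale result.
    clip_range:
        Output intensity range; the reconstruction is clipped into it.
    """

    lambda_: float = DEFAULT_LAMBDA
    tol: float = DEFAULT_TOL
    max_iter: int = DEFAULT_MAX_ITER
    layers: tuple[int, ...] = (1, 2, 3)
    backbone: str = "tiny"
    backbone_seed: int = 0
    color_mode: str = "luma"
    clip_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("layers must be non-empty")
        if not set(self.layers) <= {1, 2, 3}:
            raise ValueError(f"layers must be a subset of {{1,2,3}}, got {self.layers}")
        if self.clip_range[0] >= self.clip_range[1]:
            raise ValueError("clip_range must be ordered")
        if self.backbone not in ("tiny", "vgg16"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.color_mode not in ("luma", "grayscale"):
            raise ValueError(f"unknown color_mode {self.color_mode!r}")

    def make_backbone(self) -> ConvBackbone:
        if self.backbone == "tiny":
            return TinyBackbone(seed=self.backbone_seed)
        from .deep_feature_weights import VGG16Backbone

        return VGG16Backbone()


@dataclass
class FusedResult:
    """Fused image plus every intermediate of the pipeline."""

    fused: np.ndarray
    low_rank_fused: np.ndarray
    salient_fused: np.ndarray
    decompositions: tuple[DecomposedImage, DecomposedImage]
    weight_maps: WeightMapSet
    config: FusionConfig
    metrics: dict | None = field(default=None)


def fuse_salient(s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    """Sum rule for the salient parts: ``H = I_1^s + I_2^s`` (no clipping)."""
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError(f"salient shapes differ: {s1.shape} vs {s2.shape}")
    return s1 + s2


def reconstruct(
    G: np.ndarray, H: np.ndarray, clip: tuple[float, float] = (0.0, 255.0)
) -> np.ndarray:
    """Fused image ``R = G + H``, clipped to the output range."""
    G = np.asarray(G, dtype=float)
    H = np.asarray(H, dtype=float)
    if G.shape != H.shape:
        raise ValueError(f"component shapes differ: {G.shape} vs {H.shape}")
    return np.clip(G + H, clip[0], clip[1])


def split_color(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split an RGB image into BT.601 luma and a 2-channel chroma (Cb, Cr)."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"split_color expects an HxWx3 image, got {img.shape}")
    ycc = img @ _BT601.T
    ycc[..., 1:] += _CHROMA_OFFSET
    return ycc[..., 0], ycc[..., 1:]


def merge_color(luma: np.ndarray, chroma: np.ndarray) -> np.ndarray:
    """Inverse BT.601: luma + (Cb, Cr) back to RGB, clipped to [0, 255]."""
    luma = np.asarray(luma, dtype=float)
    chroma = np.asarray(chroma, dtype=float)
    if chroma.shape != luma.shape + (2,):
        raise ValueError(
            f"chroma shape {chroma.shape} does not match luma {luma.shape}"
        )
    ycc = np.concatenate([luma[..., None], chroma - _CHROMA_OFFSET], axis=-1)
    rgb = ycc @ _BT601_INV.T
    return np.clip(rgb, 0.0, 255.0)


def _as_gray(img: np.ndarray, cfg: FusionConfig) -> tuple[np.ndarray, np.ndarray | None]:
    """Reduce one source to a single channel; keep its chroma if luma mode."""
    img = np.asarray(img, dtype=float)
    if img.ndim == 2:
        return img, None
    if img.ndim == 3 and img.shape[2] == 3:
        if cfg.color_mode == "luma":
            luma, chroma = split_color(img)
            return luma, chroma
        return img.mean(axis=2), None
    raise ValueError(f"unsupported image shape {img.shape}")


def fuse_pair(a: np.ndarray, b: np.ndarray, cfg: FusionConfig | None = None) -> FusedResult:
    """Fuse two registered same-size images end to end.

    At most one source may be 3-channel; if one is, its chroma is
    re-attached to the fused luma so the result is color.

    Returns
    -------
    FusedResult
        ``fused`` is exactly ``clip(low_rank_fused + salient_fused)``;
        its spatial shape equals the input shape.
    """
    if cfg is None:
        cfg = FusionConfig()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[:2] != b.shape[:2]:
        raise ValueError(f"source sizes differ: {a.shape[:2]} vs {b.shape[:2]}")
    if a.ndim == 3 and b.ndim == 3:
        raise ValueError("at most one source may be a color image")

    ga, chroma_a = _as_gray(a, cfg)
    gb, chroma_b = _as_gray(b, cfg)
    chroma = chroma_a if chroma_a is not None else chroma_b

    dec_a = decompose_image(ga, lambda_=cfg.lambda_, tol=cfg.tol, max_iter=cfg.max_iter)
    dec_b = decompose_image(gb, lambda_=cfg.lambda_, tol=cfg.tol, max_iter=cfg.max_iter)

    backbone = cfg.make_backbone()
    wm = compute_weight_maps(dec_a.low_rank, dec_b.low_rank, backbone, cfg.layers)
    G = fuse_low_rank((dec_a.low_rank, dec_b.low_rank), wm)
    H = fuse_salient(dec_a.salient, dec_b.salient)
    R = reconstruct(G, H, cfg.clip_range)

    fused = R if chroma is None or cfg.color_mode != "luma" else merge_color(R, chroma)
    return FusedResult(
        fused=fused,
        low_rank_fused=G,
        salient_fused=H,
        decompositions=(dec_a, dec_b),
        weight_maps=wm,
        config=cfg,
    )
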