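"""Seeded multi-modal head phantoms and the tiny test backbone.

The phantom pairs emulate the situation real multi-modal scans create:
two registered views of one head that carry *complementary* content.
The structural member (CT-like / T1-like) shows a bright skull rim and
a piecewise-constant interior; the soft-tissue member (MRI-like /
T2-like) shows a dark rim and a smoothly textured interior (band-
limited noise), so rim information lives only in one member and texture
only in the other.  Functional pairs (PET / SPECT) replace the second
member by a pseudo-color rendering of a smooth activity field.

Every generator is a pure function of its spec: equal specs produce
bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .deep_feature_weights import TinyBackbone

__all__ = ["PhantomSpec", "make_phantom_pair", "tiny_backbone", "head_masks", "MODALITY_PAIRS"]

MODALITY_PAIRS = ("ct_mri", "mri_pet", "mri_spect", "t1_t2")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one registered phantom pair.

    Parameters
    ----------
    size:
        (H, W), each at least 32; default 256 x 256 matching typical
        registered brain-atlas slices.
    modality_pair:
        One of ``ct_mri``, ``mri_pet``, ``mri_spect``, ``t1_t2``.
    seed:
        Drives every random draw; equal specs give bit-identical pairs.
    noise_sigma:
        Standard deviation of additive Gaussian acquisition noise on the
        0-255 scale; default 2.0 (mild scanner noise).
    """

    size: tuple[int, int] = (256, 256)
    modality_pair: str = "ct_mri"
    seed: int = 0
    noise_sigma: float = 2.0

    def __post_init__(self) -> None:
        h, w = self.size
        if h < 32 or w < 32:
            raise ValueError(f"phantom size must be at least 32x32, got {self.size}")
        if self.modality_pair not in MODALITY_PAIRS:
            raise ValueError(
                f"unknown modality_pair {self.modality_pair!r}; "
                f"choose from {MODALITY_PAIRS}"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def head_masks(size: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Outer head mask, interior mask and the rim (their difference)."""
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    ry, rx = 0.42 * h, 0.36 * w
    outer = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    inner = ((yy - cy) / (0.88 * ry)) ** 2 + ((xx - cx) / (0.88 * rx)) ** 2 <= 1.0
    return outer, inner, outer & ~inner


def _ellipse(size, cy, cx, ry, rx, angle=0.0) -> np.ndarray:
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w]
    ca, sa = np.cos(angle), np.sin(angle)
    y = (yy - cy) * ca + (xx - cx) * sa
    x = -(yy - cy) * sa + (xx - cx) * ca
    return (y / ry) ** 2 + (x / rx) ** 2 <= 1.0


def _structural_member(size, rng) -> np.ndarray:
    """CT/T1-like: bright rim, piecewise-constant interior, black background."""
    h, w = size
    outer, inner, rim = head_masks(size)
    img = np.zeros(size)
    img[rim] = 230.0
    img[inner] = 55.0
    # a few constant-intensity internal structures (ventricle-like blobs)
    for _ in range(4):
        cy = h * rng.uniform(0.3, 0.7)
        cx = w * rng.uniform(0.3, 0.7)
        blob = _ellipse(size, cy, cx, h * rng.uniform(0.05, 0.14),
                        w * rng.uniform(0.05, 0.14), rng.uniform(0, np.pi))
        img[blob & inner] = rng.uniform(90.0, 190.0)
    return img


def _soft_tissue_member(size, rng) -> np.ndarray:
    """MRI/T2-like: dark rim, smooth band-limited texture inside."""
    h, w = size
    outer, inner, rim = head_masks(size)
    texture = ndimage.gaussian_filter(rng.standard_normal(size), sigma=min(h, w) / 40)
    texture = texture / (np.abs(texture).max() + 1e-12)
    img = np.zeros(size)
    img[inner] = 120.0 + 90.0 * texture[inner]
    img[rim] = 20.0
    # a bright lesion-like focus visible only in the soft-tissue member
    cy = h * rng.uniform(0.35, 0.65)
    cx = w * rng.uniform(0.35, 0.65)
    lesion = _ellipse(size, cy, cx, h * 0.06, w * 0.06)
    img[lesion & inner] = 235.0
    return np.clip(img, 0.0, 255.0)


def _activity_member(size, rng) -> np.ndarray:
    """PET/SPECT-like pseudo-color rendering of a smooth activity field."""
    h, w = size
    outer, inner, _ = head_masks(size)
    field = ndimage.gaussian_filter(rng.standard_normal(size), sigma=min(h, w) / 12)
    field -= field.min()
    field /= field.max() + 1e-12
    field *= inner
    # hot-body colormap: black -> red -> yellow -> white
    r = np.clip(3.0 * field, 0, 1)
    g = np.clip(3.0 * field - 1.0, 0, 1)
    b = np.clip(3.0 * field - 2.0, 0, 1)
    return 255.0 * np.stack([r, g, b], axis=-1)


def make_phantom_pair(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate one registered pair for the requested modality combination.

    Returns two float arrays in [0, 255] of identical spatial size; the
    second member is H x W x 3 for the functional (``mri_pet`` /
    ``mri_spect``) pairs and H x W otherwise.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.modality_pair in ("ct_mri", "t1_t2"):
        m1 = _structural_member(spec.size, rng)
        m2 = _soft_tissue_member(spec.size, rng)
    else:  # mri_pet / mri_spect: grayscale MRI + color functional map
        m1 = _soft_tissue_member(spec.size, rng)
        m2 = _activity_member(spec.size, rng)
    if spec.noise_sigma > 0:
        m1 = m1 + spec.noise_sigma * rng.standard_normal(m1.shape)
        m2 = m2 + spec.noise_sigma * rng.standard_normal(m2.shape)
    return np.clip(m1, 0.0, 255.0), np.clip(m2, 0.0, 255.0)


def tiny_backbone(seed: int = 0) -> TinyBackbone:
    """The frozen seeded three-tap CNN used as the default extractor.

    Taps have downsampling factors (1, 2, 4) and channel counts
    (4, 8, 16); same seed, same weights, bit-identical features.
    """
    return TinyBackbone(seed=seed)
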