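"""Objective fusion-quality indexes: SD, EN, Q_MI and Q_PC.

* **SD** — population standard deviation of the fused intensities; a
  proxy for overall contrast.
* **EN** — Shannon entropy (bits) of the 256-bin intensity histogram; a
  proxy for the amount of information in the result.
* **Q_MI** — normalized mutual information between the fused image and
  each source, ``2 * [ MI(a,f)/(H(a)+H(f)) + MI(b,f)/(H(b)+H(f)) ]``,
  measuring how much source information the fused image carries; range
  [0, 2], reaching 2 when the fused image reproduces both sources.
* **Q_PC** — product of the Pearson correlations between the fused
  image's phase-congruency maps (principal map and the two moment maps)
  and the element-wise maxima of the corresponding source maps; range
  [-1, 1], reaching 1 on perfect detail preservation.

Phase congruency is computed with a frequency-domain log-Gabor filter
bank in the classical formulation: local energy per orientation,
noise-threshold compensation estimated from the smallest-scale filter
response, a frequency-spread weighting, and moment analysis of the
per-orientation congruency maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HistogramSpec",
    "PCMaps",
    "MetricReport",
    "std_dev",
    "entropy",
    "mutual_information",
    "q_mi",
    "log_gabor_bank",
    "phase_congruency",
    "q_pc",
    "metric_report",
]

_EPS = 1e-4  # regularizer in the energy normalizations


@dataclass(frozen=True)
class HistogramSpec:
    """Binning convention for entropy / mutual information."""

    bins: int = 256
    range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("at least 2 bins required")


DEFAULT_HIST = HistogramSpec()


@dataclass(frozen=True)
class PCMaps:
    """Phase-congruency maps of one image.

    ``pc`` is the orientation-combined congruency in [0, 1];
    ``max_moment`` / ``min_moment`` are the principal moments of the
    per-orientation congruency (edge and corner strength).
    """

    pc: np.ndarray
    max_moment: np.ndarray
    min_moment: np.ndarray


@dataclass(frozen=True)
class MetricReport:
    """The four quality indexes of one fused result against its sources."""

    sd: float
    en: float
    q_mi: float
    q_pc: float

    def as_dict(self) -> dict[str, float]:
        return {"SD": self.sd, "EN": self.en, "Q_MI": self.q_mi, "Q_PC": self.q_pc}


def std_dev(img: np.ndarray) -> float:
    """Population standard deviation of all pixel intensities."""
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    return float(img.std())


def _hist_probs(img: np.ndarray, spec: HistogramSpec) -> np.ndarray:
    img = np.clip(np.asarray(img, dtype=float), *spec.range)
    counts, _ = np.histogram(img, bins=spec.bins, range=spec.range)
    return counts / counts.sum()


def entropy(img: np.ndarray, spec: HistogramSpec = DEFAULT_HIST) -> float:
    """Shannon entropy (bits) of the binned intensity histogram."""
    p = _hist_probs(img, spec)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def mutual_information(
    a: np.ndarray, b: np.ndarray, spec: HistogramSpec = DEFAULT_HIST
) -> float:
    """Mutual information (bits) from the joint binned histogram."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    a = np.clip(a, *spec.range)
    b = np.clip(b, *spec.range)
    joint, _, _ = np.histogram2d(
        a.ravel(), b.ravel(), bins=spec.bins, range=[spec.range, spec.range]
    )
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    outer = np.outer(px, py)
    nz = pxy > 0
    return float((pxy[nz] * np.log2(pxy[nz] / outer[nz])).sum())


def q_mi(
    a: np.ndarray, b: np.ndarray, f: np.ndarray, spec: HistogramSpec = DEFAULT_HIST
) -> float:
    """Normalized mutual-information fusion index, range [0, 2].

    Terms whose entropy denominator vanishes (a flat image) contribute 0.
    """
    for name, img in (("a", a), ("b", b)):
        if np.asarray(img).shape != np.asarray(f).shape:
            raise ValueError(f"source {name} and fused image shapes differ")
    hf = entropy(f, spec)
    total = 0.0
    for src in (a, b):
        hs = entropy(src, spec)
        denom = hs + hf
        if denom > 0:
            total += mutual_information(src, f, spec) / denom
    return 2.0 * total


# ---------------------------------------------------------------------------
# phase congruency


def _frequency_grids(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized radius and angle grids in fft layout (DC at [0, 0])."""
    rows, cols = shape
    if cols % 2:
        xr = np.arange(-(cols - 1) / 2, (cols - 1) / 2 + 1) / (cols - 1)
    else:
        xr = np.arange(-cols / 2, cols / 2) / cols
    if rows % 2:
        yr = np.arange(-(rows - 1) / 2, (rows - 1) / 2 + 1) / (rows - 1)
    else:
        yr = np.arange(-rows / 2, rows / 2) / rows
    x, y = np.meshgrid(xr, yr)
    radius = np.fft.ifftshift(np.sqrt(x**2 + y**2))
    theta = np.fft.ifftshift(np.arctan2(-y, x))
    radius[0, 0] = 1.0  # avoid log(0) at DC; the DC gain is forced to 0 anyway
    return radius, np.sin(theta), np.cos(theta)


def log_gabor_bank(
    shape: tuple[int, int],
    scales: int = 4,
    orientations: int = 6,
    min_wavelength: float = 3.0,
    mult: float = 2.1,
    sigma_onf: float = 0.55,
    d_theta_sigma: float = 1.5,
) -> np.ndarray:
    """Frequency-domain log-Gabor filters, shape (orientations, scales, H, W).

    Radial profile ``exp(-(log(r/f0))^2 / (2 log(sigma_onf)^2))`` at
    center frequencies ``f0 = 1 / (min_wavelength * mult^s)``, times a
    Gaussian angular spread of width ``pi / orientations /
    d_theta_sigma``, times a high-order Butterworth low-pass (cutoff
    0.45) that kills boundary-frequency artifacts.  DC gain is zero.
    Filters are laid out for direct multiplication with ``fft2`` output.
    """
    radius, sintheta, costheta = _frequency_grids(shape)
    lowpass = 1.0 / (1.0 + (radius / 0.45) ** 30)

    radial = np.empty((scales,) + tuple(shape))
    for s in range(scales):
        f0 = 1.0 / (min_wavelength * mult**s)
        radial[s] = np.exp(-(np.log(radius / f0) ** 2) / (2 * np.log(sigma_onf) ** 2))
        radial[s] *= lowpass
        radial[s][0, 0] = 0.0

    theta_sigma = np.pi / orientations / d_theta_sigma
    bank = np.empty((orientations, scales) + tuple(shape))
    for o in range(orientations):
        angl = o * np.pi / orientations
        ds = sintheta * np.cos(angl) - costheta * np.sin(angl)
        dc = costheta * np.cos(angl) + sintheta * np.sin(angl)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta**2) / (2 * theta_sigma**2))
        bank[o] = radial * spread
    return bank


def phase_congruency(
    img: np.ndarray,
    scales: int = 4,
    orientations: int = 6,
    min_wavelength: float = 3.0,
    mult: float = 2.1,
    sigma_onf: float = 0.55,
    noise_k: float = 2.0,
    cut_off: float = 0.5,
    gain: float = 10.0,
) -> PCMaps:
    """Phase congruency of a grayscale image via log-Gabor local energy.

    Per orientation, quadrature responses at each scale are combined
    into a local-energy measure; an additive noise floor estimated from
    the smallest-scale amplitude (Rayleigh statistics, ``noise_k``
    standard deviations above the mean) is subtracted; a sigmoidal
    weighting penalizes narrow frequency spread.  The combined map is
    total weighted energy over total amplitude, in [0, 1]; the moment
    maps are the classical principal moments of the per-orientation
    congruency.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("phase_congruency expects a single-channel image")
    if min(img.shape) < 16:
        raise ValueError(f"image too small for the filter bank: {img.shape}")

    bank = log_gabor_bank(
        img.shape, scales, orientations, min_wavelength, mult, sigma_onf
    )
    IM = np.fft.fft2(img)

    total_energy = np.zeros(img.shape)
    total_an = np.zeros(img.shape)
    covx2 = np.zeros(img.shape)
    covy2 = np.zeros(img.shape)
    covxy = np.zeros(img.shape)

    for o in range(orientations):
        eo = [np.fft.ifft2(IM * bank[o, s]) for s in range(scales)]
        an = [np.abs(e) for e in eo]
        sum_an = np.sum(an, axis=0)
        sum_e = np.sum([e.real for e in eo], axis=0)
        sum_o = np.sum([e.imag for e in eo], axis=0)
        max_an = np.max(an, axis=0)

        x_energy = np.sqrt(sum_e**2 + sum_o**2) + _EPS
        mean_e = sum_e / x_energy
        mean_o = sum_o / x_energy
        energy = np.zeros(img.shape)
        for e in eo:
            energy += e.real * mean_e + e.imag * mean_o
            energy -= np.abs(e.real * mean_o - e.imag * mean_e)

        # Rayleigh noise floor from the smallest-scale amplitude response
        tau = np.median(an[0]) / np.sqrt(np.log(4))
        total_tau = tau * (1 - (1 / mult) ** scales) / (1 - 1 / mult)
        noise_mean = total_tau * np.sqrt(np.pi / 2)
        noise_sigma = total_tau * np.sqrt((4 - np.pi) / 2)
        energy = np.maximum(energy - (noise_mean + noise_k * noise_sigma), 0.0)

        width = (sum_an / (max_an + _EPS) - 1) / (scales - 1)
        weight = 1.0 / (1.0 + np.exp(gain * (cut_off - width)))

        pc_o = weight * energy / (sum_an + _EPS)
        total_energy += weight * energy
        total_an += sum_an

        angl = o * np.pi / orientations
        covx = pc_o * np.cos(angl)
        covy = pc_o * np.sin(angl)
        covx2 += covx**2
        covy2 += covy**2
        covxy += covx * covy

    pc = np.clip(total_energy / (total_an + _EPS), 0.0, 1.0)
    covx2 /= orientations / 2.0
    covy2 /= orientations / 2.0
    covxy *= 4.0 / orientations
    denom = np.sqrt(covxy**2 + (covx2 - covy2) ** 2) + _EPS
    max_moment = (covy2 + covx2 + denom) / 2.0
    min_moment = (covy2 + covx2 - denom) / 2.0
    return PCMaps(pc=pc, max_moment=max_moment, min_moment=np.maximum(min_moment, 0.0))


def _pearson_or_zero(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        warnings.warn(
            "zero-variance phase-congruency map; correlation factor set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
        return 0.0
    return float(np.corrcoef(x.ravel(), y.ravel())[0, 1])


def q_pc(a: np.ndarray, b: np.ndarray, f: np.ndarray, **pc_params) -> float:
    """Phase-congruency fusion index ``P_p * P_M * P_m``, range [-1, 1].

    Each factor is the Pearson correlation between one of the fused
    image's phase-congruency maps and the element-wise maximum of the
    two sources' corresponding maps.  A zero-variance map zeroes its
    factor (with a warning) rather than dividing by zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    f = np.asarray(f, dtype=float)
    if not (a.shape == b.shape == f.shape):
        raise ValueError("q_pc requires three same-shape images")
    pa = phase_congruency(a, **pc_params)
    pb = phase_congruency(b, **pc_params)
    pf = phase_congruency(f, **pc_params)
    score = 1.0
    for ma, mb, mf in (
        (pa.pc, pb.pc, pf.pc),
        (pa.max_moment, pb.max_moment, pf.max_moment),
        (pa.min_moment, pb.min_moment, pf.min_moment),
    ):
        score *= _pearson_or_zero(mf, np.maximum(ma, mb))
    return score


def _luma_or_gray(img: np.ndarray) -> np.ndarray:
    if np.asarray(img).ndim == 3:
        from .fusion_core import split_color

        return split_color(np.asarray(img, dtype=float))[0]
    return np.asarray(img, dtype=float)


def metric_report(
    a: np.ndarray, b: np.ndarray, f: np.ndarray, spec: HistogramSpec = DEFAULT_HIST
) -> MetricReport:
    """All four indexes of a fused image against its two sources.

    Color inputs are reduced to BT.601 luma first.
    """
    a = _luma_or_gray(a)
    b = _luma_or_gray(b)
    f = _luma_or_gray(f)
    return MetricReport(
        sd=std_dev(f),
        en=entropy(f, spec),
        q_mi=q_mi(a, b, f, spec),
        q_pc=q_pc(a, b, f),
    )
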