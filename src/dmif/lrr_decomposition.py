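"""Latent low-rank representation (LatLRR) decomposition of image matrices.

LatLRR splits a data matrix ``X`` into a globally low-rank part ``XZ``, a
locally salient part ``LX`` and sparse noise ``E`` by solving

    min_{Z,L,E}  ||Z||_* + ||L||_* + lambda * ||E||_1
    s.t.         X = XZ + LX + E

where ``||.||_*`` is the nuclear norm (sum of singular values) and
``||.||_1`` the element-wise l1 norm.  For a medical image the low-rank
part carries the global structure and brightness while the salient part
carries local detail; the two are fused by separate rules downstream.

The solver is an inexact augmented-Lagrange-multiplier (ALM) scheme: the
two nuclear-norm blocks are handled by singular value thresholding on
auxiliary splitting variables, the sparse block by element-wise soft
thresholding, and the penalty parameter grows geometrically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "ImageMatrix",
    "LatLRRModel",
    "DecomposedImage",
    "svt",
    "soft_threshold",
    "solve_latlrr",
    "decompose_image",
]

#: default trade-off between the nuclear-norm terms and the l1 noise term
DEFAULT_LAMBDA = 0.8
#: default relative equality-constraint tolerance
DEFAULT_TOL = 1e-6
#: default iteration cap for the inexact ALM loop
DEFAULT_MAX_ITER = 500


@dataclass(frozen=True)
class ImageMatrix:
    """A single-channel image as a 2-D float array with a nominal range.

    Parameters
    ----------
    data:
        H x W array of intensities.  H, W >= 8 and all entries finite.
    value_range:
        Nominal ``(lo, hi)`` intensity range, default ``(0.0, 255.0)``.
    """

    data: np.ndarray
    value_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {arr.shape}")
        if arr.shape[0] < 8 or arr.shape[1] < 8:
            raise ValueError(f"image must be at least 8x8, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image contains non-finite values")
        lo, hi = self.value_range
        if not lo < hi:
            raise ValueError("value_range must be ordered (lo < hi)")
        object.__setattr__(self, "data", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class LatLRRModel:
    """Solved LatLRR coefficients and solver diagnostics.

    ``Z`` (W x W) are the low-rank coefficients, ``L`` (H x H) the
    saliency coefficients and ``E`` (H x W) the sparse noise, so that
    ``X ~= X @ Z + L @ X + E``.  ``residual_history`` records the
    relative Frobenius equality residual per iteration.
    """

    Z: np.ndarray
    L: np.ndarray
    E: np.ndarray
    lambda_: float
    residual_history: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = True

    @property
    def final_residual(self) -> float:
        return self.residual_history[-1] if self.residual_history else 0.0

    def objective(self, ord_weights: bool = True) -> float:
        """Value of ||Z||_* + ||L||_* + lambda * ||E||_1."""
        nz = float(np.linalg.norm(self.Z, ord="nuc"))
        nl = float(np.linalg.norm(self.L, ord="nuc"))
        ne = float(np.abs(self.E).sum())
        return nz + nl + self.lambda_ * ne


@dataclass
class DecomposedImage:
    """Structural / salient / noise split of one source image.

    ``low_rank + salient + noise`` reconstructs the input to within the
    solver tolerance.  The noise part is kept for diagnostics but is not
    used when fusing.
    """

    low_rank: np.ndarray
    salient: np.ndarray
    noise: np.ndarray
    model: LatLRRModel | None = None

    @property
    def converged(self) -> bool:
        return self.model.converged if self.model is not None else True


def soft_threshold(M: np.ndarray, tau: float) -> np.ndarray:
    """Element-wise soft thresholding ``sign(M) * max(|M| - tau, 0)``."""
    return np.sign(M) * np.maximum(np.abs(M) - tau, 0.0)


def svt(M: np.ndarray, tau: float) -> np.ndarray:
    """Singular value thresholding, the proximal operator of the nuclear norm.

    Forms the SVD ``M = U diag(s) V^T`` and returns
    ``U diag(max(s - tau, 0)) V^T``.

    Parameters
    ----------
    M:
        Any finite real matrix.
    tau:
        Non-negative threshold applied to every singular value.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("svt: input contains non-finite values")
    if tau < 0:
        raise ValueError(f"svt: tau must be non-negative, got {tau}")
    if tau == 0.0:
        return M.copy()
    try:
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
    except np.linalg.LinAlgError:
        # the default divide-and-conquer driver (gesdd) occasionally fails
        # to converge on near-singular iterates; gesvd is slower but robust
        U, s, Vt = scipy.linalg.svd(M, full_matrices=False, lapack_driver="gesvd")
    s = np.maximum(s - tau, 0.0)
    keep = s > 0
    if not np.any(keep):
        return np.zeros_like(M)
    return (U[:, keep] * s[keep]) @ Vt[keep]


def solve_latlrr(
    X: ImageMatrix | np.ndarray,
    lambda_: float = DEFAULT_LAMBDA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    mu: float | None = None,
    rho: float = 1.1,
    mu_max: float = 1e10,
) -> LatLRRModel:
    """Solve the LatLRR program by inexact ALM.

    Auxiliary variables ``J = Z`` and ``S = L`` carry the nuclear-norm
    proximal steps (singular value thresholding at ``1/mu``); ``E`` is
    updated by soft thresholding at ``lambda_/mu``; three multipliers
    enforce the equality constraint and the two splittings.  The penalty
    grows as ``mu <- min(rho * mu, mu_max)`` each sweep.

    Parameters
    ----------
    X:
        Data matrix (an image).  A raw ndarray is accepted.
    lambda_:
        Positive trade-off weight on ``||E||_1``.
    tol:
        Stop when the relative equality residual
        ``||X - XZ - LX - E||_F / ||X||_F`` drops to ``tol`` or below.
    max_iter:
        Iteration cap; hitting it sets ``converged=False`` and emits a
        warning rather than raising.
    mu:
        Initial penalty; default ``1e-2 / ||X||_2`` (scale-adaptive).

    Returns
    -------
    LatLRRModel
        Coefficients, residual history and convergence status.
    """
    if isinstance(X, ImageMatrix):
        X = X.data
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("solve_latlrr expects a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("solve_latlrr: input contains non-finite values")
    if lambda_ <= 0:
        raise ValueError("lambda_ must be positive")
    h, w = X.shape

    norm_x = np.linalg.norm(X)
    if norm_x == 0.0:
        return LatLRRModel(
            Z=np.zeros((w, w)),
            L=np.zeros((h, h)),
            E=np.zeros((h, w)),
            lambda_=lambda_,
            residual_history=[0.0],
            iterations=0,
            converged=True,
        )

    spectral = np.linalg.norm(X, 2)
    if mu is None:
        mu = 1e-2 / spectral

    Z = np.zeros((w, w))
    L = np.zeros((h, h))
    E = np.zeros((h, w))
    # multipliers for X = XZ + LX + E, Z = J, L = S
    Y1 = np.zeros((h, w))
    Y2 = np.zeros((w, w))
    Y3 = np.zeros((h, h))

    Xt = X.T
    # the linear-system factors are constant: (I + X^T X) and (I + X X^T)
    inv_z = np.linalg.inv(np.eye(w) + Xt @ X)
    inv_l = np.linalg.inv(np.eye(h) + X @ Xt)

    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # nuclear-norm proximal steps on the splitting variables
        J = svt(Z + Y2 / mu, 1.0 / mu)
        S = svt(L + Y3 / mu, 1.0 / mu)
        # exact minimization of the quadratic ALM terms in Z, then L
        Z = inv_z @ (Xt @ (X - L @ X - E) + J + (Xt @ Y1 - Y2) / mu)
        XZ = X @ Z
        L = ((X - XZ - E) @ Xt + S + (Y1 @ Xt - Y3) / mu) @ inv_l
        LX = L @ X
        # sparse part
        E = soft_threshold(X - XZ - LX + Y1 / mu, lambda_ / mu)

        R = X - XZ - LX - E
        Y1 = Y1 + mu * R
        Y2 = Y2 + mu * (Z - J)
        Y3 = Y3 + mu * (L - S)
        mu = min(rho * mu, mu_max)

        rel = float(np.linalg.norm(R) / norm_x)
        history.append(rel)
        if rel <= tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"LatLRR solver did not reach tol={tol:g} within {max_iter} "
            f"iterations (final residual {history[-1]:.3e})",
            RuntimeWarning,
            stacklevel=2,
        )
    return LatLRRModel(
        Z=Z,
        L=L,
        E=E,
        lambda_=lambda_,
        residual_history=history,
        iterations=it,
        converged=converged,
    )


def decompose_image(
    img: ImageMatrix | np.ndarray,
    lambda_: float = DEFAULT_LAMBDA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> DecomposedImage:
    """Split one image into structural, salient and noise parts via LatLRR.

    The raw intensity matrix itself is the LatLRR data matrix (no patch
    extraction).  Intensities are rescaled to [0, 1] before solving —
    the soft-threshold levels are scale-dependent — and the three parts
    are mapped back to the original range afterwards, which is exact
    because the decomposition is linear in ``X`` for fixed ``(Z, L)``.
    """
    if isinstance(img, ImageMatrix):
        mat = img.data
        lo, hi = img.value_range
    else:
        mat = np.asarray(img, dtype=float)
        lo, hi = 0.0, 255.0
    if mat.ndim != 2:
        raise ValueError("decompose_image expects a single-channel matrix")

    scale = hi - lo
    model = solve_latlrr((mat - lo) / scale, lambda_=lambda_, tol=tol, max_iter=max_iter)
    Xs = (mat - lo) / scale
    # the lo offset (zero for the standard (0,255) range) rides on the
    # low-rank part so the three parts still sum to the input
    low_rank = scale * (Xs @ model.Z) + lo
    salient = scale * (model.L @ Xs)
    noise = scale * model.E
    return DecomposedImage(low_rank=low_rank, salient=salient, noise=noise, model=model)
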