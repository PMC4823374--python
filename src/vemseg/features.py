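"""Rotationally invariant multiscale derivative features (F2D / F3D).

Each voxel is described by Gaussian-smoothed intensity, gradient
magnitude and the eigenvalues of the (scale-normalized) Hessian, computed
at a geometric ladder of scales ``sigma_i = 2**(i/2) * sigma0``.  First
derivatives are multiplied by sigma and second derivatives by sigma**2 so
responses are comparable across scales.

F2D treats every slice of the stack independently (no cross-slice
mixing), which is the right choice for anisotropic stacks where the Z
spacing is much coarser than the in-plane pixel size.  F3D uses full 3D
derivatives and is intended for (near-)isotropic stacks.

All convolutions use mirror (reflect) boundary handling and truncate the
Gaussian at 4 sigma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .volumes import ImageStack

_TRUNCATE = 4.0
_BOUNDARY = "mirror"


@lru_cache(maxsize=64)
def _second_derivative_dc(sigma: float) -> float:
    """Sum of the truncated, sampled 1D second-derivative-of-Gaussian kernel.

    A truncated sampled kernel has a small non-zero sum, so the raw
    second-derivative response to a constant image is not exactly zero.
    Subtracting ``dc * smoothed`` restores the exact annihilation of
    constant (and linear) intensity profiles.
    """
    r = int(np.ceil(_TRUNCATE * sigma))
    delta = np.zeros(2 * r + 3)
    delta[r + 1] = 1.0
    kernel = gaussian_filter1d(delta, sigma, order=2, mode="constant", truncate=_TRUNCATE)
    return float(kernel.sum())


@lru_cache(maxsize=64)
def _first_derivative_gain(sigma: float) -> float:
    """Reciprocal of the truncated kernel's response to a unit ramp.

    Multiplying first-order responses by this gain makes the sigma-scaled
    derivative of a linear intensity ramp exactly sigma, removing the
    small truncation bias of the sampled kernel.
    """
    r = int(np.ceil(_TRUNCATE * sigma))
    ramp = np.arange(4 * r + 9, dtype=np.float64)
    resp = gaussian_filter1d(ramp, sigma, order=1, mode="constant", truncate=_TRUNCATE)
    return 1.0 / float(resp[ramp.size // 2])

#: Above this anisotropy factor the 3D extractor is considered inappropriate.
F3D_RHO_THRESHOLD = 1.5


def scale_sequence(sigma0: float, n: int) -> list[float]:
    """Geometric scale ladder ``[2**(i/2) * sigma0 for i in 0..n-1]`` (pixels)."""
    if sigma0 <= 0:
        raise ValueError(f"sigma0 must be positive, got {sigma0}")
    if n < 1:
        raise ValueError(f"need at least one scale, got n={n}")
    return [2.0 ** (0.5 * i) * float(sigma0) for i in range(n)]


@dataclass(frozen=True)
class ScaleSet:
    """Base scale and number of scales of the feature ladder."""

    sigma0: float
    n: int
    sigmas: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigmas", tuple(scale_sequence(self.sigma0, self.n)))


@dataclass(frozen=True)
class FeatureStack:
    """Per-voxel feature vectors, shape (X, Y, Z, C) with C = 4n or 5n."""

    values: np.ndarray
    scale_set: ScaleSet
    extractor_tag: str  # "f2d" | "f3d"

    def __post_init__(self) -> None:
        expected = {"f2d": 4, "f3d": 5}[self.extractor_tag] * self.scale_set.n
        if self.values.shape[-1] != expected:
            raise ValueError(
                f"{self.extractor_tag} with n={self.scale_set.n} scales needs "
                f"{expected} channels, got {self.values.shape[-1]}"
            )

    @property
    def n_channels(self) -> int:
        return self.values.shape[-1]

    def matrix(self) -> np.ndarray:
        """Feature vectors flattened to (n_voxels, C)."""
        return self.values.reshape(-1, self.values.shape[-1])


# ---------------------------------------------------------------------------
# Derivative responses
# ---------------------------------------------------------------------------

def derivative_responses_2d(
    image: np.ndarray, sigma: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Scale-normalized Gaussian derivative responses of a single slice.

    Returns ``(s00, s10, s01, s20, s11, s02)`` where the subscripts give
    the derivative order along X and Y; first-order responses carry a
    factor sigma, second-order ones sigma**2.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    image = np.asarray(image, dtype=np.float64)
    dc = _second_derivative_dc(float(sigma))
    gain = _first_derivative_gain(float(sigma))
    out = []
    for order in ((0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2)):
        resp = gaussian_filter(image, sigma, order=order, mode=_BOUNDARY, truncate=_TRUNCATE)
        if 2 in order:
            resp = resp - dc * out[0]  # out[0] is the smoothed image
        resp = resp * gain ** order.count(1)
        out.append(resp * sigma ** sum(order))
    return tuple(out)


def derivative_responses_3d(volume: np.ndarray, sigma: float) -> dict[tuple[int, int, int], np.ndarray]:
    """All responses ``s_ijk`` with i+j+k <= 2 of a volume, sigma-normalized."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    volume = np.asarray(volume, dtype=np.float64)
    dc = _second_derivative_dc(float(sigma))
    orders = [
        (0, 0, 0),
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (2, 0, 0), (1, 1, 0), (1, 0, 1),
        (0, 2, 0), (0, 1, 1), (0, 0, 2),
    ]
    gain = _first_derivative_gain(float(sigma))
    out: dict[tuple[int, int, int], np.ndarray] = {}
    for o in orders:
        resp = gaussian_filter(volume, sigma, order=o, mode=_BOUNDARY, truncate=_TRUNCATE)
        if 2 in o:
            resp = resp - dc * out[(0, 0, 0)]
        resp = resp * gain ** o.count(1)
        out[o] = resp * sigma ** sum(o)
    return out


def hessian_eigenvalues_2d(
    s20: np.ndarray, s11: np.ndarray, s02: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues of [[s20, s11], [s11, s02]], elementwise, descending.

    Closed form: (trace +- sqrt((s20 - s02)**2 + 4*s11**2)) / 2.
    """
    s20 = np.asarray(s20, dtype=np.float64)
    s11 = np.asarray(s11, dtype=np.float64)
    s02 = np.asarray(s02, dtype=np.float64)
    half_trace = 0.5 * (s20 + s02)
    radius = 0.5 * np.sqrt((s20 - s02) ** 2 + 4.0 * s11**2)
    return half_trace + radius, half_trace - radius


# ---------------------------------------------------------------------------
# Extractors
# ---------------------------------------------------------------------------

def extract_f2d(stack: ImageStack, scale_set: ScaleSet) -> FeatureStack:
    """Per-slice multiscale features: (smoothed, |grad|, lambda1, lambda2) x n.

    Implemented as 3D separable filters with sigma_z = 0, which is exactly
    independent 2D filtering of every slice.
    """
    data = stack.data
    channels = []
    for sigma in scale_set.sigmas:
        sig = (sigma, sigma, 0.0)
        dc = _second_derivative_dc(float(sigma))
        gain = _first_derivative_gain(float(sigma))
        resp = {}
        for order in ((0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2)):
            r = gaussian_filter(
                data, sig, order=(order[0], order[1], 0), mode=_BOUNDARY, truncate=_TRUNCATE
            )
            if 2 in order:
                r = r - dc * resp[(0, 0)]
            r = r * gain ** order.count(1)
            resp[order] = r * sigma ** sum(order)
        lam1, lam2 = hessian_eigenvalues_2d(resp[(2, 0)], resp[(1, 1)], resp[(0, 2)])
        channels += [
            resp[(0, 0)],
            np.sqrt(resp[(1, 0)] ** 2 + resp[(0, 1)] ** 2),
            lam1,
            lam2,
        ]
    return FeatureStack(np.stack(channels, axis=-1), scale_set, "f2d")


def extract_f3d(stack: ImageStack, scale_set: ScaleSet) -> FeatureStack:
    """Volumetric multiscale features: (smoothed, |grad|, l1, l2, l3) x n.

    Intended for near-isotropic stacks; warns when ``stack.rho`` exceeds
    ``rho_warn_threshold``.
    """
    return _extract_f3d(stack, scale_set, F3D_RHO_THRESHOLD)


def _extract_f3d(stack: ImageStack, scale_set: ScaleSet, rho_warn_threshold: float) -> FeatureStack:
    if stack.rho > rho_warn_threshold:
        warnings.warn(
            f"F3D assumes near-isotropic voxels but rho={stack.rho:.2f} > "
            f"{rho_warn_threshold}; consider the F2D extractor",
            stacklevel=2,
        )
    channels = []
    for sigma in scale_set.sigmas:
        s = derivative_responses_3d(stack.data, sigma)
        grad = np.sqrt(s[(1, 0, 0)] ** 2 + s[(0, 1, 0)] ** 2 + s[(0, 0, 1)] ** 2)
        hess = np.empty(stack.data.shape + (3, 3), dtype=np.float64)
        hess[..., 0, 0] = s[(2, 0, 0)]
        hess[..., 1, 1] = s[(0, 2, 0)]
        hess[..., 2, 2] = s[(0, 0, 2)]
        hess[..., 0, 1] = hess[..., 1, 0] = s[(1, 1, 0)]
        hess[..., 0, 2] = hess[..., 2, 0] = s[(1, 0, 1)]
        hess[..., 1, 2] = hess[..., 2, 1] = s[(0, 1, 1)]
        lam = np.linalg.eigvalsh(hess)[..., ::-1]  # descending
        channels += [s[(0, 0, 0)], grad, lam[..., 0], lam[..., 1], lam[..., 2]]
    return FeatureStack(np.stack(channels, axis=-1), scale_set, "f3d")


def choose_extractor(rho: float, threshold: float = F3D_RHO_THRESHOLD) -> str:
    """Automatic extractor choice: F3D for near-isotropic stacks, else F2D."""
    return "f3d" if rho <= threshold else "f2d"


def extract_features(
    stack: ImageStack,
    scale_set: ScaleSet,
    extractor: str = "auto",
    rho_threshold: float = F3D_RHO_THRESHOLD,
) -> FeatureStack:
    """Dispatch to :func:`extract_f2d` / :func:`extract_f3d`.

    ``extractor`` is one of ``"f2d"``, ``"f3d"`` or ``"auto"`` (select by
    the stack's anisotropy factor).
    """
    if extractor == "auto":
        extractor = choose_extractor(stack.rho, rho_threshold)
    if extractor == "f2d":
        return extract_f2d(stack, scale_set)
    if extractor == "f3d":
        return _extract_f3d(stack, scale_set, rho_threshold)
    raise ValueError(f"unknown extractor {extractor!r}; expected f2d, f3d or auto")
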