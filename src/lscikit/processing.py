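"""LSCI image processing: contrast maps, dynamic models, perfusion index.

Image-domain estimation of the local speckle contrast over a sliding window
(valid mode, no padding), the classical exposure-time contrast models, and
conversion of contrast to a perfusion index with a geometry-dependent
correction factor beta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.optimize import brentq

from .factors import RatioM
from .window_model import WindowSpec

__all__ = [
    "DynamicParams",
    "ContrastMap",
    "PIMap",
    "local_contrast_map",
    "fercher_briers_contrast",
    "temporal_contrast",
    "siegert_coefficients",
    "heterogeneous_contrast",
    "perfusion_index",
    "invert_correlation_time",
    "pi_map",
    "speckle_diameter",
    "pixel_speckle_ratio",
]


@dataclass(frozen=True)
class DynamicParams:
    """Exposure/decorrelation parameters of the dynamic contrast models.

    Attributes
    ----------
    T : float
        Camera exposure time in seconds.
    tau_c : float
        Correlation time of the backscattered field, seconds.
    beta : float
        Geometry correction factor in ``(0, 1]``.
    rho : float
        Fraction of detected light scattered by moving scatterers, ``[0, 1]``.
    Cn : float
        Additive noise offset on the contrast, ``>= 0``.
    """

    T: float
    tau_c: float
    beta: float = 1.0
    rho: float = 1.0
    Cn: float = 0.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("exposure time T must be positive")
        if self.tau_c <= 0:
            raise ValueError("correlation time tau_c must be positive")
        if not (0.0 < self.beta <= 1.0):
            raise ValueError("beta must lie in (0, 1]")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")
        if self.Cn < 0:
            raise ValueError("Cn must be >= 0")

    @property
    def x(self) -> float:
        """Exposure-to-correlation time ratio ``T / tau_c``."""
        return self.T / self.tau_c


@dataclass(frozen=True)
class ContrastMap:
    """Valid-mode sliding-window contrast raster.

    ``values[i, j]`` is the contrast of the window centred at image pixel
    ``(i + offset, j + offset)`` where ``offset = (side - 1) / 2``.  Windows
    with (near-)zero mean are flagged as NaN.
    """

    values: np.ndarray
    window: WindowSpec

    @property
    def offset(self) -> int:
        return (self.window.side - 1) // 2


@dataclass(frozen=True)
class PIMap:
    """Perfusion-index raster (1/seconds), georegistered like :class:`ContrastMap`."""

    values: np.ndarray
    window: WindowSpec
    beta: float
    T: float

    @property
    def offset(self) -> int:
        return (self.window.side - 1) // 2


def local_contrast_map(image: np.ndarray, side: int, p: int | None = None) -> ContrastMap:
    """Sliding-window contrast map: sqrt(unbiased variance) / mean, valid mode.

    Parameters
    ----------
    image : ndarray
        2-D non-negative intensity raster.
    side : int
        Odd window side ``L``; the output shrinks by ``L - 1`` per axis.
    p : int, optional
        Correlation-subregion half-width recorded in the output spec
        (defaults to ``(side - 1) / 2``); it does not affect the estimate.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {img.shape}")
    if np.any(img < 0):
        raise ValueError("image intensities must be non-negative")
    window = WindowSpec(side=side, p=(side - 1) // 2 if p is None else p)
    L = window.side
    if img.shape[0] < L or img.shape[1] < L:
        raise ValueError(f"image {img.shape} smaller than window side {L}")
    n = L * L
    mean = uniform_filter(img, size=L, mode="constant")
    mean_sq = uniform_filter(img * img, size=L, mode="constant")
    h = (L - 1) // 2
    sl = slice(h, img.shape[0] - h), slice(h, img.shape[1] - h)
    mean, mean_sq = mean[sl], mean_sq[sl]
    var = np.clip(mean_sq - mean * mean, 0.0, None) * (n / (n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.sqrt(var) / mean
    k[~(mean > 0)] = np.nan
    return ContrastMap(values=k, window=window)


def fercher_briers_contrast(T: float, tau_c: float) -> float:
    """Single-integration contrast model ``K = sqrt(tau_c/(2T) (1 - e^{-2T/tau_c}))``."""
    if T <= 0 or tau_c <= 0:
        raise ValueError("T and tau_c must be positive")
    x = T / tau_c
    return math.sqrt((1.0 - math.exp(-2.0 * x)) / (2.0 * x))


def _blur_kernel(x: float) -> float:
    """``(e^{-2x} - 1 + 2x) / (2 x^2)``, the double-integrated decorrelation term."""
    if x < 1e-3:
        # series around x=0 to avoid catastrophic cancellation
        return 1.0 - 2.0 * x / 3.0 + x * x / 3.0 - 2.0 * x**3 / 15.0
    return (math.expm1(-2.0 * x) + 2.0 * x) / (2.0 * x * x)


def _half_blur_kernel(x: float) -> float:
    """``(e^{-x} - 1 + x) / x^2``, the cross (static-dynamic) term."""
    if x < 1e-3:
        return 0.5 - x / 6.0 + x * x / 24.0 - x**3 / 120.0
    return (math.expm1(-x) + x) / (x * x)


def temporal_contrast(params: DynamicParams) -> float:
    """Dynamic-scatterer contrast ``K = sqrt(beta (e^{-2x} - 1 + 2x)/(2x^2))``."""
    return math.sqrt(params.beta * _blur_kernel(params.x))


def siegert_coefficients(rho: float) -> tuple[float, float]:
    """Static/dynamic mixing coefficients of the modified Siegert relation.

    ``A = rho^2`` weights the squared field autocorrelation and
    ``B = 2 rho (1 - rho)`` the unsquared one, with
    ``rho = If / (If + Is)`` the dynamic fraction; ``A + B <= 1``.
    """
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must lie in [0, 1]")
    return rho * rho, 2.0 * rho * (1.0 - rho)


def heterogeneous_contrast(params: DynamicParams) -> float:
    """Contrast with a static-scatterer fraction and noise offset.

    ``K = sqrt(beta) * sqrt(rho^2 D2(x) + 4 rho (1-rho) D1(x) + (1-rho)^2) + Cn``
    with ``D2`` the double-integrated and ``D1`` the single-lag blur kernels.
    Reduces to :func:`temporal_contrast` at ``rho = 1``, ``Cn = 0``.
    """
    rho, x = params.rho, params.x
    inner = (
        rho * rho * _blur_kernel(x)
        + 4.0 * rho * (1.0 - rho) * _half_blur_kernel(x)
        + (1.0 - rho) ** 2
    )
    return math.sqrt(params.beta) * math.sqrt(inner) + params.Cn


def perfusion_index(K: float, beta: float, T: float) -> float:
    """Perfusion index ``PI = beta / (T K^2)`` (valid for ``T >> tau_c``).

    Substituting the asymptotic contrast ``K^2 = beta / x`` recovers
    ``PI = 1 / tau_c`` exactly.
    """
    if T <= 0 or beta <= 0:
        raise ValueError("beta and T must be positive")
    if K <= 0:
        raise ValueError("undefined flow: contrast must be positive")
    return beta / (T * K * K)


def invert_correlation_time(K: float, T: float, beta: float = 1.0) -> float:
    """Correlation time ``tau_c`` solving ``temporal_contrast = K``.

    Bracketed root-find on ``x = T / tau_c`` over ``[1e-9, 1e9]``; the blur
    kernel is strictly decreasing in ``x`` so the root is unique.
    """
    if K <= 0:
        raise ValueError("contrast K must be positive")
    if T <= 0 or beta <= 0:
        raise ValueError("T and beta must be positive")
    target = K * K / beta
    if target >= 1.0:
        raise ValueError(f"no solution: K^2 = {K * K:g} must be below beta = {beta:g}")
    lo, hi = 1e-9, 1e9
    if target >= _blur_kernel(lo):
        raise OverflowError("contrast too close to sqrt(beta): tau_c exceeds 1e9 * T")
    if target <= _blur_kernel(hi):
        raise OverflowError("contrast too small: tau_c below 1e-9 * T")
    x = brentq(lambda t: _blur_kernel(t) - target, lo, hi, rtol=1e-15, maxiter=200)
    return T / x


def pi_map(cmap: ContrastMap, beta: float, T: float) -> PIMap:
    """Element-wise perfusion index of a contrast map; zero/NaN contrast -> NaN."""
    if T <= 0 or beta <= 0:
        raise ValueError("beta and T must be positive")
    k = cmap.values
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = beta / (T * k * k)
    pi = np.where(k > 0, pi, np.nan)
    return PIMap(values=pi, window=cmap.window, beta=beta, T=T)


def speckle_diameter(mag: float, wavelength: float, f_number: float) -> float:
    """Imaged speckle diameter ``2.44 (mag + 1) lambda f#`` (same units as lambda)."""
    if mag < 0 or wavelength <= 0 or f_number <= 0:
        raise ValueError("mag must be >= 0; wavelength and f_number positive")
    return 2.44 * (mag + 1.0) * wavelength * f_number


def pixel_speckle_ratio(pixel_pitch: float, speckle_diameter: float) -> RatioM:
    """Area ratio ``M = a^2 / (pi b^2)`` with speckle radius ``b = diameter / 2``.

    Note the diameter-to-radius convention: the Gaussian correlation radius
    ``b`` is half the nominal speckle size, so the factor of 4 matters.
    """
    if pixel_pitch <= 0 or speckle_diameter <= 0:
        raise ValueError("lengths must be positive")
    return RatioM.from_lengths(pixel_pitch, speckle_diameter / 2.0)
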