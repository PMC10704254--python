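"""Inter-pixel correlation factors for Gaussian speckle.

A square camera pixel of pitch ``a`` samples a speckle field whose intensity
autocovariance is Gaussian with correlation radius ``b``.  The dimensionless
ratio ``M = a**2 / (pi * b**2)`` (pixel area over speckle correlation area)
fully determines how strongly two pixels separated by an integer offset
``(eta, xi)`` are correlated.  This module provides

* :func:`gk_factor` -- the separable 1-D factor ``G_k(M)``,
* :func:`correlation_factor` -- the closed-form 2-D factor
  ``G_eta(M) * G_xi(M)``,
* :func:`correlation_factor_numeric` -- an independent 4-D tensor-product
  Gauss-Legendre quadrature of the defining double-pixel integral (used as
  an oracle; it never touches the separable closed form),
* :func:`factor_table` -- the triangular table of factors needed for a
  correlation subregion of half-width ``p``.

All factors lie in ``(0, 1]``: 1 means perfect correlation (coincident
pixels in the small-``M`` limit), values decay monotonically with pixel
separation and with ``M``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import erf

__all__ = [
    "RatioM",
    "FactorTable",
    "gk_factor",
    "correlation_factor",
    "correlation_factor_numeric",
    "factor_table",
]

_MIN_QUAD_NODES = 8


@dataclass(frozen=True)
class RatioM:
    """Ratio of pixel area to speckle correlation area, ``M = a^2 / (pi b^2)``.

    Parameters
    ----------
    M : float
        Positive dimensionless ratio.  ``M < 1`` means a single speckle
        grain spans several pixels.
    """

    M: float

    def __post_init__(self) -> None:
        if not (self.M > 0) or not math.isfinite(self.M):
            raise ValueError(f"M must be a positive finite number, got {self.M!r}")

    @classmethod
    def from_lengths(cls, pixel_pitch: float, speckle_radius: float) -> "RatioM":
        """Build the ratio from the pixel pitch ``a`` and speckle radius ``b``."""
        if pixel_pitch <= 0 or speckle_radius <= 0:
            raise ValueError("pixel_pitch and speckle_radius must be positive")
        return cls(pixel_pitch**2 / (math.pi * speckle_radius**2))

    def __float__(self) -> float:
        return self.M


def _as_m(M: "RatioM | float") -> float:
    m = float(M)
    if not (m > 0) or not math.isfinite(m):
        raise ValueError(f"M must be a positive finite number, got {M!r}")
    return m


def gk_factor(k: int, M: "RatioM | float") -> float:
    """Separable 1-D correlation factor ``G_k(M)`` for pixel offset ``k``.

    ``G_k`` is the normalized 1-D integral of the Gaussian kernel
    ``exp(-pi*M*(x - x')**2)`` over two unit pixels offset by ``k``:

    .. math::

        G_k = \\frac{e^{-\\pi M (k-1)^2} - 2 e^{-\\pi M k^2}
                     + e^{-\\pi M (k+1)^2}}{2\\pi M}
              + \\frac{(k-1)\\,\\mathrm{erf}(\\sqrt{\\pi M}(k-1))
                     - 2k\\,\\mathrm{erf}(\\sqrt{\\pi M} k)
                     + (k+1)\\,\\mathrm{erf}(\\sqrt{\\pi M}(k+1))}{2\\sqrt{M}}

    The 2-D factor for offset ``(eta, xi)`` is ``G_eta * G_xi``.  At
    ``k = 0`` this reduces to the classical single-pixel contrast
    ``erf(sqrt(pi M))/sqrt(M) - (1 - exp(-pi M))/(pi M)``.

    Parameters
    ----------
    k : int
        Non-negative pixel offset along one axis.
    M : RatioM or float
        Pixel-to-speckle area ratio, ``> 0``.

    Returns
    -------
    float
        Factor in ``(0, 1]``.
    """
    m = _as_m(M)
    if k < 0 or int(k) != k:
        raise ValueError(f"offset k must be a non-negative integer, got {k!r}")
    k = int(k)
    s = math.sqrt(math.pi * m)
    exp_part = (
        math.exp(-math.pi * m * (k - 1) ** 2)
        - 2.0 * math.exp(-math.pi * m * k**2)
        + math.exp(-math.pi * m * (k + 1) ** 2)
    ) / (2.0 * math.pi * m)
    erf_part = (
        (k - 1) * erf(s * (k - 1))
        - 2.0 * k * erf(s * k)
        + (k + 1) * erf(s * (k + 1))
    ) / (2.0 * math.sqrt(m))
    # Mathematically G_k <= 1; guard against the last-ulp overshoot in the
    # fully-correlated limit M -> 0.
    return min(float(exp_part + erf_part), 1.0)


def correlation_factor(eta: int, xi: int, M: "RatioM | float") -> float:
    """Closed-form 2-D correlation factor for pixel offset ``(eta, xi)``.

    Negative offsets are folded by absolute value: the factor depends only
    on the separation between the pixels, and it is symmetric under
    ``(eta, xi) -> (xi, eta)``.

    Returns
    -------
    float
        ``G_|eta|(M) * G_|xi|(M)``, in ``(0, 1]``.
    """
    return gk_factor(abs(int(eta)), M) * gk_factor(abs(int(xi)), M)


def correlation_factor_numeric(
    eta: int,
    xi: int,
    M: "RatioM | float",
    nodes_per_axis: int = 48,
) -> float:
    """4-D quadrature of the defining double-pixel correlation integral.

    Evaluates

    .. math::

        \\frac{1}{a^4} \\int_{pixel(\\eta,\\xi)} \\int_{pixel(0,0)}
            e^{-(|\\vec r - \\vec r\\,'|^2)/b^2}
            \\, d^2 r' \\, d^2 r

    by tensor-product Gauss-Legendre quadrature in pixel units
    (``1/b^2 = pi M``).  This routine deliberately ignores the separable
    closed form and serves as the independent numerical oracle for
    :func:`correlation_factor`.

    Parameters
    ----------
    nodes_per_axis : int
        Gauss-Legendre nodes per axis (4 axes); at least 8.
    """
    m = _as_m(M)
    n = int(nodes_per_axis)
    if n < _MIN_QUAD_NODES:
        raise ValueError(
            f"nodes_per_axis={n} gives insufficient resolution; need >= {_MIN_QUAD_NODES}"
        )
    eta, xi = abs(int(eta)), abs(int(xi))
    t, w = leggauss(n)
    t *= 0.5  # map [-1, 1] -> [-1/2, 1/2]
    w *= 0.5
    c = math.pi * m
    # 4-D integrand F[i,j,k,l] = exp(-pi M [(x_i - x'_k)^2 + (y_j - y'_l)^2])
    # with x over pixel (eta, .), y over pixel (., xi).
    dx = (t[:, None] + eta) - t[None, :]
    dy = (t[:, None] + xi) - t[None, :]
    ax = np.exp(-c * dx**2)
    ay = np.exp(-c * dy**2)
    integrand = ax[:, None, :, None] * ay[None, :, None, :]
    w4 = w[:, None, None, None] * w[None, :, None, None] * w[None, None, :, None] * w[None, None, None, :]
    return float(np.sum(w4 * integrand))


@dataclass(frozen=True)
class FactorTable:
    """Triangular table of correlation factors ``0 <= xi <= eta <= p``.

    Lookups fold sign and order, so ``table[(-1, 2)]`` returns the
    ``(2, 1)`` entry.
    """

    M: RatioM
    p: int
    entries: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p < 0:
            raise ValueError("subregion half-width p must be >= 0")

    def __getitem__(self, key) -> float:
        eta, xi = (abs(int(k)) for k in key)
        if xi > eta:
            eta, xi = xi, eta
        return self.entries[(eta, xi)]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.items())

    def to_json(self) -> str:
        """Serialize as JSON with ``"eta,xi"`` keys and full-precision values."""
        payload = {
            "M": repr(self.M.M),
            "p": self.p,
            "entries": {f"{eta},{xi}": repr(v) for (eta, xi), v in sorted(self.entries.items())},
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FactorTable":
        payload = json.loads(text)
        entries = {
            tuple(int(s) for s in key.split(",")): float(v)
            for key, v in payload["entries"].items()
        }
        return cls(M=RatioM(float(payload["M"])), p=int(payload["p"]), entries=entries)


def factor_table(M: "RatioM | float", p: int) -> FactorTable:
    """Tabulate :func:`correlation_factor` for all ``0 <= xi <= eta <= p``."""
    m = _as_m(M)
    if p < 0 or int(p) != p:
        raise ValueError(f"subregion half-width p must be a non-negative integer, got {p!r}")
    p = int(p)
    g = [gk_factor(k, m) for k in range(p + 1)]
    entries = {
        (eta, xi): g[eta] * g[xi] for eta in range(p + 1) for xi in range(eta + 1)
    }
    return FactorTable(M=RatioM(m), p=p, entries=entries)
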