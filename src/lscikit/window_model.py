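"""Windowed spatial speckle contrast with inter-pixel correlation.

The local contrast of a speckle image is conventionally estimated over an
``L x L`` sliding window (``L`` odd) as the sample standard deviation over
the window divided by the window mean.  When the speckle grain is not small
compared to the pixel, neighbouring pixels in the window are correlated and
the expected squared contrast is no longer the single-pixel value.

This module evaluates the expected squared windowed contrast

    Ks^2(L, p) = F(0,0) - 1/(L^2 (L^2 - 1)) * [
                   sum_eta 4 L (L - eta)   F(eta, 0)      (lateral)
                 + sum_eta 4 (L - eta)^2   F(eta, eta)    (diagonal)
                 + sum_{xi<eta} 8 (L-eta)(L-xi) F(eta, xi) (knight)
                 ]

where ``F`` is the correlation factor of :mod:`lscikit.factors` and the sums
run over offsets inside a ``(2p+1) x (2p+1)`` correlation subregion; pixel
pairs at larger separations ("outsiders") are modelled as uncorrelated.

A literal pair-enumeration oracle (:func:`window_statistics_oracle`) computes
the same quantity from first principles and is used to validate the
combinatorics; it can optionally keep the outsider correlations, which gives
the exact expectation for a fully Gaussian-correlated field.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

from .factors import RatioM, factor_table, gk_factor

__all__ = [
    "WindowSpec",
    "MultiplicityTable",
    "ContrastCurve",
    "CorrelationTruncationWarning",
    "pair_multiplicities",
    "outsider_count",
    "coefficient_table",
    "spatial_contrast_sq",
    "spatial_contrast",
    "beta_uncorrected",
    "contrast_curve",
    "window_statistics_oracle",
]

_ORACLE_MAX_SIDE = 9


class CorrelationTruncationWarning(UserWarning):
    """The chosen subregion half-width leaves significant correlation outside."""


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: odd side ``L`` and subregion half-width ``p``.

    The correlation subregion is ``(2p+1) x (2p+1)`` and must fit inside the
    window (``2p+1 <= side``).
    """

    side: int
    p: int

    def __post_init__(self) -> None:
        if self.side < 1 or self.side % 2 == 0:
            raise ValueError(f"window side must be an odd positive integer, got {self.side}")
        if self.p < 0:
            raise ValueError(f"subregion half-width p must be >= 0, got {self.p}")
        if 2 * self.p + 1 > self.side:
            raise ValueError(
                f"correlation subregion (2p+1)={2 * self.p + 1} exceeds window side {self.side}"
            )

    @classmethod
    def full(cls, side: int) -> "WindowSpec":
        """Window whose correlation subregion fills it: ``p = (side - 1) / 2``."""
        return cls(side=side, p=(side - 1) // 2)

    @property
    def n_pixels(self) -> int:
        return self.side * self.side


@dataclass(frozen=True)
class MultiplicityTable:
    """Counts of ordered pixel pairs in an ``L x L`` window by offset class."""

    window: WindowSpec
    central: int
    lateral: dict
    diagonal: dict
    knight: dict
    outsiders: int

    @property
    def total(self) -> int:
        return (
            self.central
            + sum(self.lateral.values())
            + sum(self.diagonal.values())
            + sum(self.knight.values())
            + self.outsiders
        )


@dataclass(frozen=True)
class ContrastCurve:
    """Contrast ``Ks`` sampled over a grid of area ratios ``M``."""

    window: WindowSpec
    M_values: np.ndarray
    K_values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.M_values) != len(self.K_values):
            raise ValueError("M and K sequences must have equal length")

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("M,K,K_sq\n")
            for m, k in zip(self.M_values, self.K_values):
                m, k = float(m), float(k)
                fh.write(f"{m!r},{k!r},{k * k!r}\n")


def pair_multiplicities(window: WindowSpec) -> MultiplicityTable:
    """Count ordered pixel pairs of an ``L x L`` window by correlation class.

    Classes by absolute offset ``(eta, xi)`` with ``eta >= xi``: central
    ``(0,0)``, lateral ``(eta,0)``, diagonal ``(eta,eta)``, knight
    ``(eta,xi)`` with ``0 < xi < eta``; pairs whose offset leaves the
    ``(2p+1) x (2p+1)`` subregion are outsiders.

    The closed forms are ``L^2``, ``4 L (L-eta)``, ``4 (L-eta)^2`` and
    ``8 (L-eta)(L-xi)``; they are validated against exhaustive enumeration in
    the test-suite.
    """
    L, p = window.side, window.p
    lateral = {eta: 4 * L * (L - eta) for eta in range(1, p + 1)}
    diagonal = {eta: 4 * (L - eta) ** 2 for eta in range(1, p + 1)}
    knight = {
        (eta, xi): 8 * (L - eta) * (L - xi)
        for xi in range(1, p)
        for eta in range(xi + 1, p + 1)
    }
    central = L * L
    correlated = central + sum(lateral.values()) + sum(diagonal.values()) + sum(knight.values())
    return MultiplicityTable(
        window=window,
        central=central,
        lateral=lateral,
        diagonal=diagonal,
        knight=knight,
        outsiders=L**4 - correlated,
    )


def outsider_count(window: WindowSpec) -> int:
    """Number of ordered pixel pairs with offset outside the subregion.

    Closed form ``L^4 - (L (1 + 2p) - p (1 + p))^2``; identical to the
    enumeration count of :func:`pair_multiplicities`.
    """
    L, p = window.side, window.p
    return L**4 - (L * (1 + 2 * p) - p * (1 + p)) ** 2


def coefficient_table(window: WindowSpec) -> dict:
    """Exact rational weights of each correlation factor in ``Ks^2``.

    Returns a map from offset ``(eta, xi)`` (with ``0 < xi <= eta <= p``, or
    ``xi = 0``) to the negative rational coefficient that multiplies the
    correlation factor ``F(eta, xi)`` in the windowed-contrast formula:
    ``-4 L (L-eta) / D`` (lateral), ``-4 (L-eta)^2 / D`` (diagonal) and
    ``-8 (L-eta)(L-xi) / D`` (knight), with ``D = L^2 (L^2 - 1)``.
    """
    L, p = window.side, window.p
    if p == 0:
        return {}
    D = Fraction(L * L * (L * L - 1))
    table: dict = {}
    for eta in range(1, p + 1):
        table[(eta, 0)] = Fraction(-4 * L * (L - eta)) / D
        table[(eta, eta)] = Fraction(-4 * (L - eta) ** 2) / D
    for xi in range(1, p):
        for eta in range(xi + 1, p + 1):
            table[(eta, xi)] = Fraction(-8 * (L - eta) * (L - xi)) / D
    return table


def _truncation_check(window: WindowSpec, m: float) -> None:
    if 2 * window.p + 1 < window.side and gk_factor(window.p + 1, m) > 0.01:
        warnings.warn(
            f"subregion half-width p={window.p} truncates significant correlation "
            f"at M={m:g} (G_{window.p + 1} = {gk_factor(window.p + 1, m):.3f} > 0.01); "
            "the contrast model will over-estimate the true windowed contrast",
            CorrelationTruncationWarning,
            stacklevel=3,
        )


def spatial_contrast_sq(window: WindowSpec, M: "RatioM | float") -> float:
    """Expected squared windowed contrast ``Ks^2`` for area ratio ``M``.

    For ``p = 0`` this equals the single-pixel factor ``F(0, 0)``; for
    ``p >= 1`` the correlated pairs reduce the variance and the lateral,
    diagonal and knight terms are subtracted with the weights of
    :func:`coefficient_table`.
    """
    m = float(M if not isinstance(M, RatioM) else M.M)
    table = factor_table(m, window.p)
    _truncation_check(window, m)
    ks2 = table[(0, 0)]
    for offset, coeff in coefficient_table(window).items():
        ks2 += float(coeff) * table[offset]
    if ks2 < 0.0:
        # only reachable through floating-point round-off in degenerate limits
        warnings.warn("Ks^2 rounded below zero; clipping to 0", RuntimeWarning, stacklevel=2)
        ks2 = 0.0
    return ks2


def spatial_contrast(window: WindowSpec, M: "RatioM | float") -> float:
    """Expected windowed contrast ``Ks = sqrt(Ks^2)``."""
    return math.sqrt(spatial_contrast_sq(window, M))


def beta_uncorrected(M: "RatioM | float") -> float:
    """Single-pixel contrast with no inter-pixel correlation (``p = 0``).

    Equals ``erf(sqrt(pi M))/sqrt(M) - (1 - exp(-pi M))/(pi M)``; tends to 1
    as ``M -> 0`` and decreases monotonically with ``M``.
    """
    return gk_factor(0, M)


def contrast_curve(window: WindowSpec, M_grid: Sequence[float]) -> ContrastCurve:
    """Evaluate :func:`spatial_contrast` over a strictly increasing ``M`` grid."""
    grid = np.asarray(list(M_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("M grid must be non-empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("M grid must be strictly increasing")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", CorrelationTruncationWarning)
        k = np.array([spatial_contrast(window, m) for m in grid])
    return ContrastCurve(window=window, M_values=grid, K_values=k)


def window_statistics_oracle(
    window: WindowSpec,
    M: "RatioM | float",
    truncate_outsiders: bool = True,
) -> float:
    """``Ks^2`` by literal enumeration of all ``L^4`` ordered pixel pairs.

    Computes the expectation of the unbiased window variance over the squared
    mean intensity from first principles: each ordered pair at offset
    ``(d_eta, d_xi)`` contributes ``<I>^2 (1 + F(d_eta, d_xi))`` to the mean
    of the squared window average, with ``F = 0`` for outsider pairs when
    ``truncate_outsiders`` is true.  With truncation this is algebraically
    identical to :func:`spatial_contrast_sq` and validates its combinatorics;
    without truncation it is the exact expectation for a field that is
    Gaussian-correlated at every separation.

    Only intended for small windows (``side <= 9``).
    """
    L, p = window.side, window.p
    if L > _ORACLE_MAX_SIDE:
        raise ValueError(f"oracle limited to side <= {_ORACLE_MAX_SIDE}, got {L}")
    m = float(M if not isinstance(M, RatioM) else M.M)
    g = [gk_factor(k, m) for k in range(L)]
    n = L * L
    total = 0.0  # sum over ordered pairs of (1 + 1/mu)
    for r1 in range(L):
        for c1 in range(L):
            for r2 in range(L):
                for c2 in range(L):
                    de, dx = abs(r1 - r2), abs(c1 - c2)
                    if truncate_outsiders and (de > p or dx > p):
                        f = 0.0
                    else:
                        f = g[de] * g[dx]
                    total += 1.0 + f
    mean_i_sq = total / (n * n)  # <i^2> / <I>^2
    mean_pix_sq = 1.0 + g[0] * g[0]  # <I_pix^2> / <I>^2
    return (-n * mean_i_sq + n * mean_pix_sq) / (n - 1)
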