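"""Discrete kernels for the wavelet front-end.

Three kernels drive the coarse stage of the detector:

* the classical Mexican Hat (Ricker) wavelet, the negative normalized
  second derivative of a Gaussian, whose zero-mean band-pass shape responds
  to gray-level transitions;
* a radial Gaussian modulation ``exp(-(r - R)^2 / delta^2)`` that
  concentrates the wavelet's response on an annulus of radius ``R``,
  raising sensitivity to ring structures away from the kernel center;
* a difference-of-Gaussians (DoG) band-pass used to sharpen the fused
  multi-scale response and separate bright rings from the background.

All kernels are evaluated at integer pixel offsets on a square grid with an
odd side length, so a center pixel exists and the 8-fold dihedral symmetry
of the continuous profiles is preserved exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WaveletParams",
    "DoGParams",
    "make_mexican_hat",
    "make_radial_enhancement",
    "make_enhanced_kernel",
    "make_dog_kernel",
]


@dataclass(frozen=True)
class WaveletParams:
    """Parameters of the radially modulated Mexican Hat wavelet.

    Parameters
    ----------
    sigma : float
        Scale factor in pixels; controls the width of the Ricker profile.
    target_radius : float, optional
        Center ``R`` of the radial enhancement annulus, in pixels.
        Defaults to ``sigma``, which ties the annulus to the scale and
        keeps the kernel compact.
    radial_bandwidth : float, optional
        Width ``delta`` of the annulus, in pixels. Defaults to ``sigma``.
    truncation_factor : float
        Kernel half-width is ``ceil(max(truncation_factor * sigma,
        R + 3 * delta))``; the default 4 captures essentially all of the
        support of both factors.
    radial_term : {"r", "r2"}
        ``"r"`` (default) modulates by ``exp(-(r - R)^2 / delta^2)`` with
        ``r = sqrt(x^2 + y^2)``, which is dimensionally consistent.
        ``"r2"`` keeps the literal squared-radius form
        ``exp(-(r^2 - R)^2 / delta^2)``.
    """

    sigma: float
    target_radius: float | None = None
    radial_bandwidth: float | None = None
    truncation_factor: float = 4.0
    radial_term: str = "r"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.target_radius is not None and self.target_radius < 0:
            raise ValueError("target_radius must be non-negative")
        if self.radial_bandwidth is not None and self.radial_bandwidth <= 0:
            raise ValueError("radial_bandwidth must be positive")
        if self.truncation_factor <= 0:
            raise ValueError("truncation_factor must be positive")
        if self.radial_term not in ("r", "r2"):
            raise ValueError("radial_term must be 'r' or 'r2'")

    @property
    def R(self) -> float:
        return self.sigma if self.target_radius is None else self.target_radius

    @property
    def delta(self) -> float:
        return self.sigma if self.radial_bandwidth is None else self.radial_bandwidth

    @property
    def half_width(self) -> int:
        return int(math.ceil(max(self.truncation_factor * self.sigma,
                                 self.R + 3.0 * self.delta)))


@dataclass(frozen=True)
class DoGParams:
    """Difference-of-Gaussians parameters: inner sd ``sigma1 < sigma2``."""

    sigma1: float = 1.0
    sigma2: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.sigma1 < self.sigma2:
            raise ValueError(
                f"need 0 < sigma1 < sigma2, got {self.sigma1}, {self.sigma2}")

    @property
    def half_width(self) -> int:
        return int(math.ceil(4.0 * self.sigma2))


def _offset_grid(half_width: int) -> tuple[np.ndarray, np.ndarray]:
    ax = np.arange(-half_width, half_width + 1, dtype=float)
    # xx varies along columns, yy along rows
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    return xx, yy


def make_mexican_hat(sigma: float, half_width: int) -> np.ndarray:
    """Classical 2-D Mexican Hat (Ricker) wavelet on an odd square grid.

    ``h(x, y) = (1/sigma^2) (2 - r^2/sigma^2) exp(-r^2 / (2 sigma^2))``
    with ``r^2 = x^2 + y^2``. Positive central lobe of radius
    ``sqrt(2) * sigma`` surrounded by a negative annulus.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    xx, yy = _offset_grid(int(half_width))
    r2 = xx * xx + yy * yy
    s2 = sigma * sigma
    return (1.0 / s2) * (2.0 - r2 / s2) * np.exp(-r2 / (2.0 * s2))


def make_radial_enhancement(R: float, delta: float, half_width: int,
                            radial_term: str = "r") -> np.ndarray:
    """Radial Gaussian modulation, maximal (==1) on the circle ``r = R``."""
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    if R < 0:
        raise ValueError(f"R must be non-negative, got {R}")
    xx, yy = _offset_grid(int(half_width))
    r2 = xx * xx + yy * yy
    if radial_term == "r":
        t = np.sqrt(r2) - R
    elif radial_term == "r2":
        t = r2 - R
    else:
        raise ValueError("radial_term must be 'r' or 'r2'")
    return np.exp(-(t * t) / (delta * delta))


def make_enhanced_kernel(params: WaveletParams) -> np.ndarray:
    """Radially modulated Mexican Hat wavelet.

    Elementwise product of :func:`make_mexican_hat` and
    :func:`make_radial_enhancement` on the grid implied by
    ``params.half_width``. Depends only on ``r``, hence exactly symmetric
    under the dihedral symmetries of the grid.
    """
    hw = params.half_width
    base = make_mexican_hat(params.sigma, hw)
    mod = make_radial_enhancement(params.R, params.delta, hw,
                                  radial_term=params.radial_term)
    return base * mod


def make_dog_kernel(params: DoGParams, half_width: int | None = None) -> np.ndarray:
    """Difference of two unit-mass Gaussians; sums to ~0 over wide support."""
    hw = params.half_width if half_width is None else int(half_width)
    xx, yy = _offset_grid(hw)
    r2 = xx * xx + yy * yy
    s1, s2 = params.sigma1 ** 2, params.sigma2 ** 2
    g1 = np.exp(-r2 / (2.0 * s1)) / (2.0 * np.pi * s1)
    g2 = np.exp(-r2 / (2.0 * s2)) / (2.0 * np.pi * s2)
    return g1 - g2
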