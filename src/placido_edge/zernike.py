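"""Zernike-moment step-edge model and sub-pixel localization.

An ideal step edge inside the unit disc is described by four parameters:
the background level ``h``, the step height ``k``, the signed distance
``l`` of the edge line from the disc center (unit-disc units), and the
angle ``theta`` of the edge normal. The low-order Zernike moments of a
window determine these parameters in closed form, and the edge position
maps back to sub-pixel image coordinates via the template size ``N``:

    xs = col + (N*l/2) * cos(theta),   ys = row + (N*l/2) * sin(theta).

Moments are computed with precomputed ``N x N`` templates obtained by
integrating the Zernike polynomials V00 = 1, V11 = rho*e^{i*theta},
V20 = 2*rho^2 - 1 over each pixel cell's intersection with the unit disc
(the N x N square inscribes the disc, so a cell has side 2/N). Cells
wholly outside the disc get zero weight; partial cells are handled by
midpoint subsampling, which realizes the pixel-area weight of the
discrete moment definition.

Conventions
-----------
* Moments carry the ``(n+1)/pi`` normalization, so a uniform window of
  value ``c`` has ``z00 = c``.
* The closed-form parameter equations invert the step model for
  *unnormalized* disc integrals, so :func:`edge_parameters` rescales by
  ``pi/(n+1)`` internally before applying them.
* The angular factor of the m11 template is chosen as ``x + i*y`` in
  (column, row-down) coordinates, so that ``atan2(Im z11, Re z11)`` is the
  edge-normal direction in image coordinates and the displacement formula
  above holds without sign juggling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ZernikeMaskSet",
    "EdgeCandidate",
    "build_masks",
    "compute_moments",
    "moment_fields",
    "edge_parameters",
    "subpixel_coordinates",
]

_MASK_CACHE: dict[tuple[int, int], "ZernikeMaskSet"] = {}

#: |l| is clamped below 1 before the (1-l^2)^(3/2) power; larger raw values
#: indicate the window violates the single-step model.
L_CLAMP = 0.999


@dataclass(frozen=True)
class ZernikeMaskSet:
    """Moment templates for orders (0,0), (1,1), (2,0) on an N x N grid."""

    size: int
    subsampling: int
    m00: np.ndarray
    m11: np.ndarray  # complex
    m20: np.ndarray


@dataclass
class EdgeCandidate:
    """One coarse-edge pixel with its moments, step parameters and verdict."""

    row: int
    col: int
    z00: float = 0.0
    z11: complex = 0.0
    z20: float = 0.0
    z11p: float = 0.0
    l: float = 0.0
    k: float = 0.0
    h: float = 0.0
    theta: float = 0.0
    kt: float = np.nan
    lt: float = np.nan
    model_ok: bool = True
    accepted: bool = False
    xs: float = np.nan
    ys: float = np.nan


def build_masks(size: int = 9, subsampling: int = 64) -> ZernikeMaskSet:
    """Build (and cache) the three moment templates by cell integration.

    Each entry is the integral of the polynomial over the cell's
    intersection with the unit disc, approximated with ``subsampling**2``
    midpoint samples per cell; samples outside the disc contribute zero.
    """
    size = int(size)
    subsampling = int(subsampling)
    if size < 3 or size % 2 == 0:
        raise ValueError(f"template size must be odd and >= 3, got {size}")
    if subsampling < 8:
        raise ValueError(f"subsampling must be >= 8, got {subsampling}")
    key = (size, subsampling)
    if key in _MASK_CACHE:
        return _MASK_CACHE[key]

    cell = 2.0 / size
    centers = (np.arange(size) - (size - 1) / 2.0) * cell
    sub = ((np.arange(subsampling) + 0.5) / subsampling - 0.5) * cell
    w = (cell / subsampling) ** 2  # area element per sample

    m00 = np.zeros((size, size))
    m11 = np.zeros((size, size), dtype=complex)
    m20 = np.zeros((size, size))
    for i in range(size):       # rows -> y
        y = centers[i] + sub
        for j in range(size):   # cols -> x
            x = centers[j] + sub
            yy, xx = np.meshgrid(y, x, indexing="ij")
            rho2 = xx * xx + yy * yy
            inside = rho2 <= 1.0
            if not inside.any():
                continue
            m00[i, j] = w * np.count_nonzero(inside)
            m11[i, j] = w * ((xx + 1j * yy)[inside]).sum()
            m20[i, j] = w * ((2.0 * rho2 - 1.0)[inside]).sum()
    masks = ZernikeMaskSet(size=size, subsampling=subsampling,
                           m00=m00, m11=m11, m20=m20)
    _MASK_CACHE[key] = masks
    return masks


def compute_moments(image: np.ndarray, masks: ZernikeMaskSet,
                    at: tuple[int, int]) -> tuple[float, complex, float]:
    """Normalized moments (z00, z11, z20) of the window centered at ``at``.

    Windows extending beyond the image are reflect-padded.
    """
    row, col = int(at[0]), int(at[1])
    n = masks.size
    half = n // 2
    padded = np.pad(np.asarray(image, dtype=float),
                    ((half, half), (half, half)), mode="symmetric")
    win = padded[row:row + n, col:col + n]
    z00 = float((win * masks.m00).sum() / np.pi)
    z11 = complex((win * masks.m11).sum() * (2.0 / np.pi))
    z20 = float((win * masks.m20).sum() * (3.0 / np.pi))
    return z00, z11, z20


def moment_fields(image: np.ndarray, masks: ZernikeMaskSet
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moments at every pixel via correlation (reflective boundaries)."""
    img = np.asarray(image, dtype=float)
    corr = lambda m: ndimage.correlate(img, m, mode="reflect")
    z00 = corr(masks.m00) / np.pi
    z11 = (corr(masks.m11.real) + 1j * corr(masks.m11.imag)) * (2.0 / np.pi)
    z20 = corr(masks.m20) * (3.0 / np.pi)
    return z00, z11, z20


def edge_parameters(z00, z11, z20, *, min_gradient: float = 1e-12):
    """Invert the step-edge model: moments -> (l, k, h, theta).

    Accepts scalars or arrays. Where ``|z11|`` falls below ``min_gradient``
    the window is flat and (l, k) are reported as zero; such candidates are
    rejected upstream. ``l`` is clamped to ``|l| <= 0.999`` before the
    ``(1 - l^2)^{3/2}`` power.
    """
    z11 = np.asarray(z11, dtype=complex)
    scalar = z11.ndim == 0
    z00 = np.broadcast_to(np.asarray(z00, dtype=float), z11.shape).astype(float)
    z20 = np.broadcast_to(np.asarray(z20, dtype=float), z11.shape).astype(float)
    z11 = np.atleast_1d(z11)
    z00, z20 = np.atleast_1d(z00), np.atleast_1d(z20)

    theta = np.arctan2(z11.imag, z11.real)
    z11p = np.abs(z11)  # == Re(z11 * exp(-i*theta))
    # undo the (n+1)/pi normalization: the closed forms hold for raw
    # disc integrals of the step model
    a00 = z00 * np.pi
    a11 = z11p * (np.pi / 2.0)
    a20 = z20 * (np.pi / 3.0)

    flat = a11 <= min_gradient
    safe_a11 = np.where(flat, 1.0, a11)
    l = np.clip(np.where(flat, 0.0, a20 / safe_a11), -L_CLAMP, L_CLAMP)
    k = np.where(flat, 0.0, 3.0 * a11 / (2.0 * (1.0 - l * l) ** 1.5))
    h = (a00 - k * np.pi / 2.0 + k * np.arcsin(l)
         + k * l * np.sqrt(1.0 - l * l)) / np.pi
    if scalar:
        return float(l[0]), float(k[0]), float(h[0]), float(theta[0])
    return l, k, h, theta


def subpixel_coordinates(row, col, l, theta, size: int = 9):
    """Map a candidate pixel and its (l, theta) to sub-pixel (xs, ys).

    ``xs`` is a column coordinate, ``ys`` a row coordinate; the edge point
    is displaced from the pixel center by ``size*l/2`` pixels along the
    edge normal.
    """
    d = size * np.asarray(l, dtype=float) / 2.0
    xs = np.asarray(col, dtype=float) + d * np.cos(theta)
    ys = np.asarray(row, dtype=float) + d * np.sin(theta)
    if xs.ndim == 0:
        return float(xs), float(ys)
    return xs, ys
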