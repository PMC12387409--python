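"""Adaptive acceptance thresholds for Zernike edge candidates.

Two per-pixel thresholds gate the candidates:

* ``kt`` — a gray-level threshold fusing the local gradient magnitude
  ``gk = |Z11|`` with the 5x5 mean/variance statistics of the Z20 field:
  ``kt = (gk^2 + sd^2 + ln(1 + var)) / 5``. A candidate must have step
  height ``k >= kt``.
* ``lt`` — a distance threshold derived from the principal curvature of
  the response field: with ``lk`` the largest absolute eigenvalue of the
  per-pixel Hessian, ``lt = 2/N + 0.2 * lk`` (the sign of the curvature
  term is configurable). A candidate must have ``|l| <= lt``.

All statistics are computed on [0, 1]-normalized fields so that ``kt`` is
commensurate with the recovered step height ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .zernike import EdgeCandidate

__all__ = [
    "ThresholdFields",
    "gray_threshold_field",
    "distance_threshold_field",
    "gate_candidates",
]

_D2 = np.array([1.0, -2.0, 1.0])      # central second difference
_D1 = np.array([-0.5, 0.0, 0.5])      # central first difference


@dataclass
class ThresholdFields:
    gk: np.ndarray
    mu: np.ndarray
    var: np.ndarray
    sd: np.ndarray
    kt: np.ndarray
    lk: np.ndarray | None = None
    lt: np.ndarray | None = None


def gray_threshold_field(z11_field: np.ndarray,
                         z20_field: np.ndarray) -> ThresholdFields:
    """Per-pixel gray threshold from gradient and 5x5 local statistics.

    Mean uses divisor 25, variance the unbiased divisor 24; borders are
    reflect-padded.
    """
    z11_field = np.asarray(z11_field)
    z20 = np.asarray(z20_field, dtype=float)
    if z11_field.shape != z20.shape:
        raise ValueError("z11 and z20 fields must share a shape")
    gk = np.abs(z11_field)
    mu = ndimage.uniform_filter(z20, size=5, mode="reflect")
    m2 = ndimage.uniform_filter(z20 * z20, size=5, mode="reflect")
    var = np.clip(m2 - mu * mu, 0.0, None) * (25.0 / 24.0)
    sd = np.sqrt(var)
    kt = (gk * gk + var + np.log1p(var)) / 5.0
    return ThresholdFields(gk=gk, mu=mu, var=var, sd=sd, kt=kt)


def distance_threshold_field(response: np.ndarray, size: int = 9,
                             curvature_sign: int = 1
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel distance threshold from Hessian principal curvature.

    Second derivatives by central differences with reflective borders;
    ``lk`` is the largest absolute eigenvalue of the symmetric 2x2 Hessian.
    Returns ``(lk, lt)``.
    """
    r = np.asarray(response, dtype=float)
    ixx = ndimage.correlate1d(r, _D2, axis=1, mode="reflect")
    iyy = ndimage.correlate1d(r, _D2, axis=0, mode="reflect")
    ix = ndimage.correlate1d(r, _D1, axis=1, mode="reflect")
    ixy = ndimage.correlate1d(ix, _D1, axis=0, mode="reflect")
    tr = ixx + iyy
    disc = np.sqrt((ixx - iyy) ** 2 + 4.0 * ixy * ixy)
    lk = 0.5 * (np.abs(tr) + disc)  # max(|lambda1|, |lambda2|)
    lt = 2.0 / float(size) + float(curvature_sign) * 0.2 * lk
    return lk, np.clip(lt, 0.0, None)


def gate_candidates(candidates: list[EdgeCandidate], kt_field: np.ndarray,
                    lt_field: np.ndarray) -> list[EdgeCandidate]:
    """Accept candidates with ``k >= kt`` and ``|l| <= lt`` (closed bounds).

    Candidates flagged as step-model violations stay rejected. Rejected
    candidates are retained with ``accepted=False`` for diagnostics.
    """
    for c in candidates:
        c.kt = float(kt_field[c.row, c.col])
        c.lt = float(lt_field[c.row, c.col])
        c.accepted = bool(c.model_ok and c.k >= c.kt and abs(c.l) <= c.lt)
    return candidates
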