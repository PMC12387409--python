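"""Coarse-to-fine sub-pixel edge detection pipeline.

Stages: (1) multi-scale, multi-position enhanced Mexican Hat accumulation,
std-weighted fusion and DoG sharpening; coarse candidate pixels from
Otsu-binarized, thinned response; (2) Zernike moments on a 9x9 template at
every candidate; (3) adaptive gray (kt) and distance (lt) thresholds;
(4) sub-pixel mapping of accepted candidates. Deterministic for fixed
input and configuration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .kernels import DoGParams, WaveletParams, make_dog_kernel, make_enhanced_kernel
from .multiscale import (
    accumulate_shifted_responses,
    enhance_with_dog,
    extract_coarse_edges,
    fuse_scales,
)
from .thresholds import distance_threshold_field, gate_candidates, gray_threshold_field
from .zernike import (
    EdgeCandidate,
    build_masks,
    edge_parameters,
    moment_fields,
    subpixel_coordinates,
)

__all__ = ["EdgePointSet", "detect_subpixel_edges", "to_unit_gray"]

logger = logging.getLogger(__name__)

_CSV_COLUMNS = ["xs", "ys", "k", "l", "theta", "row", "col"]


@dataclass
class EdgePointSet:
    """Accepted sub-pixel edge points plus diagnostics.

    ``xs``/``ys`` are column/row coordinates (0-based pixel centers).
    ``candidates`` retains every coarse candidate, including rejected
    ones, for inspection.
    """

    xs: np.ndarray
    ys: np.ndarray
    k: np.ndarray
    l: np.ndarray
    theta: np.ndarray
    row: np.ndarray
    col: np.ndarray
    image_shape: tuple[int, int]
    provenance: str = ""
    candidates: list[EdgeCandidate] = field(default_factory=list, repr=False)
    intermediates: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.xs)

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of (xs, ys)."""
        return np.column_stack([self.xs, self.ys])

    def to_dataframe(self, one_based: bool = False) -> pd.DataFrame:
        off = 1 if one_based else 0
        return pd.DataFrame({
            "xs": self.xs + off, "ys": self.ys + off,
            "k": self.k, "l": self.l, "theta": self.theta,
            "row": self.row + off, "col": self.col + off,
        })[_CSV_COLUMNS]

    def to_csv(self, path, one_based: bool = False) -> None:
        self.to_dataframe(one_based).to_csv(path, index=False,
                                            float_format="%.6f")


def to_unit_gray(image: np.ndarray) -> np.ndarray:
    """Convert an input image to a float gray field on [0, 1].

    Integer dtypes are rescaled by their dtype maximum (so intensities keep
    absolute meaning); color images are reduced by the Rec. 601 luminance
    with a logged notice.
    """
    arr = np.asarray(image)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[..., :3]
        if arr.shape[2] != 3:
            raise ValueError(f"cannot interpret image of shape {arr.shape}")
        logger.info("color input converted to grayscale by luminance")
        arr = (0.299 * arr[..., 0] + 0.587 * arr[..., 1]
               + 0.114 * arr[..., 2])
    elif arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        return arr.astype(float) / float(np.iinfo(np.asarray(image).dtype).max)
    out = arr.astype(float)
    if not np.all(np.isfinite(out)):
        raise ValueError("image contains non-finite values")
    return out


def _minmax_norm(f: np.ndarray) -> np.ndarray:
    lo, hi = float(f.min()), float(f.max())
    if hi == lo:
        return np.zeros_like(f)
    return (f - lo) / (hi - lo)


def _empty_result(shape, cfg: PipelineConfig, candidates=None,
                  intermediates=None) -> EdgePointSet:
    e = np.empty(0)
    return EdgePointSet(xs=e, ys=e.copy(), k=e.copy(), l=e.copy(),
                        theta=e.copy(), row=np.empty(0, int),
                        col=np.empty(0, int), image_shape=shape,
                        provenance=_provenance(cfg),
                        candidates=candidates or [],
                        intermediates=intermediates or {})


def _provenance(cfg: PipelineConfig) -> str:
    return f"placido-edge {__version__} cfg:{cfg.digest()}"


def detect_subpixel_edges(image: np.ndarray,
                          config: PipelineConfig | None = None,
                          *, keep_intermediates: bool = False
                          ) -> EdgePointSet:
    """Run the full coarse-to-fine detector on a grayscale image.

    Returns every accepted sub-pixel edge point; rejected candidates are
    kept on the result for diagnostics. An empty candidate set yields an
    empty result with a warning.
    """
    cfg = config or PipelineConfig()
    img = to_unit_gray(image)

    # stage 1: multi-scale multi-position front-end
    responses = []
    for sigma in cfg.scales:
        params = WaveletParams(sigma=sigma,
                               target_radius=cfg.radius_factor * sigma,
                               radial_bandwidth=cfg.bandwidth_factor * sigma,
                               truncation_factor=cfg.truncation_factor,
                               radial_term=cfg.radial_term)
        kern = make_enhanced_kernel(params)
        responses.append(accumulate_shifted_responses(
            img, kern, cfg.step, centered=cfg.centered_shifts, sigma=sigma))
    try:
        fused = fuse_scales(responses)
    except ValueError:
        # constant image: no structure at any scale
        warnings.warn("input has no structured response; empty result",
                      stacklevel=2)
        return _empty_result(img.shape, cfg)
    dog = make_dog_kernel(DoGParams(cfg.dog_sigma1, cfg.dog_sigma2))
    ef = enhance_with_dog(fused.total, dog)
    fused.enhanced = ef
    coarse = extract_coarse_edges(ef, min_component=cfg.min_component)

    intermediates = {}
    if keep_intermediates:
        intermediates = {
            **{f"S_sigma{r.sigma:g}": r.response for r in responses},
            "E": fused.total, "Ef": ef, "mask": coarse.mask,
            "weights": fused.weights,
        }

    rows, cols = np.nonzero(coarse.mask)
    if rows.size == 0:
        warnings.warn("no coarse edge candidates found; empty result",
                      stacklevel=2)
        return _empty_result(img.shape, cfg, intermediates=intermediates)

    # stage 2: Zernike moments at candidate pixels
    source = img if cfg.moment_source == "image" else _minmax_norm(ef)
    masks = build_masks(cfg.template_size, cfg.mask_subsampling)
    z00f, z11f, z20f = moment_fields(source, masks)
    z00 = z00f[rows, cols]
    z11 = z11f[rows, cols]
    z20 = z20f[rows, cols]
    l, k, h, theta = edge_parameters(z00, z11, z20)
    # |l| beyond the unit disc before clamping violates the step model
    a11 = np.abs(z11) * (np.pi / 2.0)
    model_ok = (a11 > 1e-12) & (np.abs(z20 * (np.pi / 3.0)) <= a11)

    # stage 3: adaptive thresholds
    tf = gray_threshold_field(z11f, z20f)
    ef_norm = _minmax_norm(ef)
    lk, lt = distance_threshold_field(ef_norm, cfg.template_size,
                                      cfg.curvature_sign)
    if keep_intermediates:
        intermediates.update(kt=tf.kt, lt=lt, lk=lk)

    candidates = [
        EdgeCandidate(row=int(r), col=int(c), z00=float(a), z11=complex(b),
                      z20=float(d), z11p=float(abs(b)), l=float(li),
                      k=float(ki), h=float(hi), theta=float(ti),
                      model_ok=bool(mo))
        for r, c, a, b, d, li, ki, hi, ti, mo
        in zip(rows, cols, z00, z11, z20, l, k, h, theta, model_ok)
    ]
    gate_candidates(candidates, tf.kt, lt)

    # stage 4: sub-pixel mapping of accepted candidates
    acc = [c for c in candidates if c.accepted]
    for c in acc:
        c.xs, c.ys = subpixel_coordinates(c.row, c.col, c.l, c.theta,
                                          cfg.template_size)
    logger.info("detected %d accepted / %d candidate edge points",
                len(acc), len(candidates))
    if not acc:
        warnings.warn("all candidates rejected by the adaptive thresholds",
                      stacklevel=2)
        return _empty_result(img.shape, cfg, candidates, intermediates)

    return EdgePointSet(
        xs=np.array([c.xs for c in acc]),
        ys=np.array([c.ys for c in acc]),
        k=np.array([c.k for c in acc]),
        l=np.array([c.l for c in acc]),
        theta=np.array([c.theta for c in acc]),
        row=np.array([c.row for c in acc], dtype=int),
        col=np.array([c.col for c in acc], dtype=int),
        image_shape=img.shape,
        provenance=_provenance(cfg),
        candidates=candidates,
        intermediates=intermediates,
    )
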