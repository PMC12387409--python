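"""Synthetic fixtures: binary circle, noisy variant, ring phantom, step windows.

Every generator is a pure function of its spec and seed, so repeated calls
are byte-identical. The binary circle (400x400, white disc centered at
(200, 200), radius 150) is the standard accuracy benchmark; the Placido
phantom emulates a ring target with eyelash-like dark occluders entering
from the top edge and small bright specular spots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.draw import line
from skimage.morphology import disk

__all__ = [
    "CircleSpec",
    "PhantomSpec",
    "make_binary_circle",
    "add_gaussian_noise",
    "make_placido_phantom",
    "make_step_window",
]


@dataclass(frozen=True)
class CircleSpec:
    """White disc on black background; center in (x=col, y=row) pixels."""

    width: int = 400
    height: int = 400
    center: tuple[float, float] = (200.0, 200.0)
    radius: float = 150.0

    def __post_init__(self) -> None:
        cx, cy = self.center
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if (cx - self.radius < 0 or cx + self.radius > self.width - 1
                or cy - self.radius < 0 or cy + self.radius > self.height - 1):
            raise ValueError("circle must lie fully inside the frame")


@dataclass(frozen=True)
class PhantomSpec:
    """Concentric-ring phantom with seeded eyelash/spot interference."""

    width: int = 400
    height: int = 400
    center: tuple[float, float] | None = None  # default: frame center
    ring_radii: tuple[float, ...] = tuple(float(r) for r in range(15, 180, 15))
    ring_width: float = 4.0
    n_eyelashes: int = 6
    n_spots: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        radii = tuple(self.ring_radii)
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("ring radii must be strictly increasing")
        if self.ring_width <= 0:
            raise ValueError("ring_width must be positive")

    @property
    def cx_cy(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return ((self.width - 1) / 2.0, (self.height - 1) / 2.0)


def make_binary_circle(spec: CircleSpec | None = None,
                       supersample: int = 8) -> np.ndarray:
    """White disc on black background.

    With the default ``supersample=8`` each pixel carries the fraction of
    its area covered by the disc, i.e. the disc is rendered the way raster
    graphics libraries draw filled circles: interior pixels are exactly 1,
    exterior pixels exactly 0, and only the one-pixel boundary ring takes
    intermediate values. This area-sampled rendering is the reference
    benchmark condition — sub-pixel localization statistics at the
    0.1-pixel level are only meaningful when the boundary is not aliased
    (a hard center-sampled rasterization perturbs the boundary by up to
    half a pixel, which no local estimator can undo).

    ``supersample=1`` gives the hard rasterization: intensity 1 exactly
    where the pixel center satisfies ``(x-cx)^2 + (y-cy)^2 <= radius^2``.
    """
    spec = spec or CircleSpec()
    ss = int(supersample)
    if ss < 1:
        raise ValueError("supersample must be >= 1")
    cx, cy = spec.center
    yy, xx = np.mgrid[0:spec.height, 0:spec.width]
    if ss == 1:
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= spec.radius ** 2
        return inside.astype(float)
    sub = (np.arange(ss) + 0.5) / ss - 0.5
    out = np.zeros((spec.height, spec.width))
    # only boundary-adjacent pixels need subsampling
    r = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    out[r <= spec.radius - 1.0] = 1.0
    band = np.abs(r - spec.radius) < 1.0
    by, bx = np.nonzero(band)
    frac = np.zeros(len(by))
    for dy in sub:
        for dx in sub:
            frac += ((bx + dx - cx) ** 2 + (by + dy - cy) ** 2
                     <= spec.radius ** 2)
    out[by, bx] = frac / (ss * ss)
    return out


def add_gaussian_noise(image: np.ndarray, sd: float,
                       seed: int | None = None,
                       clip: bool = True) -> np.ndarray:
    """Add i.i.d. N(0, sd^2) per pixel; clipped to [0, 1] by default."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    img = np.asarray(image, dtype=float)
    if sd == 0:
        return img.copy()
    rng = np.random.default_rng(seed)
    out = img + rng.normal(0.0, sd, size=img.shape)
    return np.clip(out, 0.0, 1.0) if clip else out


def make_placido_phantom(spec: PhantomSpec | None = None
                         ) -> tuple[np.ndarray, dict]:
    """Ring phantom plus ground truth (center, radii, occluder mask).

    Rings have smooth Gaussian cross-sections peaking exactly at the
    specified radii; with no occluders or spots the image is exactly
    radially symmetric about the frame center.
    """
    spec = spec or PhantomSpec()
    cx, cy = spec.cx_cy
    yy, xx = np.mgrid[0:spec.height, 0:spec.width]
    r = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    img = np.zeros((spec.height, spec.width))
    prof_sd = spec.ring_width / 2.0
    for radius in spec.ring_radii:
        img += 0.9 * np.exp(-((r - radius) ** 2) / (2.0 * prof_sd ** 2))
    img = np.clip(img, 0.0, 1.0)

    rng = np.random.default_rng(spec.seed)
    occluder = np.zeros(img.shape, dtype=bool)
    for _ in range(spec.n_eyelashes):
        x = float(rng.uniform(cx - 0.6 * spec.width / 2, cx + 0.6 * spec.width / 2))
        y = 0.0
        pts = [(int(round(y)), int(round(x)))]
        depth = rng.uniform(0.45, 0.75) * spec.height
        drift = rng.uniform(-0.5, 0.5)
        while y < depth:
            y += rng.uniform(8, 16)
            x += drift * rng.uniform(4, 10) + rng.normal(0, 2.0)
            pts.append((int(round(y)), int(round(x))))
        lash = np.zeros(img.shape, dtype=bool)
        for (r0, c0), (r1, c1) in zip(pts, pts[1:]):
            rr, cc = line(r0, c0, r1, c1)
            ok = (rr >= 0) & (rr < spec.height) & (cc >= 0) & (cc < spec.width)
            lash[rr[ok], cc[ok]] = True
        lash = binary_dilation(lash, structure=disk(1))
        occluder |= lash
    img[occluder] *= 0.1

    spot_centers = []
    for _ in range(spec.n_spots):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, 0.85 * max(spec.ring_radii))
        sx, sy = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
        spot_sd = rng.uniform(1.5, 3.0)
        img += 0.8 * np.exp(-((xx - sx) ** 2 + (yy - sy) ** 2)
                            / (2.0 * spot_sd ** 2))
        spot_centers.append((float(sx), float(sy)))
    img = np.clip(img, 0.0, 1.0)

    edge_radii = sorted(
        [r - spec.ring_width / 2.0 for r in spec.ring_radii]
        + [r + spec.ring_width / 2.0 for r in spec.ring_radii])
    truth = {
        "center": (float(cx), float(cy)),
        "ring_radii": [float(x) for x in spec.ring_radii],
        # half-maximum edge radii of each ring — what an edge detector
        # should localize on a bar-profile ring
        "ring_edge_radii": [float(x) for x in edge_radii],
        "occluder_mask": occluder,
        # influence zone: a detector reacting to a lash localizes its
        # *edges*, which flank the occluder mask
        "occluder_zone": binary_dilation(occluder, structure=disk(3)),
        "spot_centers": spot_centers,
    }
    return img, truth


def make_step_window(size: int, l: float, theta: float, h: float, k: float,
                     supersample: int = 8) -> np.ndarray:
    """Area-sampled ideal step edge on an N x N pixel window.

    The edge line sits at signed distance ``l * size/2`` pixels from the
    window center with normal ``(cos(theta), sin(theta))`` in (col, row)
    coordinates; intensity is ``h`` behind the line and ``h + k`` on the
    normal side. Each pixel averages ``supersample**2`` midpoint samples
    of the continuous model.
    """
    if not abs(l) < 1:
        raise ValueError(f"need |l| < 1, got {l}")
    size = int(size)
    ss = int(supersample)
    centers = np.arange(size) - (size - 1) / 2.0
    sub = (np.arange(ss) + 0.5) / ss - 0.5
    # all sample coordinates: axis layout (pixel, subsample)
    coords = centers[:, None] + sub[None, :]
    x = coords.reshape(-1)  # length size*ss
    y = coords.reshape(-1)
    xx = x[None, :]
    yy = y[:, None]
    s = xx * np.cos(theta) + yy * np.sin(theta) - l * (size / 2.0)
    vals = h + k * (s > 0)
    # average subsample blocks back down to pixels
    vals = vals.reshape(size, ss, size, ss).mean(axis=(1, 3))
    return vals
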