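"""Tooth-area ROI delineation on the reference projection.

The projection is smoothed with a large 2-D median (``h3``), then a greedy
active contour shrinks/grows a polygon initialized as a frame-inset
rectangle. Vertices live on fixed rays from the image centre; per sweep each
vertex may move up to ``search_range`` pixels along its ray and a move is
accepted when it increases the contrast between the two square averaging
patches straddling the vertex (bright tooth inside, dark background
outside). The algorithm stops when a full sweep moves no vertex, or at
``max_iters``. The final polygon is rasterized to a binary mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from . import defaults
from .errors import DimensionError, EmptyMaskError
from .registration import ProjectionImage
from .thickness import ThicknessMap

__all__ = ["ROIMask", "ContourParams", "smooth_for_roi", "active_contour_roi", "apply_roi"]

log = logging.getLogger(__name__)


@dataclass
class ContourParams:
    search_range: int = defaults.CONTOUR_SEARCH_RANGE_PX
    patch: int = defaults.CONTOUR_PATCH_PX
    max_iters: int = defaults.CONTOUR_MAX_ITERS
    init_margin: int = defaults.CONTOUR_INIT_MARGIN_PX
    n_vertices: int = defaults.CONTOUR_VERTICES

    def __post_init__(self):
        for name in ("search_range", "patch", "max_iters", "init_margin", "n_vertices"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ROIMask:
    """Binary tooth-area mask on the (n, i) plane."""

    mask: np.ndarray
    n_iterations: int = 0
    energy_history: list = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise EmptyMaskError("ROI mask is empty")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def smooth_for_roi(proj: ProjectionImage,
                   h3: tuple[int, int] = defaults.H3) -> ProjectionImage:
    """2-D median filter of the projection, edge-replicated borders."""
    if any(s < k for s, k in zip(proj.values.shape, h3)):
        raise DimensionError(
            f"projection {proj.values.shape} smaller than median mask {h3}")
    return ProjectionImage(ndimage.median_filter(proj.values, size=h3, mode="nearest"))


def _ray_limits(center: np.ndarray, unit: np.ndarray, shape, margin: float) -> float:
    """Distance from centre to the margin-inset frame along a ray direction."""
    t_max = np.inf
    for ax in range(2):
        if unit[ax] > 1e-12:
            t_max = min(t_max, (shape[ax] - 1 - margin - center[ax]) / unit[ax])
        elif unit[ax] < -1e-12:
            t_max = min(t_max, (margin - center[ax]) / unit[ax])
    return t_max


def active_contour_roi(smooth: ProjectionImage,
                       params: ContourParams | None = None) -> ROIMask:
    """Greedy patch-contrast snake delineating the tooth footprint.

    Raises :class:`EmptyMaskError` for a flat (objectless) image.
    """
    from skimage.draw import polygon2mask

    params = params or ContourParams()
    img = smooth.values
    if np.ptp(img) < 1e-9:
        raise EmptyMaskError("flat projection: no object to outline")
    shape = img.shape
    patch_mean = ndimage.uniform_filter(img, size=params.patch, mode="nearest")
    center = np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])
    angles = np.linspace(0.0, 2.0 * np.pi, params.n_vertices, endpoint=False)
    units = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    r_max = np.array([_ray_limits(center, u, shape, params.init_margin) for u in units])
    radii = r_max.copy()  # frame-inset rectangle "standard"
    offset = params.patch // 2 + 1

    def sample(points):
        p = np.rint(points).astype(int)
        p[:, 0] = np.clip(p[:, 0], 0, shape[0] - 1)
        p[:, 1] = np.clip(p[:, 1], 0, shape[1] - 1)
        return patch_mean[p[:, 0], p[:, 1]]

    def scores(r):
        inner = center[None] + (r - offset)[:, None] * units
        outer = center[None] + (r + offset)[:, None] * units
        return sample(inner) - sample(outer)

    energy_history = []
    iterations = 0
    r_lo = float(offset + 1)
    for iterations in range(1, params.max_iters + 1):
        moved = False
        current = scores(radii)
        for k in range(len(radii)):
            cand = np.arange(r_lo, r_max[k] + 1.0)
            if cand.size == 0:
                continue
            inner = center[None] + (cand - offset)[:, None] * units[k][None]
            outer = center[None] + (cand + offset)[:, None] * units[k][None]
            s = sample(inner) - sample(outer)
            # best contrast along the ray; ties resolved outward so the
            # contour hugs the object from outside
            best = cand.size - 1 - int(np.argmax(s[::-1]))
            if s[best] > current[k] + 1e-12:
                step = np.clip(cand[best] - radii[k], -params.search_range,
                               params.search_range)
                if step != 0:
                    radii[k] = radii[k] + step
                    current[k] = scores(radii)[k]
                    moved = True
        energy_history.append(float(current.sum()))
        if not moved:
            break
    polygon = center[None] + radii[:, None] * units
    mask = polygon2mask(shape, polygon)
    if not mask.any():
        raise EmptyMaskError("active contour collapsed to an empty region")
    return ROIMask(mask, n_iterations=iterations, energy_history=energy_history)


def apply_roi(maps: list[ThicknessMap], roi: ROIMask) -> list[ThicknessMap]:
    """Blank every thickness value outside the ROI (set undefined)."""
    out = []
    for tmap in maps:
        if tmap.values.shape != roi.mask.shape:
            raise DimensionError(
                f"map {tmap.values.shape} does not match ROI {roi.mask.shape}")
        out.append(replace(tmap, values=np.where(roi.mask, tmap.values, np.nan)))
    return out


def save_mask_csv(roi: ROIMask, path) -> None:
    np.savetxt(path, roi.mask.astype(int), delimiter=",", fmt="%d")
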