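"""Inter-stage C-scan registration by exhaustive shift + zoom search.

The en-face projection of a stage is the depth sum of each A-scan, min-max
normalized to [0, 1]. A candidate transform (dn, di, dz) rescales the moving
projection back to 100 % (centre-anchored nearest neighbour), samples it at
(n + dn, i + di) with zero fill, and scores the mean absolute difference J
against the reference over the full N x I grid. The search is exhaustive:
every integer shift in [-shift_range, shift_range] on both axes, crossed
with the configured zoom percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import defaults
from ._grid import warp_to_reference, zoom_about_center
from .errors import DimensionError, ParameterError
from .thickness import ThicknessMap
from .volume import OCTVolume

__all__ = ["ProjectionImage", "RegistrationResult", "normalized_projection",
           "match_criterion", "register", "apply_transform", "identity_result"]

log = logging.getLogger(__name__)


@dataclass
class ProjectionImage:
    """Normalized en-face projection over (n, i), values in [0, 1]."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DimensionError("projection must be 2-D over (n, i)")
        if not np.isfinite(self.values).all():
            raise ParameterError("projection contains non-finite values")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ParameterError("projection values must lie in [0, 1]")


@dataclass
class RegistrationResult:
    """Optimal transform aligning a moving stage to the reference.

    ``J_surface`` holds the criterion over the whole searched grid, indexed
    (zoom, dn + shift_range, di + shift_range).
    """

    dn: int
    di: int
    dz: float
    J: float
    J_surface: np.ndarray | None = None
    shift_range: int = defaults.SHIFT_RANGE_PX
    zoom_percents: tuple = defaults.ZOOM_PERCENTS


def identity_result() -> RegistrationResult:
    return RegistrationResult(dn=0, di=0, dz=0.0, J=0.0, J_surface=None)


def normalized_projection(volume: OCTVolume) -> ProjectionImage:
    """Depth-sum each A-scan and min-max normalize to [0, 1].

    A constant projection (degenerate denominator) returns all zeros with a
    warning instead of dividing by zero.
    """
    sums = volume.data.sum(axis=0, dtype=np.float64)
    lo, hi = sums.min(), sums.max()
    if hi == lo:
        log.warning("constant projection image; returning all zeros")
        return ProjectionImage(np.zeros_like(sums))
    return ProjectionImage((sums - lo) / (hi - lo))


def match_criterion(ref: ProjectionImage, moving: ProjectionImage,
                    dn: int, di: int, dz: float,
                    shift_range: int = defaults.SHIFT_RANGE_PX) -> float:
    """Mean absolute difference J for one candidate transform.

    Out-of-range samples of the moving image contribute |ref - 0| (zero
    fill); the denominator is always the full grid size I*N.
    """
    if ref.values.shape != moving.values.shape:
        raise DimensionError("reference and moving projections differ in shape")
    if abs(dn) > shift_range or abs(di) > shift_range:
        raise ParameterError(f"|dn|, |di| must not exceed {shift_range}")
    warped = warp_to_reference(moving.values, dn, di, dz, fill=0.0)
    return float(np.abs(ref.values - warped).mean())


def register(ref: ProjectionImage, moving: ProjectionImage,
             *,
             shift_range: int = defaults.SHIFT_RANGE_PX,
             zoom_percents: tuple = defaults.ZOOM_PERCENTS,
             keep_surface: bool = True) -> RegistrationResult:
    """Exhaustive search for the transform minimizing J.

    Shifts step every pixel over [-shift_range, shift_range] on both axes for
    each zoom level. Exact ties are broken by the smallest Euclidean norm of
    (dn, di, dz) and then lexicographically.
    """
    if ref.values.shape != moving.values.shape:
        raise DimensionError("reference and moving projections differ in shape")
    n_cols, n_scans = ref.values.shape
    span = 2 * shift_range + 1
    surface = np.empty((len(zoom_percents), span, span))
    refv = ref.values.astype(np.float32)
    buf = np.empty_like(refv)
    grid_size = float(n_cols * n_scans)
    for zi, dz in enumerate(zoom_percents):
        z = 1.0 + dz / 100.0
        m = zoom_about_center(moving.values, 1.0 / z, fill=0.0) if dz else moving.values
        padded = np.pad(m.astype(np.float32), shift_range, mode="constant")
        for a in range(span):
            block = np.ascontiguousarray(padded[a:a + n_cols])
            for b in range(span):
                np.subtract(refv, block[:, b:b + n_scans], out=buf)
                np.abs(buf, out=buf)
                surface[zi, a, b] = float(buf.sum(dtype=np.float64)) / grid_size
    j_min = surface.min()
    cand = np.argwhere(surface == j_min)
    def tie_key(c):
        zi, a, b = c
        dn, di, dz = a - shift_range, b - shift_range, zoom_percents[zi]
        return (dn * dn + di * di + dz * dz, dn, di, dz)
    zi, a, b = min(map(tuple, cand), key=tie_key)
    if len(cand) > 1:
        log.warning("registration: %d exact ties at J = %g", len(cand), j_min)
    return RegistrationResult(dn=int(a - shift_range), di=int(b - shift_range),
                              dz=float(zoom_percents[zi]), J=float(j_min),
                              J_surface=surface if keep_surface else None,
                              shift_range=shift_range, zoom_percents=tuple(zoom_percents))


def apply_transform(tmap: ThicknessMap, result: RegistrationResult) -> ThicknessMap:
    """Resample a stage's thickness map onto the reference grid.

    Uses the same sampling as the criterion; cells drawn from outside the
    stage grid become undefined (NaN), and undefined cells propagate.
    """
    if (result.dn, result.di, result.dz) == (0, 0, 0.0):
        return replace(tmap, values=tmap.values.copy())
    values = warp_to_reference(tmap.values, result.dn, result.di, result.dz, fill=np.nan)
    return replace(tmap, values=values)


def save_surface_csv(result: RegistrationResult, path) -> None:
    """Dump the J surface as CSV blocks, one per zoom level."""
    import pandas as pd

    if result.J_surface is None:
        raise ValueError("registration result carries no J surface")
    frames = []
    for zi, dz in enumerate(result.zoom_percents):
        df = pd.DataFrame(result.J_surface[zi])
        df.insert(0, "dz", dz)
        df.insert(1, "dn", np.arange(-result.shift_range, result.shift_range + 1))
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
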