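"""Shared grid resampling primitives: integer shifts and centre-anchored
nearest-neighbour zoom with zero/constant fill.

A planted stage transform is ``plant_transform`` (shift content by +dn/+di,
then zoom about the grid centre); ``warp_to_reference`` applies the inverse
sampling used by the registration criterion, so a planted transform is
recovered by the same code path that evaluates candidate transforms.
"""

from __future__ import annotations

import numpy as np

__all__ = ["shift_sample", "zoom_about_center", "warp_to_reference", "plant_transform"]


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


def _shift_map(size: int, d: int):
    src = np.arange(size) + int(d)
    valid = (src >= 0) & (src < size)
    return src, valid


def _zoom_map(size: int, factor: float):
    # Centre-anchored: out[r] = in[round((r - c)/factor + c)]; factor > 1 enlarges.
    c = (size - 1) / 2.0
    src = _round_half_up((np.arange(size) - c) / factor + c)
    valid = (src >= 0) & (src < size)
    return src, valid


def _remap(a: np.ndarray, maps, axes, fill):
    """Gather ``a`` through per-axis (src, valid) index maps; fill elsewhere."""
    if isinstance(fill, float) and np.isnan(fill) and not np.issubdtype(a.dtype, np.floating):
        a = a.astype(np.float64)
    out = np.full(a.shape, fill, dtype=a.dtype)
    idx_out, idx_src = [], []
    for ax in range(a.ndim):
        if ax in axes:
            src, valid = maps[axes.index(ax)]
            idx_out.append(np.where(valid)[0])
            idx_src.append(src[valid])
        else:
            r = np.arange(a.shape[ax])
            idx_out.append(r)
            idx_src.append(r)
    out[np.ix_(*idx_out)] = a[np.ix_(*idx_src)]
    return out


def shift_sample(a: np.ndarray, dn: int, di: int, *, axes=(0, 1), fill=0.0) -> np.ndarray:
    """Sample ``a`` at (n + dn, i + di); out-of-range cells take ``fill``."""
    maps = [_shift_map(a.shape[axes[0]], dn), _shift_map(a.shape[axes[1]], di)]
    return _remap(a, maps, axes, fill)


def zoom_about_center(a: np.ndarray, factor: float, *, axes=(0, 1), fill=0.0) -> np.ndarray:
    """Nearest-neighbour rescale about the grid centre, same output shape.

    ``factor`` > 1 enlarges the content; rows/columns falling outside the
    source take ``fill`` (zero-fill), extra content is cropped.
    """
    if factor <= 0:
        raise ValueError(f"zoom factor must be positive, got {factor}")
    if factor == 1.0:
        return a.copy()
    maps = [_zoom_map(a.shape[axes[0]], factor), _zoom_map(a.shape[axes[1]], factor)]
    return _remap(a, maps, axes, fill)


def warp_to_reference(a: np.ndarray, dn: int, di: int, dz: float, *, axes=(0, 1), fill=0.0) -> np.ndarray:
    """Bring a moved/zoomed image back onto the reference grid.

    First rescales to 100 % (undo a zoom of ``dz`` percent), then samples at
    (n + dn, i + di). This is the sampling the match criterion applies to the
    moving image, and the inverse of :func:`plant_transform`.
    """
    z = 1.0 + dz / 100.0
    b = zoom_about_center(a, 1.0 / z, axes=axes, fill=fill) if dz else a
    return shift_sample(b, dn, di, axes=axes, fill=fill)


def plant_transform(a: np.ndarray, dn: int, di: int, dz: float, *, axes=(0, 1), fill=0.0) -> np.ndarray:
    """Displace content by (+dn, +di) and zoom it by ``dz`` percent."""
    b = shift_sample(a, -dn, -di, axes=axes, fill=fill)
    z = 1.0 + dz / 100.0
    return zoom_about_center(b, z, axes=axes, fill=fill) if dz else b
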