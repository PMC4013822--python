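"""Enamel boundary segmentation on OCT B-scan volumes.

The chain, applied to a raw volume:

1. 3-D median pre-filter (mask ``h1``).
2. Global Otsu threshold ``p_r``; the outer object boundary ``L_ef(n, i)`` is
   the first row brighter than ``p_r`` in each A-scan.
3. Per-column thresholds from the sub-surface segment of the A-scan:
   ``p_r2`` is the modal brightness, ``p_r3`` the mean of the trailing
   constant-brightness plateau plus one standard deviation. The plateau is
   located by a minimal two-segment residual-sum-of-squares change point.
4. Binarization above the per-column threshold, 3-D median (``h2``),
   morphological closing (``SE``), hole filling, and per-B-scan selection of
   the largest 8-connected component.
5. The raw inner boundary ``L_inr(n)`` is the deepest component row per
   column; columns whose two threshold candidates disagree by more than
   ``limit_shift_px`` rows are replaced by the median of their neighbours;
   a degree-3 polynomial fit yields the smoothed boundary ``L_in(n)``.
6. The outer enamel boundary ``L_en(n)`` is ``L_ef(n)`` restricted to the
   column span of the component.

Undefined boundary cells are encoded as NaN throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import defaults
from .errors import DimensionError, NoObjectError, ParameterError
from .volume import OCTVolume

__all__ = [
    "ThresholdSet",
    "BoundarySet",
    "median_filter_3d",
    "otsu_threshold",
    "detect_upper_boundary",
    "column_histogram",
    "inner_threshold",
    "binarize_enamel",
    "refine_binary",
    "extract_inner_boundary",
    "extract_outer_boundary",
    "segment_enamel",
]

log = logging.getLogger(__name__)


@dataclass
class ThresholdSet:
    """Thresholds driving the segmentation.

    ``p_r`` is the global Otsu surface threshold; ``p_r2``/``p_r3`` are
    per-(n, i) inner-boundary threshold candidates (NaN where the column has
    no surface). ``p_r3 >= p_r2`` holds whenever the modal brightness of the
    sub-surface segment is the plateau level, which is the typical case; it
    is not enforced because clamping would corrupt columns whose histogram
    mode falls in the bright band.
    """

    p_r: float
    p_r2: np.ndarray
    p_r3: np.ndarray


@dataclass
class BoundarySet:
    """Per-(n, i) boundary rows; NaN marks undefined columns."""

    L_ef: np.ndarray
    L_en: np.ndarray
    L_inr: np.ndarray
    L_in: np.ndarray
    poly_coeffs: list = field(default_factory=list)  # per B-scan, (4,) array or None
    thresholds: ThresholdSet | None = None
    no_object_scans: list = field(default_factory=list)
    ambiguous_columns: np.ndarray | None = None

    def to_csv(self, path) -> None:
        import pandas as pd

        n_cols, n_scans = self.L_ef.shape
        nn, ii = np.meshgrid(np.arange(n_cols), np.arange(n_scans), indexing="ij")
        pd.DataFrame({
            "i": ii.ravel(), "n": nn.ravel(),
            "L_ef": self.L_ef.ravel(), "L_en": self.L_en.ravel(),
            "L_inr": self.L_inr.ravel(), "L_in": self.L_in.ravel(),
        }).to_csv(path, index=False)


def median_filter_3d(volume: OCTVolume, mask_shape: tuple[int, int, int] = defaults.H1) -> OCTVolume:
    """3-D median filter with edge replication at the borders."""
    if any(s < k for s, k in zip(volume.shape, mask_shape)):
        raise DimensionError(
            f"volume shape {volume.shape} smaller than median mask {mask_shape}")
    return volume.with_data(ndimage.median_filter(volume.data, size=mask_shape, mode="nearest"))


def otsu_threshold(data: np.ndarray) -> int:
    """Otsu's threshold: maximize between-class variance over all 256 cuts.

    The object class is ``value > t``. Exactly tied maximizers (adjacent cuts
    separating the same two pixel populations) are resolved to the middle of
    the maximizing plateau, so a two-level image thresholds strictly between
    its levels.
    """
    hist = np.bincount(np.asarray(data, dtype=np.uint8).ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    w0 = np.cumsum(hist)
    mu = np.cumsum(hist * np.arange(256))
    mu_total = mu[-1]
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu / w0
        mu1 = (mu_total - mu) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=-1.0)
    best = np.flatnonzero(sigma_b == sigma_b.max())
    return int(best[len(best) // 2])


def detect_upper_boundary(volume: OCTVolume) -> tuple[np.ndarray, int]:
    """First row per (n, i) brighter than the global Otsu threshold.

    Returns ``(L_ef, p_r)`` where ``L_ef`` is (N, I) float with NaN for
    columns that never exceed ``p_r``. Raises :class:`NoObjectError` if no
    pixel anywhere is above threshold.
    """
    p_r = otsu_threshold(volume.data)
    above = volume.data > p_r
    has_object = above.any(axis=0)
    if not has_object.any():
        raise NoObjectError("no pixel above the Otsu threshold anywhere in the volume")
    l_ef = np.argmax(above, axis=0).astype(float)
    l_ef[~has_object] = np.nan
    return l_ef, p_r


def column_histogram(volume: OCTVolume, n: int, i: int) -> np.ndarray:
    """Brightness histogram of one full A-scan; counts sum to M."""
    return np.bincount(volume.data[:, n, i], minlength=256)


def _subsurface_thresholds(data: np.ndarray, l_ef: np.ndarray,
                           chunk: int = 16384) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ``(p_r2, p_r3)`` for every column.

    Works on the sub-surface segment (rows ``L_ef(n, i)`` .. M-1). ``p_r2``
    is the histogram mode (smallest grey level on ties); the plateau for
    ``p_r3`` is the suffix after the split minimizing the two-segment RSS.
    Columns with undefined ``L_ef`` yield NaN.
    """
    m_rows = data.shape[0]
    flat = data.reshape(m_rows, -1)
    ef = l_ef.reshape(-1)
    n_k = flat.shape[1]
    p_r2 = np.full(n_k, np.nan)
    p_r3 = np.full(n_k, np.nan)
    rows = np.arange(m_rows)[:, None]
    for start in range(0, n_k, chunk):
        sl = slice(start, min(start + chunk, n_k))
        seg = flat[:, sl]
        ef_c = ef[sl]
        valid = np.isfinite(ef_c)
        if not valid.any():
            continue
        ef_i = np.where(valid, ef_c, m_rows).astype(np.int64)
        w = rows >= ef_i[None, :]

        # per-column histogram of the weighted segment
        k_local = seg.shape[1]
        code = (np.arange(k_local, dtype=np.int64)[None, :] << 8) | seg.astype(np.int64)
        counts = np.bincount(code[w], minlength=k_local * 256).reshape(k_local, 256)
        mode = counts.argmax(axis=1).astype(float)

        # two-segment RSS change point on the weighted column
        x = seg.astype(np.float64) * w
        cum1 = np.cumsum(x, axis=0)
        cum2 = np.cumsum(x * x, axis=0)
        cnt = np.cumsum(w, axis=0).astype(np.float64)
        tot1, tot2, totc = cum1[-1], cum2[-1], cnt[-1]
        n1 = cnt
        n2 = totc[None, :] - n1
        with np.errstate(divide="ignore", invalid="ignore"):
            rss1 = cum1 * 0.0
            np.divide(cum1 ** 2, n1, out=rss1, where=n1 > 0)
            rss1 = cum2 - rss1
            s2 = tot1[None, :] - cum1
            q2 = tot2[None, :] - cum2
            rss2 = np.zeros_like(rss1)
            np.divide(s2 ** 2, n2, out=rss2, where=n2 > 0)
            rss2 = q2 - rss2
        cost = rss1 + rss2
        cost[(n1 < 1) | (n2 < 1)] = np.inf
        splittable = np.isfinite(cost).any(axis=0)
        k_star = np.argmin(cost, axis=0)

        take = lambda a: np.take_along_axis(a, k_star[None, :], axis=0)[0]
        n2k = totc - take(cnt)
        s2k = tot1 - take(cum1)
        q2k = tot2 - take(cum2)
        with np.errstate(divide="ignore", invalid="ignore"):
            mean2 = s2k / n2k
            var2 = q2k / n2k - mean2 ** 2
        upper = mean2 + np.sqrt(np.clip(var2, 0.0, None))

        # unsplittable but non-empty segment (single row): plateau = that row
        single = valid & ~splittable & (totc >= 1)
        if single.any():
            upper[single] = (tot1[single] / totc[single])

        p_r2[sl][valid] = mode[valid]
        p_r3[sl][valid] = upper[valid]
    shape = l_ef.shape
    return p_r2.reshape(shape), p_r3.reshape(shape)


def inner_threshold(volume: OCTVolume, n: int, i: int, l_ef: np.ndarray) -> tuple[float, float]:
    """``(p_r2, p_r3)`` for a single column; NaN if ``L_ef`` is undefined there."""
    col = volume.data[:, n:n + 1, i:i + 1]
    p2, p3 = _subsurface_thresholds(col[:, :, 0], np.asarray([[l_ef[n, i]]]))
    return float(p2[0, 0]), float(p3[0, 0])


def binarize_enamel(volume: OCTVolume, thresholds: np.ndarray) -> np.ndarray:
    """Binary volume: intensity strictly above the per-(n, i) threshold.

    NaN thresholds (columns without a surface) binarize to all-zero.
    """
    thr = np.asarray(thresholds, dtype=float)
    if thr.shape != volume.shape[1:]:
        raise DimensionError(f"threshold grid {thr.shape} does not match volume {volume.shape[1:]}")
    with np.errstate(invalid="ignore"):
        return volume.data > thr[None, :, :]


def refine_binary(binary: np.ndarray,
                  h2: tuple[int, int, int] = defaults.H2,
                  se: tuple[int, int] = defaults.SE) -> tuple[np.ndarray, list[int]]:
    """Clean the binary volume and keep one component per B-scan.

    3-D median (``h2``), in-plane closing (``se``, sized for noise clusters
    of 2-3 pixels), hole filling and 8-connected labelling per B-scan; only
    the largest component of each scan survives. Returns the cleaned volume
    and the indices of B-scans left empty.
    """
    med = ndimage.median_filter(binary.astype(np.uint8), size=h2, mode="nearest")
    # closing written as min(max(.)) with edge replication, in-plane only
    closed = ndimage.grey_erosion(
        ndimage.grey_dilation(med, size=(*se, 1), mode="nearest"),
        size=(*se, 1), mode="nearest").astype(bool)
    out = np.zeros_like(closed)
    eight = np.ones((3, 3), dtype=bool)
    empty = []
    for i in range(closed.shape[2]):
        plane = ndimage.binary_fill_holes(closed[:, :, i])
        labels, n_lab = ndimage.label(plane, structure=eight)
        if n_lab == 0:
            empty.append(i)
            continue
        sizes = np.bincount(labels.ravel())[1:]
        out[:, :, i] = labels == (1 + int(np.argmax(sizes)))
    return out, empty


def extract_inner_boundary(clean_plane: np.ndarray,
                           poly_degree: int = defaults.POLY_DEGREE
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Raw and polynomial-smoothed inner boundary of one B-scan component.

    ``L_inr(n)`` is the deepest component row per column (NaN where the
    component is absent). ``L_in(n)`` evaluates the least-squares degree-3
    fit over the component's contiguous column span; with fewer than
    ``poly_degree + 1`` defined columns the fit falls back to the raw
    boundary and the coefficients are None.
    """
    m_rows, n_cols = clean_plane.shape
    has = clean_plane.any(axis=0)
    l_inr = np.full(n_cols, np.nan)
    l_inr[has] = (m_rows - 1 - np.argmax(clean_plane[::-1], axis=0))[has]
    l_in = np.full(n_cols, np.nan)
    coeffs = None
    defined = np.flatnonzero(has)
    if defined.size >= poly_degree + 1:
        coeffs = np.polyfit(defined.astype(float), l_inr[defined], poly_degree)
        span = np.arange(defined[0], defined[-1] + 1)
        l_in[span] = np.polyval(coeffs, span.astype(float))
    elif defined.size:
        warnings.warn("fewer than 4 defined columns; inner boundary left unsmoothed",
                      stacklevel=2)
        l_in[defined] = l_inr[defined]
    return l_inr, l_in, coeffs


def extract_outer_boundary(l_ef_col: np.ndarray, object_columns: np.ndarray) -> np.ndarray:
    """``L_en(n)``: the object's upper edge restricted to the enamel span.

    ``object_columns`` is the boolean column support of the B-scan's
    component; ``L_en`` equals ``L_ef`` on the contiguous span between the
    first and last object column and is NaN elsewhere.
    """
    l_en = np.full_like(np.asarray(l_ef_col, dtype=float), np.nan)
    idx = np.flatnonzero(object_columns)
    if idx.size:
        l_en[idx[0]:idx[-1] + 1] = l_ef_col[idx[0]:idx[-1] + 1]
    return l_en


def _last_row_above(data: np.ndarray, thresholds: np.ndarray, l_ef: np.ndarray) -> np.ndarray:
    """Deepest sub-surface row per (n, i) strictly above the threshold grid."""
    m_rows = data.shape[0]
    rows = np.arange(m_rows)[:, None, None]
    ef = np.where(np.isfinite(l_ef), l_ef, m_rows)
    with np.errstate(invalid="ignore"):
        above = (data > thresholds[None]) & (rows >= ef[None])
    any_above = above.any(axis=0)
    last = (m_rows - 1 - np.argmax(above[::-1], axis=0)).astype(float)
    last[~any_above] = np.nan
    return last


def segment_enamel(volume: OCTVolume,
                   *,
                   prefiltered: bool = False,
                   h1: tuple[int, int, int] = defaults.H1,
                   h2: tuple[int, int, int] = defaults.H2,
                   se: tuple[int, int] = defaults.SE,
                   limit_shift_px: int = defaults.LIMIT_SHIFT_PX,
                   neighbor_window: int = defaults.NEIGHBOR_WINDOW,
                   poly_degree: int = defaults.POLY_DEGREE) -> BoundarySet:
    """Run the full boundary-detection chain on one stage volume.

    The binarization threshold is ``p_r3`` (plateau mean + one standard
    deviation): the operative cut lies between the two candidates ``p_r2``
    and ``p_r3``, and the modal value alone leaves half of the plateau above
    threshold under speckle. Columns where the two candidates' raw
    boundaries disagree by more than ``limit_shift_px`` rows are flagged
    ambiguous and replaced by the median of the ``neighbor_window``
    surrounding columns. On a noise-free piecewise-constant phantom both
    candidates coincide and the recovery is exact.
    """
    vol_f = volume if prefiltered else median_filter_3d(volume, h1)
    l_ef, p_r = detect_upper_boundary(vol_f)
    p_r2, p_r3 = _subsurface_thresholds(vol_f.data, l_ef)
    thresholds = ThresholdSet(p_r=float(p_r), p_r2=p_r2, p_r3=p_r3)

    binary = binarize_enamel(vol_f, p_r3)
    clean, empty_scans = refine_binary(binary, h2, se)
    if len(empty_scans) == vol_f.n_scans:
        raise NoObjectError("no enamel object found on any B-scan")
    for i in empty_scans:
        log.warning("B-scan %d: no enamel object after cleaning", i)

    b2 = _last_row_above(vol_f.data, p_r2, l_ef)
    b3 = _last_row_above(vol_f.data, p_r3, l_ef)
    with np.errstate(invalid="ignore"):
        ambiguous = np.abs(b2 - b3) > limit_shift_px
    if ambiguous.any():
        log.warning("%d columns ambiguous between p_r2/p_r3 boundaries "
                    "(> %d rows apart); using neighbour medians",
                    int(ambiguous.sum()), limit_shift_px)

    n_cols, n_scans = l_ef.shape
    l_en = np.full((n_cols, n_scans), np.nan)
    l_inr = np.full((n_cols, n_scans), np.nan)
    l_in = np.full((n_cols, n_scans), np.nan)
    coeffs_all = []
    half = neighbor_window // 2
    for i in range(n_scans):
        plane = clean[:, :, i]
        if not plane.any():
            coeffs_all.append(None)
            continue
        raw, _, _ = extract_inner_boundary(plane, poly_degree)
        amb = ambiguous[:, i] & np.isfinite(raw)
        if amb.any():
            orig = raw.copy()
            for n in np.flatnonzero(amb):
                lo, hi = max(0, n - half), min(n_cols, n + half + 1)
                med = np.nanmedian(orig[lo:hi])
                if np.isfinite(med):
                    raw[n] = med
        defined = np.isfinite(raw)
        if defined.sum() >= poly_degree + 1:
            idx = np.flatnonzero(defined)
            coeffs = np.polyfit(idx.astype(float), raw[idx], poly_degree)
            span = np.arange(idx[0], idx[-1] + 1)
            fitted = np.full(n_cols, np.nan)
            fitted[span] = np.polyval(coeffs, span.astype(float))
        else:
            log.warning("B-scan %d: polynomial fallback (%d defined columns)",
                        i, int(defined.sum()))
            coeffs = None
            fitted = raw.copy()
        coeffs_all.append(coeffs)
        l_inr[:, i] = raw
        l_in[:, i] = fitted
        l_en[:, i] = extract_outer_boundary(l_ef[:, i], plane.any(axis=0))

    return BoundarySet(L_ef=l_ef, L_en=l_en, L_inr=l_inr, L_in=l_in,
                       poly_coeffs=coeffs_all, thresholds=thresholds,
                       no_object_scans=empty_scans, ambiguous_columns=ambiguous)
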