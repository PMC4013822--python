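"""Per-stage enamel thickness maps and unit conversion."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import defaults
from .errors import DimensionError, UnitError
from .segmentation import BoundarySet

__all__ = ["ThicknessMap", "thickness_map", "to_micrometers", "to_pixels",
           "save_csv", "save_preview"]

log = logging.getLogger(__name__)


@dataclass
class ThicknessMap:
    """Thickness per (n, i); NaN cells are undefined.

    ``unit`` is ``"px"`` (axial pixels) or ``"um"``; ``stage_label`` is one
    of the treatment-stage letters a..g (or None).
    """

    values: np.ndarray
    unit: str = "px"
    stage_label: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.unit not in ("px", "um"):
            raise UnitError(f"unit must be 'px' or 'um', got {self.unit!r}")

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


def thickness_map(bounds: BoundarySet, stage_label: str | None = None) -> ThicknessMap:
    """Thickness in axial pixels: smoothed inner minus outer boundary.

    Cells where either boundary is undefined stay NaN. Negative differences
    (a segmentation failure, since zero is a meaningful thickness) are set
    undefined with a logged warning. Raises if the map is fully undefined.
    """
    values = bounds.L_in - bounds.L_en
    negative = values < 0
    if negative.any():
        log.warning("%d cells with inner boundary above outer; marked undefined",
                    int(negative.sum()))
        values = np.where(negative, np.nan, values)
    if not np.isfinite(values).any():
        raise ValueError("thickness map is undefined everywhere")
    return ThicknessMap(values, unit="px", stage_label=stage_label)


def to_micrometers(tmap: ThicknessMap,
                   spacing_axial: float = defaults.AXIAL_UM_PER_PX) -> ThicknessMap:
    """Convert a pixel-unit map to micrometres (e.g. 70 px at 5 um/px -> 350 um)."""
    if tmap.unit != "px":
        raise UnitError("map is already in micrometres")
    return replace(tmap, values=tmap.values * spacing_axial, unit="um")


def to_pixels(tmap: ThicknessMap,
              spacing_axial: float = defaults.AXIAL_UM_PER_PX) -> ThicknessMap:
    """Inverse of :func:`to_micrometers`."""
    if tmap.unit != "um":
        raise UnitError("map is already in pixels")
    return replace(tmap, values=tmap.values / spacing_axial, unit="px")


def save_csv(tmap: ThicknessMap, path) -> None:
    """Write the map as a CSV matrix (rows n, columns i)."""
    import pandas as pd

    pd.DataFrame(tmap.values).to_csv(path, index=False)


def save_preview(tmap: ThicknessMap, path) -> None:
    """Colour-mapped PNG preview of the thickness map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(tmap.values.T, origin="lower", aspect="auto", cmap="jet",
                   interpolation="nearest")
    ax.set_xlabel("column n")
    ax.set_ylabel("B-scan i")
    fig.colorbar(im, ax=ax, label=f"thickness [{tmap.unit}]")
    fig.savefig(path, dpi=120)
    plt.close(fig)
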