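"""OCT volume container and plain-file I/O (multi-page TIFF, PNG directory)."""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import defaults
from .errors import ParameterError

__all__ = ["OCTVolume", "read_volume", "write_volume"]


@dataclass
class OCTVolume:
    """A grayscale OCT stack indexed (m: depth row, n: column, i: B-scan).

    ``data`` is an (M, N, I) uint8 array; spacings are micrometres per pixel
    (axial, lateral) and micrometres between consecutive B-scans.
    """

    data: np.ndarray
    spacing_axial: float = defaults.AXIAL_UM_PER_PX
    spacing_lateral: float = defaults.LATERAL_UM_PER_PX
    spacing_slice: float = defaults.SLICE_UM

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ParameterError(f"volume must be 3-D (M, N, I), got shape {self.data.shape}")
        if self.data.dtype != np.uint8:
            if self.data.min() < 0 or self.data.max() > 255:
                raise ParameterError("intensities must lie in [0, 255]")
            self.data = self.data.astype(np.uint8)
        for name in ("spacing_axial", "spacing_lateral", "spacing_slice"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    @property
    def n_scans(self) -> int:
        return self.data.shape[2]

    def with_data(self, data: np.ndarray) -> "OCTVolume":
        return replace(self, data=data)


def read_volume(path: str | os.PathLike,
                spacing_axial: float = defaults.AXIAL_UM_PER_PX,
                spacing_lateral: float = defaults.LATERAL_UM_PER_PX,
                spacing_slice: float = defaults.SLICE_UM) -> OCTVolume:
    """Read a volume from a multi-page TIFF or a directory of image slices.

    TIFF pages (or sorted directory files) are B-scans of shape (M, N);
    they are stacked along the last axis.
    """
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in {".png", ".tif", ".tiff", ".bmp"})
        if not files:
            raise FileNotFoundError(f"no image slices found in {path}")
        pages = [np.asarray(iio.imread(f)) for f in files]
        stack = np.stack(pages, axis=0)
    else:
        import tifffile

        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
    if stack.ndim != 3:
        raise ParameterError(f"expected grayscale slices, got shape {stack.shape}")
    data = np.moveaxis(stack, 0, 2)  # (I, M, N) -> (M, N, I)
    return OCTVolume(data, spacing_axial, spacing_lateral, spacing_slice)


def write_volume(volume: OCTVolume, path: str | os.PathLike) -> None:
    """Write the volume as an uncompressed multi-page TIFF, one page per B-scan."""
    import tifffile

    pages = np.moveaxis(volume.data, 2, 0)  # (M, N, I) -> (I, M, N)
    tifffile.imwrite(path, pages, photometric="minisblack")
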