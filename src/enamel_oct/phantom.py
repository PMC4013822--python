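"""Synthetic OCT tooth phantoms with exact ground truth.

A phantom column inside the tooth footprint is, from top to bottom:
background, a bright enamel band, then dimmer dentine down to the last row.
The outer boundary is the first enamel row, the inner boundary the last one,
so ``thickness_px = inner - outer`` and a noise-free phantom is recovered
exactly by the segmentation chain.

Surface and thickness fields are callables of normalized lateral coordinates
``(u, v)`` in [-1, 1]^2 (u along columns n, v along B-scans i), which keeps
parameter sets independent of the grid size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import defaults
from ._grid import plant_transform
from .errors import ParameterError
from .volume import OCTVolume, write_volume

__all__ = [
    "PhantomParams",
    "PhantomGroundTruth",
    "generate_volume",
    "generate_stage_series",
    "save_phantom",
    "flat_surface",
    "parabolic_surface",
    "constant_thickness",
    "elliptical_thickness",
]

Field = Callable[[np.ndarray, np.ndarray], np.ndarray]


def flat_surface(row: float) -> Field:
    """Outer surface at a constant depth row."""
    return lambda u, v: np.full(np.broadcast(u, v).shape, float(row))


def parabolic_surface(base_row: float, amp_n: float = 25.0, amp_i: float = 8.0) -> Field:
    """Gently curved surface: deepest at the lateral centre."""
    return lambda u, v: base_row + amp_n * u ** 2 + amp_i * v ** 2


def constant_thickness(px: float) -> Field:
    """Enamel band of uniform thickness across the full grid."""
    return lambda u, v: np.full(np.broadcast(u, v).shape, float(px))


def elliptical_thickness(px: float, a: float = 0.8, b: float = 0.75) -> Field:
    """Uniform-thickness enamel restricted to an elliptical tooth footprint."""

    def g(u, v):
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        return np.where(inside, float(px), 0.0)

    return g


@dataclass
class PhantomParams:
    """Full description of one synthetic stage volume."""

    shape: tuple[int, int, int] = (300, 256, 32)
    spacings: tuple[float, float, float] = (
        defaults.AXIAL_UM_PER_PX,
        defaults.LATERAL_UM_PER_PX,
        defaults.SLICE_UM,
    )
    surface_profile: Field = field(default_factory=lambda: parabolic_surface(60.0))
    enamel_thickness_field: Field = field(default_factory=lambda: elliptical_thickness(70.0))
    intensity_levels: tuple[int, int, int] = (10, 200, 80)  # background, enamel, dentine
    speckle_strength: float = 0.0
    speckle_model: str = "rayleigh"
    seed: int = 0

    def __post_init__(self):
        m, n, i = self.shape
        if min(m, n, i) < 1:
            raise ParameterError(f"invalid shape {self.shape}")
        bg, en, de = self.intensity_levels
        if not (0 <= bg <= 255 and 0 <= en <= 255 and 0 <= de <= 255):
            raise ParameterError("intensity levels must lie in [0, 255]")
        if not en > de > bg:
            raise ParameterError(
                "intensity ordering must be enamel > dentine > background, "
                f"got {self.intensity_levels}")
        if self.speckle_strength < 0:
            raise ParameterError("speckle strength must be >= 0")
        if self.speckle_model != "rayleigh":
            raise ParameterError(f"unknown speckle model {self.speckle_model!r}")


@dataclass
class PhantomGroundTruth:
    """Per-(n, i) ground truth arrays on the stage's own grid."""

    outer_boundary: np.ndarray  # float rows, NaN outside the tooth
    inner_boundary: np.ndarray  # float rows, NaN outside the tooth
    thickness_px: np.ndarray    # float, 0 outside the tooth
    tooth_mask: np.ndarray      # bool
    applied_transform: tuple[int, int, float] = (0, 0, 0.0)


def _lateral_grids(shape):
    _, n, i = shape
    u = np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1)
    v = np.linspace(-1.0, 1.0, i) if i > 1 else np.zeros(1)
    return np.meshgrid(u, v, indexing="ij")


def generate_volume(params: PhantomParams) -> tuple[OCTVolume, PhantomGroundTruth]:
    """Render one stage volume plus its exact ground truth.

    Deterministic for a fixed seed. Speckle is multiplicative Rayleigh-like
    noise (unit mean) clipped to [0, 255]; strength 0 disables it.
    """
    m_rows, n_cols, n_scans = params.shape
    uu, vv = _lateral_grids(params.shape)
    surface = np.asarray(params.surface_profile(uu, vv), dtype=float)
    thickness = np.asarray(params.enamel_thickness_field(uu, vv), dtype=float)
    if np.any(thickness < 0):
        raise ParameterError("enamel thickness field must be >= 0 everywhere")
    outer = np.floor(surface + 0.5)
    t_px = np.floor(thickness + 0.5)
    mask = t_px > 0
    inner = outer + t_px
    if np.any(outer[mask] < 0) or np.any(inner[mask] > m_rows - 1):
        raise ParameterError("surface + thickness leaves the depth range [0, M)")

    bg, en, de = params.intensity_levels
    m_grid = np.arange(m_rows, dtype=float)[:, None, None]
    vol = np.full(params.shape, float(bg))
    in_enamel = mask[None] & (m_grid >= outer[None]) & (m_grid <= inner[None])
    in_dentine = mask[None] & (m_grid > inner[None])
    vol[in_enamel] = en
    vol[in_dentine] = de

    if params.speckle_strength > 0:
        rng = np.random.default_rng(params.seed)
        ray = rng.rayleigh(scale=1.0, size=params.shape)
        factor = 1.0 + params.speckle_strength * (ray - math.sqrt(math.pi / 2.0))
        vol = vol * np.clip(factor, 0.0, None)
    data = np.clip(np.floor(vol + 0.5), 0, 255).astype(np.uint8)

    truth = PhantomGroundTruth(
        outer_boundary=np.where(mask, outer, np.nan),
        inner_boundary=np.where(mask, inner, np.nan),
        thickness_px=np.where(mask, t_px, 0.0),
        tooth_mask=mask,
    )
    return OCTVolume(data, *params.spacings), truth


def generate_stage_series(
    base: PhantomParams,
    stage_deltas_um: Sequence[float],
    stage_transforms: Sequence[tuple[int, int, float]] | None = None,
) -> list[tuple[OCTVolume, PhantomGroundTruth]]:
    """Render a series of treatment stages from one base geometry.

    Stage k's enamel thickness field is the base field offset by
    ``stage_deltas_um[k]`` (converted to axial pixels, clipped at zero inside
    the footprint), then displaced/zoomed by ``stage_transforms[k]``. The
    first stage must carry the identity transform. Each stage uses seed
    ``base.seed + k`` so speckle realisations are independent.
    """
    n_stages = len(stage_deltas_um)
    if stage_transforms is None:
        stage_transforms = [(0, 0, 0.0)] * n_stages
    if len(stage_transforms) != n_stages:
        raise ParameterError("stage_deltas and stage_transforms lengths differ")
    if tuple(stage_transforms[0]) != (0, 0, 0.0) and tuple(stage_transforms[0]) != (0, 0, 0):
        raise ParameterError("first stage must have the identity transform")
    axial = base.spacings[0]
    out = []
    for k, (delta_um, (dn, di, dz)) in enumerate(zip(stage_deltas_um, stage_transforms)):
        if abs(dn) > defaults.SHIFT_RANGE_PX or abs(di) > defaults.SHIFT_RANGE_PX:
            raise ParameterError(
                f"stage {k}: |shift| exceeds the +/-{defaults.SHIFT_RANGE_PX} px search range")
        if abs(dz) > max(abs(z) for z in defaults.ZOOM_PERCENTS):
            raise ParameterError(f"stage {k}: |zoom| exceeds the searched range")
        delta_px = delta_um / axial
        base_field = base.enamel_thickness_field

        def staged_field(u, v, _g=base_field, _d=delta_px):
            g = np.asarray(_g(u, v), dtype=float)
            return np.where(g > 0, np.clip(g + _d, 0.0, None), 0.0)

        params = replace(base, enamel_thickness_field=staged_field, seed=base.seed + k)
        vol, truth = generate_volume(params)
        if (dn, di, dz) != (0, 0, 0.0) and (dn, di, dz) != (0, 0, 0):
            data = plant_transform(vol.data, dn, di, dz, axes=(1, 2), fill=0)
            vol = vol.with_data(data)
            truth = PhantomGroundTruth(
                outer_boundary=plant_transform(truth.outer_boundary, dn, di, dz, fill=np.nan),
                inner_boundary=plant_transform(truth.inner_boundary, dn, di, dz, fill=np.nan),
                thickness_px=plant_transform(truth.thickness_px, dn, di, dz, fill=0.0),
                tooth_mask=plant_transform(truth.tooth_mask, dn, di, dz, fill=False),
                applied_transform=(dn, di, dz),
            )
        out.append((vol, truth))
    return out


def save_phantom(vol: OCTVolume, truth: PhantomGroundTruth, out_dir: str | Path,
                 prefix: str = "stage") -> None:
    """Export a stage as multi-page TIFF plus ground-truth CSV arrays."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_volume(vol, out_dir / f"{prefix}.tiff")
    np.savetxt(out_dir / f"{prefix}_outer_boundary.csv", truth.outer_boundary, delimiter=",", fmt="%.1f")
    np.savetxt(out_dir / f"{prefix}_inner_boundary.csv", truth.inner_boundary, delimiter=",", fmt="%.1f")
    np.savetxt(out_dir / f"{prefix}_thickness_px.csv", truth.thickness_px, delimiter=",", fmt="%.1f")
    np.savetxt(out_dir / f"{prefix}_tooth_mask.csv", truth.tooth_mask.astype(int), delimiter=",", fmt="%d")
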