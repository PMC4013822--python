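"""Per-stage ROI statistics, stage-difference matrix, accuracy metric, reports."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import defaults
from .errors import DimensionError, ParameterError
from .thickness import ThicknessMap

__all__ = ["StageStats", "DifferenceMatrix", "ExpertBoundaries",
           "stage_statistics", "difference_matrix", "measurement_error",
           "interpolate_expert_points", "load_expert_csv",
           "export_report", "read_report"]

log = logging.getLogger(__name__)


@dataclass
class StageStats:
    """Summary of enamel thickness inside the ROI for one stage, micrometres."""

    stage_label: str
    mean: float
    std: float
    min: float
    max: float
    n_defined: int


@dataclass
class DifferenceMatrix:
    """Pairwise differences of stage means: ``entries[r, c] = mean_c - mean_r``.

    The row stage is the baseline, so a thickness loss from stage r to stage
    c appears as a negative entry; the matrix is antisymmetric by
    construction.
    """

    entries: np.ndarray
    labels: tuple

    def __getitem__(self, rc):
        return self.entries[rc]


@dataclass
class ExpertBoundaries:
    """Reference boundaries for one B-scan: outer, inner and their difference."""

    L_en_E: np.ndarray
    L_in_E: np.ndarray

    @property
    def L_d_E(self) -> np.ndarray:
        return self.L_in_E - self.L_en_E


def stage_statistics(tmap: ThicknessMap, mask: np.ndarray | None = None) -> StageStats:
    """Mean/std/min/max thickness over the defined, in-mask cells.

    The map must be in micrometres; ``std`` is the population standard
    deviation. Raises if no cell qualifies.
    """
    if tmap.unit != "um":
        raise ParameterError("stage statistics expect a map in micrometres")
    keep = tmap.defined_mask
    if mask is not None:
        mask = getattr(mask, "mask", mask)
        if mask.shape != tmap.values.shape:
            raise DimensionError("mask shape does not match the thickness map")
        keep = keep & mask
    cells = tmap.values[keep]
    if cells.size == 0:
        raise ValueError("no defined in-mask thickness cells")
    return StageStats(stage_label=tmap.stage_label or "?",
                      mean=float(cells.mean()), std=float(cells.std()),
                      min=float(cells.min()), max=float(cells.max()),
                      n_defined=int(cells.size))


def _pairwise_differences(means: np.ndarray) -> np.ndarray:
    return means[None, :] - means[:, None]


def difference_matrix(stats: list[StageStats], n_stages: int = 7) -> DifferenceMatrix:
    """Stage-difference matrix from the per-stage means (7 stages a..g)."""
    if len(stats) != n_stages:
        raise ParameterError(f"expected {n_stages} stages, got {len(stats)}")
    means = np.array([s.mean for s in stats], dtype=float)
    return DifferenceMatrix(entries=_pairwise_differences(means),
                            labels=tuple(s.stage_label for s in stats))


def measurement_error(l_d: np.ndarray, l_d_expert: np.ndarray) -> float:
    """Mean absolute relative thickness error against a reference, percent.

    Averaged over the columns where both profiles are defined; reference
    columns at or below zero are excluded with a warning.
    """
    l_d = np.asarray(l_d, dtype=float).ravel()
    l_d_expert = np.asarray(l_d_expert, dtype=float).ravel()
    if l_d.shape != l_d_expert.shape:
        raise DimensionError("profiles differ in length")
    common = np.isfinite(l_d) & np.isfinite(l_d_expert)
    bad = common & (l_d_expert <= 0)
    if bad.any():
        log.warning("%d columns with non-positive reference thickness excluded",
                    int(bad.sum()))
    use = common & (l_d_expert > 0)
    if not use.any():
        raise ValueError("no comparable columns")
    return float(np.mean(np.abs(l_d[use] - l_d_expert[use]) / l_d_expert[use]) * 100.0)


def interpolate_expert_points(columns: np.ndarray, rows: np.ndarray,
                              n_cols: int) -> np.ndarray:
    """Connect sparse expert-marked points with straight segments.

    Linear interpolation between consecutive marked columns; columns outside
    the marked range stay undefined (NaN).
    """
    columns = np.asarray(columns, dtype=float)
    rows = np.asarray(rows, dtype=float)
    order = np.argsort(columns)
    columns, rows = columns[order], rows[order]
    out = np.full(n_cols, np.nan)
    if columns.size == 0:
        return out
    lo, hi = int(np.ceil(columns[0])), int(np.floor(columns[-1]))
    span = np.arange(lo, hi + 1)
    out[span] = np.interp(span, columns, rows)
    return out


def load_expert_csv(path, n_cols: int) -> dict[int, ExpertBoundaries]:
    """Read expert point annotations: CSV columns ``i, n, boundary, row``.

    ``boundary`` is ``en`` (outer) or ``in`` (inner); points are linearly
    interpolated per B-scan across the marked column range.
    """
    df = pd.read_csv(path)
    required = {"i", "n", "boundary", "row"}
    if not required.issubset(df.columns):
        raise ParameterError(f"expert CSV must have columns {sorted(required)}")
    out = {}
    for i, group in df.groupby("i"):
        en = group[group["boundary"] == "en"]
        inn = group[group["boundary"] == "in"]
        out[int(i)] = ExpertBoundaries(
            L_en_E=interpolate_expert_points(en["n"].to_numpy(), en["row"].to_numpy(), n_cols),
            L_in_E=interpolate_expert_points(inn["n"].to_numpy(), inn["row"].to_numpy(), n_cols),
        )
    return out


def export_report(stats: list[StageStats], matrix: DifferenceMatrix | None,
                  meta: dict, out_dir) -> dict[str, Path]:
    """Write ``stage_stats.csv``, ``difference_matrix.csv`` and ``run_meta.json``."""
    if not stats:
        raise ParameterError("no stage statistics to export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    stats_df = pd.DataFrame([{"stage": s.stage_label, "mean": s.mean, "std": s.std,
                              "min": s.min, "max": s.max, "n": s.n_defined}
                             for s in stats])
    paths["stage_stats"] = out_dir / "stage_stats.csv"
    stats_df.to_csv(paths["stage_stats"], index=False)
    if matrix is not None:
        mat_df = pd.DataFrame(matrix.entries, index=matrix.labels, columns=matrix.labels)
        paths["difference_matrix"] = out_dir / "difference_matrix.csv"
        mat_df.to_csv(paths["difference_matrix"])
    paths["run_meta"] = out_dir / "run_meta.json"
    with open(paths["run_meta"], "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def read_report(out_dir) -> tuple[pd.DataFrame, pd.DataFrame | None, dict]:
    """Round-trip reader for :func:`export_report`."""
    out_dir = Path(out_dir)
    stats = pd.read_csv(out_dir / "stage_stats.csv")
    matrix_path = out_dir / "difference_matrix.csv"
    matrix = pd.read_csv(matrix_path, index_col=0) if matrix_path.exists() else None
    with open(out_dir / "run_meta.json") as fh:
        meta = json.load(fh)
    return stats, matrix, meta
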