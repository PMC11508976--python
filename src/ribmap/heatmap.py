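"""Fracture-frequency aggregation and 3D heat-map painting.

Fracture records aggregate two ways: a rib x position-bin count matrix (the
numeric substrate of the histogram and heat map) and a smoothed along-rib
density per rib (Gaussian kernel in percent coordinates with boundary
reflection at 0 and 100, so no probability mass leaks off the ends of the
rib).  Both live in 1D percent coordinates; the 3D rendering transfers them to
template vertices through each vertex's arc-length fraction and a monotone
blue-to-red colormap — blue marks positions with few fracture lines, red the
positions where they concentrate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .geometry import RIB_INDICES, ThoraxTemplate, tube_mesh
from .mapping import Cohort, DEFAULT_BIN_WIDTH, n_bins

SideScope = Literal["left", "right", "pooled", "mirrored"]

_SCOPE_SIDES: dict[str, tuple[str, ...]] = {
    "left": ("left",),
    "right": ("right",),
    "pooled": ("left", "right"),
    "mirrored": ("left", "right"),  # counts pool; painting targets one hemithorax
}


@dataclass(frozen=True)
class FrequencyMatrix:
    """Integer fracture-line counts, rows = ribs 1-12, columns = position bins."""

    counts: np.ndarray
    side_scope: SideScope
    bin_width: float

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (12, n_bins(self.bin_width)) or (c < 0).any():
            raise ValueError("counts must be a non-negative (12, n_bins) matrix")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def bin_totals(self) -> np.ndarray:
        """Counts per position bin pooled over ribs (the 10 %-segment histogram)."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: rib, bin_start, bin_end, count."""
        k = self.counts.shape[1]
        rows = [
            (rib, b * self.bin_width, (b + 1) * self.bin_width, int(self.counts[rib - 1, b]))
            for rib in RIB_INDICES
            for b in range(k)
        ]
        return pd.DataFrame(rows, columns=["rib", "bin_start", "bin_end", "count"])


def frequency_matrix(
    cohort: Cohort,
    bin_width: float = DEFAULT_BIN_WIDTH,
    side_scope: SideScope = "pooled",
) -> FrequencyMatrix:
    """Count fracture records per (rib, position bin) under a side scope.

    ``pooled`` sums left + right; ``mirrored`` does too (positions are
    side-symmetric percentages, so mirroring changes only where the counts are
    painted, not the counts themselves).  The grand total always equals the
    number of in-scope records.
    """
    if side_scope not in _SCOPE_SIDES:
        raise ValueError(f"unknown side_scope {side_scope!r}")
    k = n_bins(bin_width)
    counts = np.zeros((12, k), dtype=int)
    sides = _SCOPE_SIDES[side_scope]
    for rec in cohort.fracture_records():
        if rec.side in sides:
            counts[rec.rib_index - 1, rec.bin(bin_width)] += 1
    return FrequencyMatrix(counts, side_scope, bin_width)


@dataclass(frozen=True)
class DensityProfile:
    """Smoothed along-rib fracture-line density on a percent grid.

    The density integrates (trapezoidally) to the number of contributing
    records: each record contributes one unit of mass, kept inside [0, 100] by
    boundary reflection.
    """

    rib_index: int
    side_scope: SideScope
    sample_positions: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        if (np.asarray(self.density) < 0).any():
            raise ValueError("density must be non-negative")

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.sample_positions))

    def at(self, percent: np.ndarray | float) -> np.ndarray:
        """Linear interpolation of the density at arbitrary percent positions."""
        return np.interp(percent, self.sample_positions, self.density)


def _reflected_kernel_sum(
    grid: np.ndarray, positions: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Sum of Gaussian kernels with single reflection at 0 and at 100."""
    images = np.concatenate([positions, -positions, 200.0 - positions])
    z = (grid[:, None] - images[None, :]) / bandwidth
    kern = np.exp(-0.5 * z * z) / (bandwidth * np.sqrt(2.0 * np.pi))
    return kern.sum(axis=1)


def density_profile(
    cohort: Cohort,
    rib_index: int,
    side_scope: SideScope = "pooled",
    bandwidth: float = 5.0,
    grid_step: float = 0.5,
) -> DensityProfile:
    """Boundary-reflected Gaussian kernel density of one rib's fracture positions.

    A rib with no in-scope records yields an explicit all-zero profile rather
    than an error, so downstream painting can treat every rib uniformly.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if side_scope not in _SCOPE_SIDES:
        raise ValueError(f"unknown side_scope {side_scope!r}")
    grid = np.arange(0.0, 100.0 + grid_step / 2, grid_step)
    sides = _SCOPE_SIDES[side_scope]
    positions = np.array(
        [r.percent for r in cohort.fracture_records()
         if r.rib_index == rib_index and r.side in sides]
    )
    if positions.size == 0:
        dens = np.zeros_like(grid)
    else:
        dens = _reflected_kernel_sum(grid, positions, bandwidth)
    return DensityProfile(rib_index, side_scope, grid, dens, bandwidth)


def all_density_profiles(
    cohort: Cohort,
    side_scope: SideScope = "pooled",
    bandwidth: float = 5.0,
    grid_step: float = 0.5,
) -> dict[int, DensityProfile]:
    return {
        rib: density_profile(cohort, rib, side_scope, bandwidth, grid_step)
        for rib in RIB_INDICES
    }


# ---------------------------------------------------------------------------
# 3D painting
# ---------------------------------------------------------------------------

def paint_heatmap(
    template: ThoraxTemplate,
    source: FrequencyMatrix | Mapping[int, DensityProfile],
    *,
    cmap: str = "jet",
    vmin: float | None = None,
    vmax: float | None = None,
    tube_radius: float = 4.0,
    n_sides: int = 16,
):
    """Paint per-rib frequencies onto the template as a colored tube model.

    Each tube vertex gets the density (or bin count) at its arc-length
    percentage, mapped through a monotone colormap with one fixed color range
    for the whole figure, so inter-rib frequency differences stay visible.
    Returns a ``trimesh.Trimesh`` with per-vertex RGBA colors; deterministic
    for fixed inputs.
    """
    import trimesh
    from matplotlib import colormaps

    if isinstance(source, FrequencyMatrix):
        scope = source.side_scope
        def value_at(rib: int, percent: np.ndarray) -> np.ndarray:
            width = source.bin_width
            k = source.counts.shape[1]
            idx = np.minimum((percent // width).astype(int), k - 1)
            return source.counts[rib - 1, idx].astype(float)
        all_values = source.counts.astype(float)
    else:
        scopes = {p.side_scope for p in source.values()}
        if len(scopes) != 1:
            raise ValueError("density profiles mix side scopes")
        scope = next(iter(scopes))
        def value_at(rib: int, percent: np.ndarray) -> np.ndarray:
            return source[rib].at(percent)
        all_values = np.concatenate([p.density for p in source.values()])

    paint_sides = {"left": ("left",), "right": ("right",),
                   "pooled": ("left", "right"), "mirrored": ("right",)}[scope]

    lo = 0.0 if vmin is None else vmin
    hi = float(np.max(all_values)) if vmax is None else vmax
    if hi <= lo:
        hi = lo + 1.0  # all-zero field paints uniformly at the colormap minimum
    colormap = colormaps[cmap]

    meshes = []
    for curve in template.curves:
        if curve.side not in paint_sides:
            continue
        verts, faces, percent = tube_mesh(curve, tube_radius, n_sides)
        scalars = value_at(curve.rib_index, percent)
        normed = np.clip((scalars - lo) / (hi - lo), 0.0, 1.0)
        colors = (colormap(normed) * 255).astype(np.uint8)
        meshes.append(
            trimesh.Trimesh(vertices=verts, faces=faces, vertex_colors=colors,
                            process=False)
        )
    return trimesh.util.concatenate(meshes)


def export_heatmap_ply(mesh, path: str | Path) -> None:
    """Write the painted model as PLY with per-vertex RGB color."""
    mesh.export(str(path), file_type="ply")


def export_heatmap_stl(mesh, path: str | Path) -> None:
    """Write the model geometry as STL (no color; STL carries none)."""
    mesh.export(str(path), file_type="stl")


def profiles_to_frame(profiles: Mapping[int, DensityProfile]) -> pd.DataFrame:
    """Long-format density table: rib, position, density."""
    rows = []
    for rib in sorted(profiles):
        p = profiles[rib]
        rows.extend(zip([rib] * len(p.sample_positions), p.sample_positions, p.density))
    return pd.DataFrame(rows, columns=["rib", "position", "density"])


def plot_bin_histogram(matrix: FrequencyMatrix, path: str | Path) -> None:
    """Bar chart of fracture-line counts per position segment (all ribs pooled)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    totals = matrix.bin_totals()
    width = matrix.bin_width
    labels = [f"{int(b * width)}-{int((b + 1) * width)}%" for b in range(len(totals))]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(range(len(totals)), totals, color="#3b6fb5")
    ax.set_xticks(range(len(totals)), labels, rotation=45, ha="right")
    ax.set_xlabel("Percentage position along the rib")
    ax.set_ylabel("Fracture lines")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
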