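"""Image-coverage rasters: how many images observed each point of the site.

Each camera exposure contributes a footprint polygon in plane coordinates. The
coverage raster counts, at 0.5 cm/pixel by default, how many footprints
contain each cell centre; per-quadrat summaries are the mean count ("average
coverage") and the population standard deviation of counts ("coverage
variation"). No occlusion modelling: a footprint observes every point inside
it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely

from .errors import MissingDataError, ParameterError
from .rugosity import QuadratGrid

__all__ = [
    "DEFAULT_COVERAGE_CELL",
    "CameraView",
    "CoverageRaster",
    "CoverageMetrics",
    "rasterize_coverage",
    "quadrat_coverage",
]

DEFAULT_COVERAGE_CELL = 0.005  # m/pixel


@dataclass
class CameraView:
    """One image footprint: a convex polygon in plane coordinates (m)."""

    view_id: object
    footprint: shapely.Polygon

    def __post_init__(self) -> None:
        if not isinstance(self.footprint, shapely.Polygon):
            self.footprint = shapely.Polygon(self.footprint)
        if self.footprint.is_empty or self.footprint.area <= 0:
            raise ParameterError(f"view {self.view_id}: degenerate footprint")


@dataclass
class CoverageRaster:
    """Integer per-cell image counts. Cell (i, j) is centred at
    ``origin + (j + 1/2, i + 1/2) * cell_size``."""

    counts: np.ndarray
    origin: tuple[float, float]
    cell_size: float = DEFAULT_COVERAGE_CELL

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or np.any(self.counts < 0):
            raise ParameterError("counts must be a non-negative 2D grid")
        if not self.cell_size > 0:
            raise ParameterError("cell_size must be positive")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.counts.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        return xs, ys


@dataclass
class CoverageMetrics:
    quadrat_id: int
    avg_coverage: float
    coverage_variation: float
    n_cells: int


def rasterize_coverage(
    views: list[CameraView],
    extent: tuple[float, float, float, float],
    cell_size: float = DEFAULT_COVERAGE_CELL,
) -> CoverageRaster:
    """Count, per cell, the footprints containing the cell centre.

    ``extent`` is (minx, miny, maxx, maxy) in plane coordinates. Each view is
    tested only on the cells inside its bounding box, so cost is proportional
    to footprint area, not raster area.
    """
    minx, miny, maxx, maxy = extent
    if not (maxx > minx and maxy > miny):
        raise ParameterError("degenerate extent")
    nx = int(np.ceil((maxx - minx) / cell_size - 1e-9))
    ny = int(np.ceil((maxy - miny) / cell_size - 1e-9))
    counts = np.zeros((ny, nx), dtype=np.int64)
    if not views:
        warnings.warn("no camera views: coverage raster is all zero", stacklevel=2)
        return CoverageRaster(counts, (minx, miny), cell_size)

    xs = minx + (np.arange(nx) + 0.5) * cell_size
    ys = miny + (np.arange(ny) + 0.5) * cell_size
    for view in views:
        bx0, by0, bx1, by1 = view.footprint.bounds
        j0 = max(0, int(np.floor((bx0 - minx) / cell_size)))
        j1 = min(nx, int(np.ceil((bx1 - minx) / cell_size)) + 1)
        i0 = max(0, int(np.floor((by0 - miny) / cell_size)))
        i1 = min(ny, int(np.ceil((by1 - miny) / cell_size)) + 1)
        if j0 >= j1 or i0 >= i1:
            continue
        gx, gy = np.meshgrid(xs[j0:j1], ys[i0:i1])
        inside = shapely.contains_xy(view.footprint, gx.ravel(), gy.ravel())
        counts[i0:i1, j0:j1] += inside.reshape(gy.shape)
    return CoverageRaster(counts, (minx, miny), cell_size)


def quadrat_coverage(
    raster: CoverageRaster, grid: QuadratGrid
) -> list[CoverageMetrics]:
    """Average coverage and coverage variation (population sd) per quadrat.

    Every quadrat of the grid must lie inside the raster; otherwise a
    :class:`MissingDataError` names the offending quadrats.
    """
    xs, ys = raster.cell_centers()
    metrics = []
    missing = []
    s = grid.quadrat_size
    for row in range(grid.n_rows):
        for col in range(grid.n_cols):
            qid = grid.quadrat_id(row, col)
            x0 = grid.origin[0] + col * s
            y0 = grid.origin[1] + row * s
            jsel = (xs >= x0) & (xs < x0 + s)
            isel = (ys >= y0) & (ys < y0 + s)
            block = raster.counts[np.ix_(isel, jsel)]
            # the quadrat must be fully tiled by raster cells
            expect = int(round(s / raster.cell_size))
            if block.shape[0] < expect or block.shape[1] < expect:
                missing.append(qid)
                continue
            metrics.append(
                CoverageMetrics(
                    quadrat_id=qid,
                    avg_coverage=float(block.mean()),
                    coverage_variation=float(block.std()),  # population form
                    n_cells=int(block.size),
                )
            )
    if missing:
        raise MissingDataError(f"quadrat(s) outside the coverage raster: {missing}")
    return metrics
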