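"""Surface rugosity (SR) per virtual quadrat at multiple link sizes.

The rugosity index is the ratio of true 3D surface area to its orthographic
projection onto a site-level plane of best fit:

    SR = sum_i a_i / sum_i a_proj_i

where ``a_i`` is the area of face ``i`` and ``a_proj_i`` its projected area
``a_i * |cos(theta_i)|``, ``theta_i`` the angle between the face normal and
the plane normal. Fitting the projection plane to the whole site decouples SR
from the overall slope of the terrain: a tilted but perfectly planar site has
SR = 1. The absolute value makes overhanging faces add area rather than
cancel, so SR >= 1 always.

"Link size" is the spatial resolution at which SR is measured — the analogue
of chain-link length in chain-and-tape surveys. Coarser link sizes smooth
relief and monotonically reduce SR; here a link size is realised by
block-mean resampling of the heightfield before triangulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGeometryError,
    ParameterError,
    UndefinedStatisticError,
)
from .surface_model import HeightField, SurfaceMesh, heightfield_to_mesh

__all__ = [
    "DEFAULT_LINK_SIZES",
    "ReferencePlane",
    "QuadratGrid",
    "QuadratRugosity",
    "fit_reference_plane",
    "projected_face_area",
    "partition_quadrats",
    "compute_sr",
    "resample_link_size",
    "multiscale_sr",
]

#: link sizes used throughout (m): native 2.5 cm plus 5 cm steps up to 25 cm
DEFAULT_LINK_SIZES = (0.025, 0.05, 0.10, 0.15, 0.20, 0.25)


@dataclass
class ReferencePlane:
    """The site-level projection plane.

    ``point`` lies on the plane, ``normal`` is unit length and points into the
    +z hemisphere, and ``axes`` (2, 3) are two orthonormal in-plane directions;
    the first is the projection of world +x onto the plane, which fixes the
    quadrat grid orientation deterministically.
    """

    point: np.ndarray
    normal: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(2, 3)

    @classmethod
    def from_point_normal(cls, point, normal) -> "ReferencePlane":
        n = np.asarray(normal, dtype=float)
        n = n / np.linalg.norm(n)
        if n[2] < 0:
            n = -n
        ref = np.array([1.0, 0.0, 0.0])
        u = ref - np.dot(ref, n) * n
        if np.linalg.norm(u) < 1e-12:  # normal parallel to x: fall back to +y
            ref = np.array([0.0, 1.0, 0.0])
            u = ref - np.dot(ref, n) * n
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return cls(np.asarray(point, dtype=float), n, np.vstack([u, v]))

    def to_plane_coords(self, points: np.ndarray) -> np.ndarray:
        """Project points into (u, v) plane coordinates (n, 2)."""
        d = np.asarray(points, dtype=float) - self.point
        return d @ self.axes.T


@dataclass(frozen=True)
class QuadratGrid:
    """Non-overlapping square virtual quadrats, axis-aligned in plane coords.

    Quadrat (row, col) covers
    ``[origin + col*s, origin + (col+1)*s) x [origin + row*s, ...)`` with
    ``s = quadrat_size``; its id is ``row * n_cols + col``.
    """

    origin: tuple[float, float]
    n_rows: int
    n_cols: int
    quadrat_size: float = 2.0

    def __post_init__(self) -> None:
        if not self.quadrat_size > 0:
            raise ParameterError("quadrat_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ParameterError("grid must contain at least one quadrat")

    @classmethod
    def from_extent(cls, min_uv, max_uv, quadrat_size: float = 2.0) -> "QuadratGrid":
        """Smallest grid of full quadrats covering the [min_uv, max_uv] box."""
        min_uv = np.asarray(min_uv, dtype=float)
        max_uv = np.asarray(max_uv, dtype=float)
        span = max_uv - min_uv
        if np.any(span <= 0):
            raise ParameterError("degenerate extent")
        n_cols = max(1, int(np.ceil(span[0] / quadrat_size - 1e-9)))
        n_rows = max(1, int(np.ceil(span[1] / quadrat_size - 1e-9)))
        return cls((float(min_uv[0]), float(min_uv[1])), n_rows, n_cols, quadrat_size)

    def quadrat_id(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def rowcol(self, quadrat_id: int) -> tuple[int, int]:
        return divmod(quadrat_id, self.n_cols)

    def locate(self, uv: np.ndarray) -> np.ndarray:
        """Quadrat id for each (u, v) point; -1 when outside the grid.

        A point exactly on an internal boundary belongs to the lower-index
        quadrat (tie rule).
        """
        uv = np.asarray(uv, dtype=float).reshape(-1, 2)
        t = (uv - np.asarray(self.origin)) / self.quadrat_size
        idx = np.floor(t).astype(np.int64)
        # exact internal boundary -> lower index
        on_edge = (t == idx) & (idx > 0)
        idx = idx - on_edge
        col, row = idx[:, 0], idx[:, 1]
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        out = np.where(inside, row * self.n_cols + col, -1)
        return out


@dataclass
class QuadratRugosity:
    """One SR measurement: quadrat, link size, SR, and the two area sums."""

    quadrat_id: int
    link_size: float
    sr: float
    total_area: float
    projected_area: float
    n_faces: int


def fit_reference_plane(mesh: SurfaceMesh) -> ReferencePlane:
    """Total (orthogonal) least-squares plane through the mesh vertices.

    The normal is the smallest principal direction of the centered vertex
    cloud, flipped into the +z hemisphere. Rotation-invariant, so rigidly
    transforming the mesh and refitting leaves SR unchanged.
    """
    verts = mesh.vertices
    if len(verts) < 3:
        raise DegenerateGeometryError("need at least 3 vertices to fit a plane")
    centroid = verts.mean(axis=0)
    centered = verts - centroid
    # SVD of the (3, 3) scatter is cheap and robust for any vertex count
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    if w[1] <= 1e-12 * max(w[2], 1.0):
        raise DegenerateGeometryError("vertices are (near-)collinear; plane undefined")
    normal = v[:, 0]  # smallest eigenvalue
    return ReferencePlane.from_point_normal(centroid, normal)


def projected_face_area(face_vertices: np.ndarray, plane: ReferencePlane) -> float:
    """Orthographically projected area of one triangle onto the plane.

    Equals ``area * |cos theta|``; the absolute value means overhangs add
    projected area rather than cancel it. Zero-area faces project to 0.
    """
    tri = np.asarray(face_vertices, dtype=float).reshape(3, 3)
    cross = np.cross(tri[1] - tri[0], tri[2] - tri[0])
    return 0.5 * abs(float(np.dot(cross, plane.normal)))


def _face_areas_and_projections(
    mesh: SurfaceMesh, plane: ReferencePlane
) -> tuple[np.ndarray, np.ndarray]:
    cross = mesh.face_normals_unnormalized()
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    proj = 0.5 * np.abs(cross @ plane.normal)
    return areas, proj


def partition_quadrats(
    mesh: SurfaceMesh,
    plane: ReferencePlane,
    grid: QuadratGrid,
    min_fill: float = 0.5,
) -> pd.DataFrame:
    """Assign every face to exactly one quadrat by its projected centroid.

    Returns a DataFrame indexed by face with columns ``quadrat_id`` (-1 for
    faces outside the grid); the attribute ``.attrs['excluded']`` maps
    quadrat_id -> bool for quadrats whose summed projected area is below
    ``min_fill * quadrat_size**2`` (rim quadrats of a non-rectangular site).
    """
    if mesh.n_faces == 0:
        out = pd.DataFrame({"quadrat_id": np.array([], dtype=np.int64)})
        out.attrs["excluded"] = {}
        return out
    uv = plane.to_plane_coords(mesh.face_centroids())
    qid = grid.locate(uv)
    _, proj = _face_areas_and_projections(mesh, plane)
    out = pd.DataFrame({"quadrat_id": qid})
    proj_sum = (
        pd.Series(proj[qid >= 0]).groupby(qid[qid >= 0]).sum()
    )
    threshold = min_fill * grid.quadrat_size**2
    out.attrs["excluded"] = {int(q): bool(a < threshold) for q, a in proj_sum.items()}
    return out


def compute_sr(
    mesh: SurfaceMesh,
    plane: ReferencePlane,
    face_indices: np.ndarray | None = None,
    quadrat_id: int = 0,
    link_size: float = float("nan"),
) -> QuadratRugosity:
    """SR = (sum of face areas) / (sum of projected face areas) over a face set."""
    areas, proj = _face_areas_and_projections(mesh, plane)
    if face_indices is not None:
        areas = areas[np.asarray(face_indices)]
        proj = proj[np.asarray(face_indices)]
    total = float(areas.sum())
    projected = float(proj.sum())
    if projected <= 0.0:
        raise UndefinedStatisticError(
            "projected area is zero (all faces perpendicular to the plane); SR undefined"
        )
    return QuadratRugosity(
        quadrat_id=int(quadrat_id),
        link_size=float(link_size),
        sr=total / projected,
        total_area=total,
        projected_area=projected,
        n_faces=int(len(areas)),
    )


def resample_link_size(hf: HeightField, link_size: float) -> HeightField:
    """Resample a heightfield to a coarser link size by block averaging.

    Output nodes sit on the same origin-anchored lattice with spacing
    ``link_size``; each output node takes the mean of the unmasked input nodes
    nearest to it (bins of width ``link_size`` centred on the output nodes).
    Because a partial edge bin's samples are not centred on its node, the raw
    bin mean is first-order corrected: means are treated as samples at the
    bin's true mean position and linearly interpolated back to the lattice.
    This makes the operation exact for planar fields (tilted sites keep
    SR = 1 at every link size). Output nodes whose bin contains no unmasked
    input are masked; resampling at the native resolution is the identity.
    """
    if link_size < hf.cell_size - 1e-12:
        raise ParameterError(
            f"link_size {link_size} below native resolution {hf.cell_size}"
        )
    if abs(link_size - hf.cell_size) < 1e-12:
        return HeightField(hf.elevations.copy(), hf.origin, hf.cell_size)

    nrow, ncol = hf.shape
    xpos = np.arange(ncol) * hf.cell_size
    ypos = np.arange(nrow) * hf.cell_size
    # nearest-node binning: floor(t + 1/2) avoids np.rint's round-half-even
    xi = np.floor(xpos / link_size + 0.5).astype(np.int64)
    yi = np.floor(ypos / link_size + 0.5).astype(np.int64)
    n_out_c = int(xi.max()) + 1
    n_out_r = int(yi.max()) + 1

    z = hf.elevations
    ok = ~np.isnan(z)
    flat_bins = (yi[:, None] * n_out_c + xi[None, :])[ok]
    sums = np.bincount(flat_bins, weights=z[ok], minlength=n_out_r * n_out_c)
    counts = np.bincount(flat_bins, minlength=n_out_r * n_out_c)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mean = mean.reshape(n_out_r, n_out_c)

    # per-axis mean sample position of each bin (mask-independent, separable)
    xbar = np.bincount(xi, weights=xpos, minlength=n_out_c) / np.maximum(
        np.bincount(xi, minlength=n_out_c), 1
    )
    ybar = np.bincount(yi, weights=ypos, minlength=n_out_r) / np.maximum(
        np.bincount(yi, minlength=n_out_r), 1
    )
    if n_out_r >= 2 and n_out_c >= 2:
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (ybar, xbar), mean, method="linear", bounds_error=False, fill_value=None
        )
        gy, gx = np.meshgrid(
            np.arange(n_out_r) * link_size, np.arange(n_out_c) * link_size,
            indexing="ij",
        )
        corrected = interp(np.column_stack([gy.ravel(), gx.ravel()])).reshape(mean.shape)
        # keep holes masked; fall back to the raw mean next to holes
        corrected = np.where(np.isnan(corrected) & ~np.isnan(mean), mean, corrected)
        corrected[np.isnan(mean)] = np.nan
        mean = corrected
    return HeightField(mean, hf.origin, link_size)


def multiscale_sr(
    hf: HeightField,
    plane: ReferencePlane | None = None,
    grid: QuadratGrid | None = None,
    link_sizes=DEFAULT_LINK_SIZES,
    quadrat_size: float = 2.0,
    min_fill: float = 0.5,
    include_excluded: bool = False,
) -> pd.DataFrame:
    """SR per (quadrat, link size) over a heightfield site.

    The reference plane is fit once to the full-resolution surface (unless
    given) and reused at every link size, as is the quadrat grid, so SR values
    are comparable across scales. Returns a tidy DataFrame with columns
    quadrat_id, row, col, link_size_m, SR, total_area_m2, projected_area_m2,
    n_faces, excluded.
    """
    link_sizes = sorted(float(s) for s in link_sizes)
    base_mesh = heightfield_to_mesh(hf)
    if plane is None:
        plane = fit_reference_plane(base_mesh)
    if grid is None:
        uv = plane.to_plane_coords(base_mesh.vertices)
        grid = QuadratGrid.from_extent(uv.min(axis=0), uv.max(axis=0), quadrat_size)

    records = []
    for link in link_sizes:
        mesh = base_mesh if abs(link - hf.cell_size) < 1e-12 else heightfield_to_mesh(
            resample_link_size(hf, link)
        )
        part = partition_quadrats(mesh, plane, grid, min_fill=min_fill)
        excluded = part.attrs["excluded"]
        qids = part["quadrat_id"].to_numpy()
        for qid in np.unique(qids[qids >= 0]):
            faces = np.nonzero(qids == qid)[0]
            qr = compute_sr(mesh, plane, faces, quadrat_id=qid, link_size=link)
            row, col = grid.rowcol(int(qid))
            records.append(
                {
                    "quadrat_id": int(qid),
                    "row": row,
                    "col": col,
                    "link_size_m": link,
                    "SR": qr.sr,
                    "total_area_m2": qr.total_area,
                    "projected_area_m2": qr.projected_area,
                    "n_faces": qr.n_faces,
                    "excluded": excluded.get(int(qid), True),
                }
            )
    out = pd.DataFrame.from_records(
        records,
        columns=[
            "quadrat_id", "row", "col", "link_size_m", "SR",
            "total_area_m2", "projected_area_m2", "n_faces", "excluded",
        ],
    )
    if not include_excluded and len(out):
        # a quadrat flagged at any scale is dropped at all scales
        bad = set(out.loc[out["excluded"], "quadrat_id"])
        out = out[~out["quadrat_id"].isin(bad)].reset_index(drop=True)
    return out
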