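"""Terrain representations: triangle meshes, gridded heightfields, rigid transforms.

Two interchangeable forms of a benthic terrain model are supported:

* :class:`SurfaceMesh` — an arbitrary triangle mesh (the native output of a
  photogrammetric reconstruction), with per-face areas used by the rugosity
  index.
* :class:`HeightField` — a regular elevation grid (one z sample per node),
  which is the form the synthetic generator produces and the form on which
  link-size resampling is defined. ``NaN`` elevations mark masked (absent)
  nodes; holes propagate to the mesh.

File formats are deliberately plain-text: ASCII PLY / OBJ for meshes and the
ESRI ASCII grid for heightfields.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import (
    EmptySurfaceError,
    InvalidTransformError,
    MeshFormatError,
    ParameterError,
)

__all__ = [
    "SurfaceMesh",
    "HeightField",
    "RigidTransform",
    "heightfield_to_mesh",
    "apply_transform",
    "read_mesh",
    "write_mesh",
    "read_esri_ascii",
    "write_esri_ascii",
]


@dataclass
class SurfaceMesh:
    """A triangle mesh in metres: ``vertices`` (n, 3) float, ``faces`` (m, 3) int.

    Face indices are 0-based internally; 1-based conventions (OBJ) are
    converted at the file boundary.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise ParameterError("mesh vertices must be finite")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ParameterError("face index out of range")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """Face corner coordinates, shape (m, 3, 3)."""
        return self.vertices[self.faces]

    def face_normals_unnormalized(self) -> np.ndarray:
        """Per-face cross products; |.|/2 is the face area."""
        tri = self.triangles()
        return np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals_unnormalized(), axis=1)

    def face_centroids(self) -> np.ndarray:
        return self.triangles().mean(axis=1)

    def total_area(self) -> float:
        return float(self.face_areas().sum())


@dataclass
class HeightField:
    """A regular grid of elevations (metres).

    ``elevations[i, j]`` is the z sample at node
    ``(origin[0] + j * cell_size, origin[1] + i * cell_size)``; ``NaN`` marks a
    masked node.
    """

    elevations: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 1.0

    def __post_init__(self) -> None:
        self.elevations = np.asarray(self.elevations, dtype=float)
        if self.elevations.ndim != 2:
            raise ParameterError("elevations must be a 2D grid")
        if not self.cell_size > 0:
            raise ParameterError("cell_size must be positive")
        vals = self.elevations[~np.isnan(self.elevations)]
        if vals.size and not np.all(np.isfinite(vals)):
            raise ParameterError("unmasked elevations must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevations.shape

    @property
    def mask(self) -> np.ndarray:
        """True where the node is masked (absent)."""
        return np.isnan(self.elevations)

    def node_x(self) -> np.ndarray:
        return self.origin[0] + self.cell_size * np.arange(self.shape[1])

    def node_y(self) -> np.ndarray:
        return self.origin[1] + self.cell_size * np.arange(self.shape[0])


@dataclass
class RigidTransform:
    """A proper rigid transform: x -> rotation @ x + translation."""

    rotation: np.ndarray = field(
        default_factory=lambda: np.eye(3)
    )
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        r = self.rotation
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise InvalidTransformError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-8):
            raise InvalidTransformError("rotation determinant must be +1 (no reflection)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    @staticmethod
    def about_z(angle_rad: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        return RigidTransform(rot, np.asarray(translation, dtype=float))


def heightfield_to_mesh(hf: HeightField) -> SurfaceMesh:
    """Triangulate a heightfield: each fully-unmasked 2x2 node block (one grid
    cell) contributes two triangles split along the same diagonal everywhere.

    Masked nodes leave holes; no face spans a hole. Raises
    :class:`EmptySurfaceError` when no complete cell exists.
    """
    z = hf.elevations
    nrow, ncol = z.shape
    if nrow < 2 or ncol < 2:
        raise EmptySurfaceError("heightfield smaller than one cell")
    ok = ~np.isnan(z)
    cell_ok = ok[:-1, :-1] & ok[:-1, 1:] & ok[1:, :-1] & ok[1:, 1:]
    if not cell_ok.any():
        raise EmptySurfaceError("all heightfield cells are masked")

    xs = hf.node_x()
    ys = hf.node_y()
    xx, yy = np.meshgrid(xs, ys)
    vertices = np.column_stack([xx.ravel(), yy.ravel(), z.ravel()])
    vertices[np.isnan(vertices[:, 2]), 2] = 0.0  # never referenced by a face

    idx = np.arange(nrow * ncol).reshape(nrow, ncol)
    i, j = np.nonzero(cell_ok)
    v00 = idx[i, j]
    v01 = idx[i, j + 1]
    v10 = idx[i + 1, j]
    v11 = idx[i + 1, j + 1]
    # diagonal v00 -- v11 in every cell (deterministic choice)
    tri_a = np.column_stack([v00, v01, v11])
    tri_b = np.column_stack([v00, v11, v10])
    faces = np.vstack([tri_a, tri_b])
    return SurfaceMesh(vertices, faces)


def apply_transform(mesh: SurfaceMesh, t: RigidTransform) -> SurfaceMesh:
    """Apply a rigid transform to every vertex; connectivity is untouched.

    Face areas (and so rugosity, once the reference plane is refit) are
    invariant.
    """
    return SurfaceMesh(t.apply(mesh.vertices), mesh.faces.copy())


# --------------------------------------------------------------------------
# mesh file I/O (ASCII PLY / OBJ, triangles only)

_FORMATS = {"ply", "obj"}


def _check_format(fmt: str) -> str:
    fmt = fmt.lower().lstrip(".")
    if fmt not in _FORMATS:
        raise ParameterError(f"unsupported mesh format {fmt!r}; use 'ply' or 'obj'")
    return fmt


def _prescan(path: Path, fmt: str) -> None:
    """Reject quads / unsupported dialects with a line-numbered error, and warn
    about extra PLY vertex properties (they are read past, not interpreted)."""
    text = path.read_text(errors="replace")
    if fmt == "obj":
        for lineno, line in enumerate(text.splitlines(), start=1):
            if line.startswith("f "):
                n = len(line.split()) - 1
                if n != 3:
                    raise MeshFormatError(
                        f"{path}:{lineno}: face with {n} vertices (triangles only)"
                    )
    else:  # ply
        header, _, _ = text.partition("end_header")
        if "end_header" not in text:
            raise MeshFormatError(f"{path}:1: missing PLY end_header")
        if "format ascii" not in header:
            raise MeshFormatError(f"{path}:2: only ASCII PLY is supported")
        props, in_vertex = [], False
        for line in header.splitlines():
            tok = line.split()
            if tok[:1] == ["element"]:
                in_vertex = tok[1] == "vertex"
            elif tok[:1] == ["property"] and in_vertex:
                props.append(tok[-1])
        extra = [p for p in props if p not in ("x", "y", "z")]
        if extra:
            warnings.warn(
                f"{path}: ignoring extra vertex properties {extra}", stacklevel=3
            )


def read_mesh(path, fmt: str | None = None) -> SurfaceMesh:
    """Read an ASCII PLY or OBJ triangle mesh, preserving vertex/face order."""
    path = Path(path)
    fmt = _check_format(fmt or path.suffix)
    _prescan(path, fmt)
    try:
        tm = trimesh.load_mesh(io.BytesIO(path.read_bytes()), file_type=fmt, process=False)
    except Exception as exc:  # trimesh raises a mix of types
        raise MeshFormatError(f"cannot parse {path}: {exc}") from exc
    if tm.faces.shape[1] != 3:
        raise MeshFormatError(f"{path}: non-triangular faces")
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def write_mesh(mesh: SurfaceMesh, path, fmt: str | None = None) -> None:
    """Write an ASCII PLY or OBJ file; round-trips exactly through read_mesh."""
    path = Path(path)
    fmt = _check_format(fmt or path.suffix)
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    if fmt == "ply":
        data = tm.export(file_type="ply", encoding="ascii")
        if isinstance(data, bytes):
            data = data.decode()
    else:
        data = tm.export(file_type="obj")
    path.write_text(data)


# --------------------------------------------------------------------------
# ESRI ASCII grid I/O

def read_esri_ascii(path) -> HeightField:
    """Read an ESRI ASCII grid (ncols/nrows/xllcorner/yllcorner/cellsize header).

    Row 0 of the file is the northern-most row; internally row 0 is the
    southern-most (y increases with row index), so rows are flipped on read.
    """
    path = Path(path)
    header: dict[str, float] = {}
    lines = path.read_text().splitlines()
    ix = 0
    for ix, line in enumerate(lines):
        tok = line.split()
        if len(tok) == 2 and tok[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[tok[0].lower()] = float(tok[1])
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise MeshFormatError(f"{path}: missing ESRI grid header field {key!r}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = np.loadtxt(io.StringIO("\n".join(lines[ix:])), dtype=float, ndmin=2)
    if data.shape != (nrows, ncols):
        raise MeshFormatError(
            f"{path}: grid body shape {data.shape} != header ({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value")
    if nodata is not None:
        data[data == nodata] = np.nan
    return HeightField(
        np.flipud(data),
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
    )


def write_esri_ascii(hf: HeightField, path, nodata: float = -9999.0) -> None:
    path = Path(path)
    z = np.flipud(hf.elevations)
    z = np.where(np.isnan(z), nodata, z)
    nrows, ncols = z.shape
    with path.open("w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {hf.origin[0]!r}\n")
        fh.write(f"yllcorner {hf.origin[1]!r}\n")
        fh.write(f"cellsize {hf.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        np.savetxt(fh, z, fmt="%.10g")
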