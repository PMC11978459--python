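"""Reading, writing, conditioning and measuring triangulated muscle surfaces.

All coordinates are millimetres in a right-handed frame. A specimen is one
closed triangulated surface of one muscle; meshes are cleaned on read
(duplicate vertices merged, degenerate faces dropped) so that downstream
registration and distance computations never see zero-area geometry.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

log = logging.getLogger(__name__)

#: merge tolerance for duplicate vertices, mm
MERGE_TOL = 1e-9

_FORMATS = ("ply", "stl", "obj", "vtk")
_SCALAR_FORMATS = ("ply", "vtk")


@dataclass
class SurfaceMesh:
    """A triangulated surface of one muscle specimen.

    Attributes
    ----------
    specimen_id : str
        Identifier linking the surface to its covariate row.
    vertices : (n, 3) float ndarray
        Vertex coordinates in mm.
    faces : (m, 3) int ndarray
        Vertex-index triplets; consistent outward winding is assumed for
        volume computation.
    side : {"left", "right", "unknown"}
        Anatomical side; flipped by :func:`reflect_sagittal`.
    """

    specimen_id: str
    vertices: np.ndarray
    faces: np.ndarray
    side: str = "unknown"

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array of triangles")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("vertex coordinates must be finite")
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise ValueError("face indices out of range")
        if self.side not in ("left", "right", "unknown"):
            raise ValueError(f"invalid side {self.side!r}")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.specimen_id, self.vertices.copy(),
                           self.faces.copy(), self.side)

    def with_vertices(self, vertices: np.ndarray) -> "SurfaceMesh":
        """Same connectivity and identity, new coordinates."""
        return SurfaceMesh(self.specimen_id, np.asarray(vertices, float),
                           self.faces.copy(), self.side)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)


def _face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a = vertices[faces[:, 1]] - vertices[faces[:, 0]]
    b = vertices[faces[:, 2]] - vertices[faces[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def clean_mesh(mesh: SurfaceMesh, merge_tol: float = MERGE_TOL) -> SurfaceMesh:
    """Merge duplicate vertices, drop degenerate faces and unreferenced vertices.

    Vertex order is preserved for the surviving (first-occurrence) vertices;
    face order is preserved for surviving faces.
    """
    v, f = mesh.vertices, mesh.faces
    # merge duplicates: quantize to merge_tol grid, keep first occurrence
    key = np.round(v / merge_tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True,
                                  return_inverse=True)
    order = np.argsort(first)           # preserve original ordering
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    v = v[np.sort(first)]
    f = rank[inverse][f]
    # drop faces with repeated vertices or (numerically) zero area
    distinct = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
    f = f[distinct]
    areas = _face_areas(v, f)
    f = f[areas > 1e-14]
    # drop unreferenced vertices
    used = np.zeros(len(v), dtype=bool)
    used[f.ravel()] = True
    remap = np.cumsum(used) - 1
    v = v[used]
    f = remap[f]
    out = SurfaceMesh(mesh.specimen_id, v, f, mesh.side)
    if out.n_vertices < 4 or out.n_faces < 4:
        raise ValueError(
            f"{mesh.specimen_id}: fewer than 4 vertices/faces after cleaning")
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in _FORMATS:
            raise ValueError(f"unsupported format {fmt!r}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix not in _FORMATS:
        raise ValueError(f"cannot infer mesh format from {path.name!r}")
    return suffix


def _triangulate_polys(polys: list[list[int]]) -> np.ndarray:
    """Fan-split polygons into triangles; warn when non-triangles appear."""
    tris = []
    split = False
    for p in polys:
        if len(p) < 3:
            continue
        if len(p) > 3:
            split = True
        for i in range(1, len(p) - 1):
            tris.append((p[0], p[i], p[i + 1]))
    if split:
        warnings.warn("non-triangular faces fan-triangulated", stacklevel=3)
    return np.asarray(tris, dtype=np.int64).reshape(-1, 3)


def _read_vtk_polydata(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Minimal legacy-VTK ASCII POLYDATA reader (points, polygons, scalars)."""
    tokens: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 4 or "vtk" not in lines[0].lower():
        raise ValueError(f"{path}: not a legacy VTK file")
    if lines[2].strip().upper() != "ASCII":
        raise ValueError(f"{path}: only ASCII legacy VTK is supported")
    for ln in lines[3:]:
        tokens.extend(ln.split())
    pos = 0

    def expect(word: str) -> None:
        nonlocal pos
        if tokens[pos].upper() != word:
            raise ValueError(f"{path}: expected {word}, got {tokens[pos]!r}")
        pos += 1

    expect("DATASET")
    expect("POLYDATA")
    expect("POINTS")
    n = int(tokens[pos]); pos += 2  # skip dtype
    pts = np.array(tokens[pos:pos + 3 * n], dtype=np.float64).reshape(n, 3)
    pos += 3 * n
    polys: list[list[int]] = []
    scalars = None
    while pos < len(tokens):
        word = tokens[pos].upper()
        if word == "POLYGONS":
            m = int(tokens[pos + 1])
            pos += 3
            for _ in range(m):
                k = int(tokens[pos])
                polys.append([int(t) for t in tokens[pos + 1:pos + 1 + k]])
                pos += 1 + k
        elif word == "POINT_DATA":
            pos += 2
        elif word == "SCALARS":
            pos += 4  # SCALARS name dtype ncomp
            if tokens[pos].upper() == "LOOKUP_TABLE":
                pos += 2
            scalars = np.array(tokens[pos:pos + n], dtype=np.float64)
            pos += n
        else:
            pos += 1
    faces = _triangulate_polys(polys)
    return pts, faces, scalars


def _write_vtk_polydata(path: Path, mesh: SurfaceMesh,
                        scalars: np.ndarray | None) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{mesh.specimen_id}\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        if scalars is not None:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            fh.write("SCALARS variation double 1\nLOOKUP_TABLE default\n")
            for s in scalars:
                fh.write(f"{s:.17g}\n")


def _write_ply_with_quality(path: Path, mesh: SurfaceMesh,
                            scalars: np.ndarray) -> None:
    """ASCII PLY with a per-vertex float `quality` property (float32)."""
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property float quality\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        q = scalars.astype(np.float32)
        for v, s in zip(mesh.vertices, q):
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g} {s:.9g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_mesh(path: str | Path, fmt: str = "auto",
              specimen_id: str | None = None, side: str = "unknown",
              clean: bool = True) -> SurfaceMesh:
    """Read a surface mesh (PLY, STL, OBJ or legacy VTK polydata).

    The mesh is cleaned: duplicate vertices within ``1e-9`` mm are merged,
    degenerate faces dropped, unreferenced vertices removed. Non-triangular
    faces are fan-triangulated with a warning.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"mesh file not found: {path}")
    fmt = _detect_format(path, fmt)
    sid = specimen_id if specimen_id is not None else path.stem
    if fmt == "vtk":
        verts, faces, _ = _read_vtk_polydata(path)
    else:
        try:
            tm = trimesh.load(str(path), file_type=fmt, process=False,
                              force="mesh")
        except Exception as exc:
            raise IOError(f"cannot parse {path} as {fmt}: {exc}") from exc
        verts = np.asarray(tm.vertices, dtype=np.float64)
        faces = np.asarray(tm.faces, dtype=np.int64)
    mesh = SurfaceMesh(sid, verts, faces, side)
    return clean_mesh(mesh) if clean else mesh


def read_scalars(path: str | Path, fmt: str = "auto") -> np.ndarray | None:
    """Read the per-vertex scalar field written by :func:`write_mesh`, if any."""
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt == "vtk":
        return _read_vtk_polydata(path)[2]
    if fmt == "ply":
        with open(path) as fh:
            header, props = [], []
            n_vertex = 0
            for line in fh:
                header.append(line.strip())
                parts = line.split()
                if parts[:2] == ["element", "vertex"]:
                    n_vertex = int(parts[2])
                if line.strip() == "end_header":
                    break
            in_vertex = False
            for h in header:
                p = h.split()
                if p[:1] == ["element"]:
                    in_vertex = p[1] == "vertex"
                elif in_vertex and p[:1] == ["property"]:
                    props.append(p[-1])
            if "quality" not in props:
                return None
            if "format ascii 1.0" not in header:
                raise ValueError("scalar read supported for ASCII PLY only")
            col = props.index("quality")
            vals = [float(next(fh).split()[col]) for _ in range(n_vertex)]
        return np.asarray(vals)
    raise ValueError(f"format {fmt!r} does not carry per-vertex scalars")


def write_mesh(mesh: SurfaceMesh, path: str | Path, fmt: str = "auto",
               scalar_field: np.ndarray | None = None) -> None:
    """Write a mesh; optionally attach a per-vertex scalar field (PLY/VTK).

    VTK scalars round-trip bit-exactly (written as 17-significant-digit
    doubles); PLY scalars are stored at float32 precision.
    """
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if scalar_field is not None:
        scalar_field = np.asarray(scalar_field, dtype=np.float64)
        if scalar_field.shape != (mesh.n_vertices,):
            raise ValueError("scalar_field length must equal vertex count")
        if fmt not in _SCALAR_FORMATS:
            raise ValueError(f"format {fmt!r} cannot carry per-vertex scalars")
    if fmt == "vtk":
        _write_vtk_polydata(path, mesh, scalar_field)
    elif fmt == "ply" and scalar_field is not None:
        _write_ply_with_quality(path, mesh, scalar_field)
    else:
        mesh.to_trimesh().export(str(path), file_type=fmt)


# ---------------------------------------------------------------------------
# Conditioning
# ---------------------------------------------------------------------------

def reflect_sagittal(mesh: SurfaceMesh) -> SurfaceMesh:
    """Mirror the mesh about its own sagittal plane (x = centroid x).

    Left-sided specimens are reflected so all muscles share one anatomical
    frame. Face winding is reversed to keep the outward orientation, and the
    side flag is flipped.
    """
    cx = mesh.vertices[:, 0].mean()
    v = mesh.vertices.copy()
    v[:, 0] = 2.0 * cx - v[:, 0]
    f = mesh.faces[:, [0, 2, 1]].copy()
    side = {"left": "right", "right": "left"}.get(mesh.side, "unknown")
    return SurfaceMesh(mesh.specimen_id, v, f, side)


def _vertex_adjacency(mesh: SurfaceMesh):
    """Row-normalized vertex adjacency (uniform umbrella weights), sparse."""
    from scipy import sparse

    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 1], f[:, 2], f[:, 2], f[:, 0]])
    cols = np.concatenate([f[:, 1], f[:, 0], f[:, 2], f[:, 1], f[:, 0], f[:, 2]])
    n = mesh.n_vertices
    a = sparse.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    a = (a.tocsr() > 0).astype(np.float64)
    deg = np.asarray(a.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    return sparse.diags(1.0 / deg) @ a


def mean_edge_length(mesh: SurfaceMesh) -> float:
    f, v = mesh.faces, mesh.vertices
    e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    return float(np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1).mean())


def smooth(mesh: SurfaceMesh, sigma_mm: float = 2.0,
           method: str = "taubin", lam: float = 0.5,
           mu: float = -0.5) -> SurfaceMesh:
    """Smooth vertex positions with uniform-weight umbrella operators.

    The smoothing strength is parametrized by ``sigma_mm``, the approximate
    spatial scale of features to suppress: the iteration count is
    ``round((sigma_mm / mean_edge_length)**2)`` (diffusion distance scales
    with the square root of the step count). ``taubin`` (the default)
    alternates a shrink pass of weight ``lam`` with an inflate pass of
    weight ``mu``; the balanced pair (0.5, -0.5) keeps the enclosed volume
    of a closed surface within a fraction of a per cent at working
    resolutions (an inflate weight of larger magnitude, the other common
    choice, slowly inflates the lowest-frequency mode when many iterations
    are run). ``laplacian`` is a pure shrinking flow.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    if method not in ("taubin", "laplacian"):
        raise ValueError(f"unknown smoothing method {method!r}")
    from scipy.sparse import csgraph

    adj = _vertex_adjacency(mesh)
    n_comp = csgraph.connected_components(adj, directed=False,
                                          return_labels=False)
    if n_comp > 1:
        warnings.warn(f"{mesh.specimen_id}: {n_comp} disconnected components "
                      "smoothed independently")
    n_iter = max(1, round((sigma_mm / mean_edge_length(mesh)) ** 2))
    v = mesh.vertices.copy()
    for _ in range(n_iter):
        v = v + lam * (adj @ v - v)
        if method == "taubin":
            v = v + mu * (adj @ v - v)
    return mesh.with_vertices(v)


# ---------------------------------------------------------------------------
# Measures
# ---------------------------------------------------------------------------

def open_edge_count(mesh: SurfaceMesh) -> int:
    """Number of edges not shared by exactly two faces."""
    f = mesh.faces
    e = np.sort(np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1)
    _, counts = np.unique(e, axis=0, return_counts=True)
    return int(np.sum(counts != 2))


def enclosed_volume(mesh: SurfaceMesh) -> float:
    """Volume enclosed by a watertight surface, mm^3 (divergence theorem).

    The signed volume is computed from the face winding; the absolute value
    is returned, with a warning when the winding pointed inward.
    """
    n_open = open_edge_count(mesh)
    if n_open:
        raise ValueError(
            f"{mesh.specimen_id}: mesh is not watertight ({n_open} open edges)")
    v, f = mesh.vertices, mesh.faces
    signed = np.einsum("ij,ij->i", v[f[:, 0]],
                       np.cross(v[f[:, 1]], v[f[:, 2]])).sum() / 6.0
    if signed < 0:
        log.warning("%s: inward-oriented faces (signed volume negative)",
                    mesh.specimen_id)
    return abs(float(signed))


def rms_size(mesh: SurfaceMesh) -> float:
    """Root-mean-square vertex distance to the centroid.

    The sampling-density-invariant size measure: equals
    ``centroid_size / sqrt(n_vertices)``. Used for size normalization of
    landmark-free meshes, where vertex counts differ by specimen and the
    plain centroid size would conflate size with sampling density.
    """
    c = mesh.vertices.mean(axis=0)
    ms = float(np.mean(np.sum((mesh.vertices - c) ** 2, axis=1)))
    if ms == 0.0:
        raise ValueError("degenerate mesh: all vertices identical")
    return float(np.sqrt(ms))


def centroid_size(mesh: SurfaceMesh) -> float:
    """Square root of summed squared vertex distances to the vertex centroid.

    The standard geometric-morphometrics size measure used for optional
    size normalization before alignment.
    """
    c = mesh.vertices.mean(axis=0)
    ss = float(np.sum((mesh.vertices - c) ** 2))
    if ss == 0.0:
        raise ValueError("degenerate mesh: all vertices identical")
    return float(np.sqrt(ss))
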