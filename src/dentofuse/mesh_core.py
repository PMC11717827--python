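"""Triangle-mesh data model, region labels, and STL/PLY I/O.

Every surface the fusion workflows touch — intra-oral scans, facial
stereophotogrammetric captures, CBCT-derived skin and teeth surfaces,
tracer scans — is represented as a :class:`TriMesh`: vertices and faces in
millimetres plus named vertex regions ("forehead", "anterior_teeth", ...)
that delimit the matching areas used by region-restricted registration.

STL cannot carry labels, and a single integer-per-vertex PLY property
cannot represent overlapping regions, so region membership always travels
in a JSON sidecar ``<mesh>.regions.json`` holding explicit vertex-index
lists.  PLY files additionally get an integer ``region_id`` vertex
property (first-listed region wins for a multiply-labeled vertex) so that
third-party viewers can colour the regions; on read the sidecar, when
present, is authoritative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

__all__ = ["TriMesh", "read_mesh", "write_mesh", "extract_region", "REGION_NAMES"]

#: Region labels with defined semantics in the fusion workflows.  Meshes may
#: carry additional ad-hoc labels; workflows only ever reference these.
REGION_NAMES = (
    "forehead",
    "zygoma",
    "cheeks",
    "lips",
    "anterior_teeth",
    "occlusal",
    "maxilla",
    "tracer_body",
    "impression",
)

_WELD_TOL = 1e-6  # mm; STL duplicates vertices per facet


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be parsed or has an unknown format."""


class RegionLookupError(KeyError):
    """Raised when a referenced region is missing or empty."""


@dataclass
class TriMesh:
    """Triangle mesh in millimetres with optional named vertex regions.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices
    regions : dict mapping region name to a 1-D array of vertex indices
    """

    vertices: np.ndarray
    faces: np.ndarray
    regions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.isfinite(self.vertices).all():
            raise ValueError("vertex coordinates must be finite")
        n = len(self.vertices)
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= n):
            raise ValueError("face indices out of vertex range")
        self.regions = {
            k: np.unique(np.asarray(v, dtype=np.int64)) for k, v in self.regions.items()
        }
        for name, idx in self.regions.items():
            if len(idx) and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(f"region {name!r} indexes outside vertex range")
        self._drop_degenerate_faces()

    def _drop_degenerate_faces(self) -> None:
        if not len(self.faces):
            return
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        area2 = np.linalg.norm(np.cross(b - a, c - a), axis=1)
        keep = area2 > 1e-18
        if not keep.all():
            self.faces = self.faces[keep]

    # -- convenience ------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def region_vertices(self, name: str) -> np.ndarray:
        """Coordinates of the vertices in region *name*."""
        return self.vertices[self.region_index(name)]

    def region_index(self, name: str) -> np.ndarray:
        if name not in self.regions:
            raise RegionLookupError(f"region {name!r} not defined on mesh")
        idx = self.regions[name]
        if len(idx) == 0:
            raise RegionLookupError(f"region {name!r} is empty")
        return idx

    def as_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    def transformed(self, matrix: np.ndarray) -> "TriMesh":
        """Return a copy with vertices mapped by a 4x4 homogeneous matrix."""
        m = np.asarray(matrix, dtype=np.float64)
        v = self.vertices @ m[:3, :3].T + m[:3, 3]
        return TriMesh(v, self.faces.copy(), {k: i.copy() for k, i in self.regions.items()})

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(),
            self.faces.copy(),
            {k: v.copy() for k, v in self.regions.items()},
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".regions.json")


def _weld(vertices: np.ndarray, faces: np.ndarray, tol: float = _WELD_TOL):
    """Merge vertices closer than *tol*; used on STL import."""
    if len(vertices) == 0:
        return vertices, faces
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    return vertices[first], inverse[faces]


def read_mesh(path: str | Path, format: str | None = None) -> TriMesh:
    """Read an STL (ASCII or binary) or PLY file into a :class:`TriMesh`.

    STL vertices are welded at 1e-6 mm (the format stores each facet's
    corners independently).  Regions are restored from the
    ``<mesh>.regions.json`` sidecar when present, else — for PLY — from an
    integer ``region_id`` vertex property.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("stl", "ply"):
        raise MeshFormatError(f"unsupported mesh format {fmt!r} (want stl or ply)")
    try:
        raw = _trimesh.load(str(path), file_type=fmt, process=False)
    except Exception as exc:  # pragma: no cover - message path
        size = path.stat().st_size
        raise MeshFormatError(
            f"cannot parse {path} as {fmt} (file is {size} bytes): {exc}"
        ) from exc
    if not isinstance(raw, _trimesh.Trimesh):
        raise MeshFormatError(f"{path} did not parse to a single triangle mesh")

    vertices = np.asarray(raw.vertices, dtype=np.float64)
    faces = np.asarray(raw.faces, dtype=np.int64)
    regions: dict[str, np.ndarray] = {}

    if fmt == "stl":
        vertices, faces = _weld(vertices, faces)

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        regions = {k: np.asarray(v, dtype=np.int64) for k, v in meta.get("regions", {}).items()}
    elif fmt == "ply":
        regions = _regions_from_ply_property(raw)
    return TriMesh(vertices, faces, regions)


def _regions_from_ply_property(raw: _trimesh.Trimesh) -> dict[str, np.ndarray]:
    ply = raw.metadata.get("_ply_raw", {})
    vdata = ply.get("vertex", {}).get("data")
    if vdata is None:
        return {}
    try:
        rid = np.asarray(vdata["region_id"], dtype=np.int64).ravel()
    except (KeyError, ValueError, IndexError):
        return {}
    names = raw.metadata.get("region_names", {})
    out: dict[str, np.ndarray] = {}
    for rid_val in np.unique(rid):
        if rid_val < 0:
            continue
        name = names.get(int(rid_val), f"region_{rid_val}")
        out[name] = np.flatnonzero(rid == rid_val)
    return out


def write_mesh(mesh: TriMesh, path: str | Path, format: str | None = None) -> None:
    """Write *mesh* as STL (binary) or PLY, with a region sidecar if labeled.

    Vertex order is preserved for PLY; STL stores facets independently so a
    subsequent read welds them back (coordinates survive to 1e-6 mm).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("stl", "ply"):
        raise MeshFormatError(f"unsupported mesh format {fmt!r} (want stl or ply)")
    tm = mesh.as_trimesh()
    if fmt == "ply" and mesh.regions:
        rid = np.full(mesh.n_vertices, -1, dtype=np.int32)
        # reversed so the first-listed region wins on overlap
        for i, name in reversed(list(enumerate(mesh.regions))):
            rid[mesh.regions[name]] = i
        tm.vertex_attributes["region_id"] = rid
    try:
        tm.export(str(path), file_type=fmt)
    except OSError as exc:
        raise OSError(f"cannot write mesh to {path}: {exc}") from exc

    sidecar = _sidecar_path(path)
    if mesh.regions:
        regions = mesh.regions
        if fmt == "stl":
            # STL stores facets independently in float32; a reader welds
            # them back into sorted-key order.  Precompute that indexing so
            # the sidecar's vertex lists match what read_mesh reconstructs.
            v32 = mesh.vertices.astype(np.float32).astype(np.float64)
            key = np.round(v32 / _WELD_TOL).astype(np.int64)
            _, inverse = np.unique(key, axis=0, return_inverse=True)
            regions = {k: np.unique(inverse[v]) for k, v in regions.items()}
        meta = {
            "id_to_name": {i: name for i, name in enumerate(regions)},
            "regions": {k: v.tolist() for k, v in regions.items()},
        }
        sidecar.write_text(json.dumps(meta))
    elif sidecar.exists():
        sidecar.unlink()


def extract_region(mesh: TriMesh, name: str) -> TriMesh:
    """Sub-mesh of all faces whose three vertices lie in region *name*.

    The returned mesh keeps the parent's labels restricted to the surviving
    vertices, and records the re-indexing map on its ``parent_index``
    attribute (new position -> parent vertex index).
    """
    idx = mesh.region_index(name)
    member = np.zeros(mesh.n_vertices, dtype=bool)
    member[idx] = True
    face_keep = member[mesh.faces].all(axis=1)
    faces = mesh.faces[face_keep]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    regions = {}
    for rname, ridx in mesh.regions.items():
        kept = remap[ridx]
        kept = kept[kept >= 0]
        if len(kept):
            regions[rname] = kept
    sub = TriMesh(mesh.vertices[used], remap[faces], regions)
    sub.parent_index = used
    return sub
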