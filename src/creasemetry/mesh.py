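"""Triangulated surface meshes in millimetre coordinates.

A :class:`SurfaceMesh` is the common currency between the segmentation
stage (which produces one from a binary volume) and the relief-enhancement
stage (which crops and detrends it).  Vertices are stored as an ``(n, 3)``
float array in mm; faces as an ``(m, 3)`` integer array of vertex indices.
``polarity`` records whether the surface is the scanned clay surface
(``actual_surface``) or its negation (``reverse_cast``) — an impression is
the negative cast of the object that made it, so crease analysis is done
on the reversed relief.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

ACTUAL_SURFACE = "actual_surface"
REVERSE_CAST = "reverse_cast"


@dataclass
class SurfaceMesh:
    vertices: np.ndarray  # (n, 3) float64, mm
    faces: np.ndarray  # (m, 3) int
    polarity: str = ACTUAL_SURFACE

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")
        if len(self.faces) < 1:
            raise ValueError("mesh must contain at least one triangle")
        if not np.isfinite(self.vertices).all():
            raise ValueError("mesh vertices contain non-finite coordinates")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """Per-face vertex coordinates, shape (m, 3, 3)."""
        return self.vertices[self.faces]

    def translated(self, offset) -> "SurfaceMesh":
        return replace(self, vertices=self.vertices + np.asarray(offset, float))

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )


def mesh_area(mesh: SurfaceMesh) -> float:
    """Total surface area in mm²: the sum of individual triangle areas.

    Degenerate (zero-area) triangles contribute nothing; a warning is
    emitted so silent mesh defects do not go unnoticed.
    """
    tri = mesh.triangles()
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    n_degenerate = int(np.count_nonzero(areas == 0.0))
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} degenerate zero-area triangle(s) ignored",
            stacklevel=2,
        )
    return float(areas.sum())


def vertex_components(mesh: SurfaceMesh) -> np.ndarray:
    """Connected-component label per vertex (edge connectivity)."""
    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    data = np.ones(len(rows), dtype=np.int8)
    graph = coo_matrix((data, (rows, cols)), shape=(mesh.n_vertices,) * 2)
    _, labels = connected_components(graph, directed=False)
    return labels


def largest_component(mesh: SurfaceMesh) -> SurfaceMesh:
    """Keep only the largest connected component (by triangle count)."""
    labels = vertex_components(mesh)
    face_labels = labels[mesh.faces[:, 0]]
    counts = np.bincount(face_labels)
    keep = face_labels == counts.argmax()
    return subset_faces(mesh, keep)


def subset_faces(mesh: SurfaceMesh, face_mask: np.ndarray) -> SurfaceMesh:
    """Sub-mesh of the faces where ``face_mask`` is true; drops unused vertices."""
    faces = mesh.faces[face_mask]
    if len(faces) == 0:
        raise ValueError("face selection is empty")
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return SurfaceMesh(
        vertices=mesh.vertices[used], faces=remap[faces], polarity=mesh.polarity
    )


def write_obj(mesh: SurfaceMesh, path) -> None:
    """Write an ASCII Wavefront OBJ (``v``/``f`` records, 1-based indices)."""
    with open(path, "w") as fh:
        fh.write("# creasemetry surface mesh (mm)\n")
        fh.write(f"# polarity: {mesh.polarity}\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces + 1:
            fh.write(f"f {f[0]} {f[1]} {f[2]}\n")


def read_obj(path) -> SurfaceMesh:
    polarity = ACTUAL_SURFACE
    tm = trimesh.load(path, file_type="obj", process=False)
    with open(path) as fh:
        for line in fh:
            if line.startswith("# polarity:"):
                polarity = line.split(":", 1)[1].strip()
                break
            if not line.startswith("#"):
                break
    return SurfaceMesh(
        vertices=np.asarray(tm.vertices, float),
        faces=np.asarray(tm.faces, int),
        polarity=polarity,
    )
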