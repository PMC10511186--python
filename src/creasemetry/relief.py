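"""Section-based relief enhancement of cropped impressions.

A crease impression rides on the general shape of the object (a curved
clay surface), so crease geometry is treated as the high-frequency part
of the surface: the cropped point cloud is fitted with a full bivariate
polynomial of degree 5 in each variable and the fitted surface is
subtracted.  What remains — the residual relief — carries the ridge and
furrow signal that the breadth measurement stage works on.

Because an impression is the reverse cast of the object that made it
(skin ridges appear as grooves in clay), the residual relief is negated
before crease analysis; :func:`invert_cast` performs that flip.

The local fitting frame is chosen by principal-axes analysis: the height
axis is the direction of least spatial variance of the cropped points,
and the two in-plane axes are normalized to [-1, 1] before fitting so the
degree-5 Vandermonde system stays well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from shapely.geometry import Point, Polygon

from .mesh import (
    REVERSE_CAST,
    ACTUAL_SURFACE,
    SurfaceMesh,
    largest_component,
    subset_faces,
)

FIT_DEGREE = 5
N_COEFFS = (FIT_DEGREE + 1) ** 2  # full bivariate degree-(5,5) basis


# ---------------------------------------------------------------------------
# crop regions


@dataclass
class SphereRegion:
    center: np.ndarray
    radius: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")
        d = np.linalg.norm(points - np.asarray(self.center, float), axis=1)
        return d <= self.radius


@dataclass
class BoxRegion:
    """Axis-aligned box; either bound may be ±inf to leave a side open."""

    lo: np.ndarray
    hi: np.ndarray

    def contains(self, points: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.lo, float)
        hi = np.asarray(self.hi, float)
        if np.any(lo >= hi):
            raise ValueError("box lower bound must be below upper bound")
        return np.all((points >= lo) & (points <= hi), axis=1)


def _principal_frame(points: np.ndarray):
    """Orthonormal (u, v, h) axes: variance-descending, deterministic signs.

    The height axis h is the least-variance direction.  Each of u and h is
    flipped so its largest-magnitude component is positive, and v = h x u,
    which makes the frame right-handed and reproducible; the convention is
    stable under moderate rigid motions of the patch.
    """
    center = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - center, full_matrices=False)
    u, h = vt[0], vt[2]
    if u[np.argmax(np.abs(u))] < 0:
        u = -u
    if h[np.argmax(np.abs(h))] < 0:
        h = -h
    v = np.cross(h, u)
    return center, np.vstack([u, v, h])


class PolygonRegion:
    """A 2D polygon evaluated in the mesh's dominant (largest-variance) plane."""

    def __init__(self, polygon: Polygon):
        self.polygon = polygon

    def contains_2d(self, uv: np.ndarray) -> np.ndarray:
        poly = self.polygon
        return np.fromiter(
            (poly.covers(Point(p)) for p in uv), dtype=bool, count=len(uv)
        )


def crop_roi(mesh: SurfaceMesh, region) -> SurfaceMesh:
    """Crop a mesh to a region of interest.

    Only triangles with all three vertices inside the region survive, and
    of the surviving triangles only the largest connected component is
    kept (stray disconnected islands are editing artifacts).
    """
    if isinstance(region, PolygonRegion):
        center, axes = _principal_frame(mesh.vertices)
        uv = (mesh.vertices - center) @ axes[:2].T
        inside = region.contains_2d(uv)
    else:
        inside = region.contains(mesh.vertices)
    face_mask = inside[mesh.faces].all(axis=1)
    if not face_mask.any():
        raise ValueError("region contains no complete triangle of the mesh")
    return largest_component(subset_faces(mesh, face_mask))


def split_sections(mesh: SurfaceMesh, boundaries: list[Polygon]) -> list[SurfaceMesh]:
    """Split an impression into independently fittable sections.

    ``boundaries`` are disjoint polygons in the mesh's dominant plane.
    Each triangle is assigned to the polygon containing its centroid, so
    sections never share a triangle and, when the polygons tile the patch,
    triangle areas are conserved exactly.
    """
    for i in range(len(boundaries)):
        for j in range(i + 1, len(boundaries)):
            inter = boundaries[i].intersection(boundaries[j])
            if inter.area > 1e-12:
                raise ValueError(f"polygons {i} and {j} overlap")
    center, axes = _principal_frame(mesh.vertices)
    uv = (mesh.vertices - center) @ axes[:2].T
    centroids = uv[mesh.faces].mean(axis=1)
    sections = []
    for poly in boundaries:
        mask = np.fromiter(
            (poly.contains(Point(c)) for c in centroids),
            dtype=bool,
            count=len(centroids),
        )
        if not mask.any():
            raise ValueError("a section polygon contains no triangle")
        sections.append(subset_faces(mesh, mask))
    return sections


# ---------------------------------------------------------------------------
# polynomial detrending


@dataclass
class ReliefPatch:
    """A cropped impression with its fitted baseline and residual relief.

    ``frame_axes`` rows are the (u, v, height) unit vectors; ``uv`` holds
    in-plane coordinates in mm (local, un-normalized); ``coeffs`` are the
    36 degree-(5,5) coefficients in the normalized [-1, 1]² variables.
    """

    points: np.ndarray  # (n, 3) world mm
    frame_origin: np.ndarray  # (3,)
    frame_axes: np.ndarray  # (3, 3), rows u, v, h
    uv: np.ndarray  # (n, 2) local mm
    uv_mid: np.ndarray  # (2,) normalization centre
    uv_half: np.ndarray  # (2,) normalization half-span
    coeffs: np.ndarray  # (36,)
    residuals: np.ndarray  # (n,) mm, observed minus fitted height
    triangles: np.ndarray  # (m, 3) connectivity carried from the mesh
    polarity: str = ACTUAL_SURFACE

    def to_local(self, points_world: np.ndarray) -> np.ndarray:
        return (np.asarray(points_world, float) - self.frame_origin) @ self.frame_axes.T

    def direction_to_local(self, direction_world: np.ndarray) -> np.ndarray:
        return np.asarray(direction_world, float) @ self.frame_axes.T


def _design_matrix(un: np.ndarray, vn: np.ndarray) -> np.ndarray:
    pu = np.vander(un, FIT_DEGREE + 1, increasing=True)
    pv = np.vander(vn, FIT_DEGREE + 1, increasing=True)
    return (pu[:, :, None] * pv[:, None, :]).reshape(len(un), N_COEFFS)


def fit_surface(mesh: SurfaceMesh) -> ReliefPatch:
    """Fit the degree-(5,5) baseline surface and compute the residual relief.

    The height axis is the least-variance principal axis of the vertex
    cloud; the fit is ordinary least squares of height on the full
    36-term bivariate polynomial basis in normalized (u, v).
    """
    pts = mesh.vertices
    if len(pts) < N_COEFFS:
        raise ValueError(
            f"need at least {N_COEFFS} points for a degree-{FIT_DEGREE} "
            f"bivariate fit, got {len(pts)}"
        )
    origin, axes = _principal_frame(pts)
    local = (pts - origin) @ axes.T
    uv, height = local[:, :2], local[:, 2]
    lo, hi = uv.min(axis=0), uv.max(axis=0)
    half = (hi - lo) / 2.0
    if np.any(half <= 0):
        raise ValueError("points do not span both in-plane axes")
    mid = (hi + lo) / 2.0
    norm = (uv - mid) / half
    X = _design_matrix(norm[:, 0], norm[:, 1])
    coeffs, _, rank, _ = np.linalg.lstsq(X, height, rcond=None)
    if rank < N_COEFFS:
        raise ValueError(
            "rank-deficient polynomial design (points may be collinear "
            "or too regularly degenerate)"
        )
    residuals = height - X @ coeffs
    return ReliefPatch(
        points=pts,
        frame_origin=origin,
        frame_axes=axes,
        uv=uv,
        uv_mid=mid,
        uv_half=half,
        coeffs=coeffs,
        residuals=residuals,
        triangles=mesh.faces.copy(),
        polarity=mesh.polarity,
    )


def evaluate_baseline(patch: ReliefPatch, uv: np.ndarray) -> np.ndarray:
    """Fitted baseline height at local in-plane coordinates (mm)."""
    norm = (np.asarray(uv, float) - patch.uv_mid) / patch.uv_half
    return _design_matrix(norm[:, 0], norm[:, 1]) @ patch.coeffs


def invert_cast(patch: ReliefPatch) -> ReliefPatch:
    """Flip the relief to the reverse cast: residuals negated, polarity toggled.

    An involution — applying it twice returns the original patch.  Crests
    of the inverted relief sit at the troughs of the original.
    """
    polarity = (
        REVERSE_CAST if patch.polarity == ACTUAL_SURFACE else ACTUAL_SURFACE
    )
    return replace(patch, residuals=-patch.residuals, polarity=polarity)


def relief_mesh(patch: ReliefPatch) -> SurfaceMesh:
    """The residual relief as a mesh in the patch's local frame.

    Vertices are (u, v, residual) in mm; the baseline plane is z = 0, so
    the mesh pierces z = 0 exactly at crease boundaries.
    """
    verts = np.column_stack([patch.uv, patch.residuals])
    return SurfaceMesh(verts, patch.triangles, polarity=patch.polarity)


def save_patch(patch: ReliefPatch, path) -> None:
    np.savez(
        path,
        points=patch.points,
        frame_origin=patch.frame_origin,
        frame_axes=patch.frame_axes,
        uv=patch.uv,
        uv_mid=patch.uv_mid,
        uv_half=patch.uv_half,
        coeffs=patch.coeffs,
        residuals=patch.residuals,
        triangles=patch.triangles,
        polarity=np.array(patch.polarity),
    )


def load_patch(path) -> ReliefPatch:
    with np.load(path) as z:
        return ReliefPatch(
            points=z["points"],
            frame_origin=z["frame_origin"],
            frame_axes=z["frame_axes"],
            uv=z["uv"],
            uv_mid=z["uv_mid"],
            uv_half=z["uv_half"],
            coeffs=z["coeffs"],
            residuals=z["residuals"],
            triangles=z["triangles"],
            polarity=str(z["polarity"]),
        )
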