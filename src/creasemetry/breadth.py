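"""Crease breadth and count from straight transects over a relief patch.

A measurement run traces a straight line across the bundle of ridges of
an enhanced (detrended) impression.  The residual relief pierces its own
baseline plane at crease boundaries, so the intersections of the transect
with the relief mesh — computed with the Möller–Trumbore ray–triangle
algorithm — mark where creases begin and end.  The number of ridges is
half the number of intersections.

Two classical breadth definitions are provided:

* Kamp: distance spanned by complete ridge–furrow pairs divided by the
  number of pairs.
* Penrose: mean distance between centres of consecutive furrows.

Repeated runs (three by default, to mirror intra-observer replication)
are averaged into a mean crease breadth (MCB).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .relief import ReliefPatch, relief_mesh

#: intersections closer along the line than this are one hit (shared edges)
HIT_MERGE_TOL = 1e-9


@dataclass
class MeasurementLine:
    """A finite straight transect: origin, unit direction, length (mm)."""

    origin: np.ndarray
    direction: np.ndarray
    length: float

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.length <= 0:
            raise ValueError("line length must be positive")
        norm = np.linalg.norm(self.direction)
        if norm == 0:
            raise ValueError("line direction must be non-zero")
        if abs(norm - 1.0) > 1e-9:
            warnings.warn("line direction was not unit length; normalizing")
            self.direction = self.direction / norm


@dataclass
class CreaseProfile:
    """Ordered transect/relief intersections and derived crease landmarks.

    ``hits`` are distances (mm) along the line, strictly increasing.
    Crest/trough positions are the centres of the ridge/furrow intervals
    bounded by consecutive hits.
    """

    hits: np.ndarray
    crease_count: int
    crest_positions: np.ndarray = field(default_factory=lambda: np.array([]))
    trough_positions: np.ndarray = field(default_factory=lambda: np.array([]))


def moller_trumbore(
    origin: np.ndarray,
    direction: np.ndarray,
    triangles: np.ndarray,
    t_max: float = np.inf,
    eps: float = 1e-12,
) -> np.ndarray:
    """Ray–triangle intersection distances by the Möller–Trumbore method.

    ``triangles`` has shape (m, 3, 3).  Returns the unsorted ray
    parameters t of every triangle hit with t in [0, t_max]; the
    barycentric coordinates are solved via the scalar-triple-product
    formulation, rejecting rays (near-)parallel to a triangle's plane.
    """
    origin = np.asarray(origin, float)
    direction = np.asarray(direction, float)
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0
    pvec = np.cross(direction[None, :], e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > eps
    if not ok.any():
        return np.empty(0)
    inv = np.zeros_like(det)
    inv[ok] = 1.0 / det[ok]
    tvec = origin[None, :] - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = np.cross(tvec, e1)
    v = qvec @ direction * inv
    t = np.einsum("ij,ij->i", e2, qvec) * inv
    hit = ok & (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0) & (t >= 0.0) & (t <= t_max)
    return t[hit]


def _merge_hits(t: np.ndarray, tol: float = HIT_MERGE_TOL) -> np.ndarray:
    if len(t) == 0:
        return t
    t = np.sort(t)
    keep = np.concatenate([[True], np.diff(t) > tol])
    return t[keep]


def _surface_heights(
    mesh_triangles: np.ndarray, uv: np.ndarray, z_lo: float
) -> np.ndarray:
    """Relief height above the baseline at in-plane points (vertical rays)."""
    out = np.full(len(uv), np.nan)
    for i, (u, v) in enumerate(uv):
        t = moller_trumbore(
            np.array([u, v, z_lo]), np.array([0.0, 0.0, 1.0]), mesh_triangles
        )
        if len(t):
            out[i] = z_lo + t.min()
    return out


def intersect_line_mesh(line: MeasurementLine, patch: ReliefPatch) -> CreaseProfile:
    """Intersect a transect with the zero-pierced residual relief.

    The line is expressed in the same frame as the patch points, mapped
    into the patch's local frame, and embedded in the baseline plane
    (z = 0); Möller–Trumbore tests against every relief triangle give the
    crossing distances.  Duplicate hits at shared triangle edges are
    collapsed.  A line that misses the patch yields an empty profile.
    """
    rmesh = relief_mesh(patch)
    origin = patch.to_local(line.origin)
    direction = patch.direction_to_local(line.direction)
    origin[2] = 0.0
    direction[2] = 0.0
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        raise ValueError("transect direction is perpendicular to the patch")
    direction = direction / norm
    tri = rmesh.triangles()
    hits = _merge_hits(moller_trumbore(origin, direction, tri, t_max=line.length))
    crease_count = len(hits) // 2
    crests: list[float] = []
    troughs: list[float] = []
    if len(hits) >= 2:
        mids = 0.5 * (hits[:-1] + hits[1:])
        mid_uv = origin[None, :2] + mids[:, None] * direction[None, :2]
        z_lo = float(patch.residuals.min()) - 1.0
        heights = _surface_heights(tri, mid_uv, z_lo)
        for m, h in zip(mids, heights):
            if not np.isfinite(h):
                continue
            (crests if h > 0 else troughs).append(float(m))
    return CreaseProfile(
        hits=hits,
        crease_count=crease_count,
        crest_positions=np.asarray(crests),
        trough_positions=np.asarray(troughs),
    )


def kamp_breadth(profile: CreaseProfile) -> float:
    """Breadth as complete-pair span divided by the number of pairs.

    Every two consecutive crossings bound one crease, so hits ``0`` and
    ``2k`` bound exactly ``k`` ridge–furrow pairs; the breadth is that
    span divided by ``k``.  A trailing crossing that does not complete a
    pair is dropped with a warning.
    """
    hits = profile.hits
    n_pairs = (len(hits) - 1) // 2
    if n_pairs < 1:
        raise ValueError(
            "need at least one complete ridge-furrow pair (3 crossings); "
            f"got {len(hits)}"
        )
    if len(hits) > 2 * n_pairs + 1:
        warnings.warn(
            "transect ends inside a crease; truncating to the last "
            "complete ridge-furrow pair"
        )
    span = hits[2 * n_pairs] - hits[0]
    return float(span / n_pairs)


def penrose_breadth(profile: CreaseProfile) -> float:
    """Breadth as the mean spacing of consecutive furrow centres."""
    troughs = profile.trough_positions
    if len(troughs) < 2:
        raise ValueError(
            f"need at least two furrow centres, got {len(troughs)}"
        )
    return float(np.mean(np.diff(np.sort(troughs))))


@dataclass
class BreadthMeasurement:
    """Aggregate of repeated breadth runs on one impression."""

    definition: str
    run_values: list[float]
    mcb: float
    mean_crease_count: float
    span_mm: float
    lines: list[MeasurementLine] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.run_values):
            raise ValueError("all run breadths must be positive")


_DEFINITIONS = {"kamp": kamp_breadth, "penrose": penrose_breadth}


def measure_impression(
    patch: ReliefPatch,
    lines: list[MeasurementLine],
    definition: str = "kamp",
) -> BreadthMeasurement:
    """Measure breadth along each transect and average into an MCB.

    Each line is one run; the MCB is the arithmetic mean of the run
    breadths and the mean crease count is averaged the same way.  Any run
    whose profile cannot support the chosen definition aborts the
    measurement, naming the run.
    """
    if definition not in _DEFINITIONS:
        raise ValueError(f"unknown breadth definition {definition!r}")
    if len(lines) < 1:
        raise ValueError("need at least one measurement line")
    fn = _DEFINITIONS[definition]
    values, counts, spans = [], [], []
    for i, line in enumerate(lines, start=1):
        profile = intersect_line_mesh(line, patch)
        try:
            values.append(fn(profile))
        except ValueError as exc:
            raise ValueError(f"run {i} failed: {exc}") from exc
        counts.append(profile.crease_count)
        spans.append(float(profile.hits[-1] - profile.hits[0]))
    return BreadthMeasurement(
        definition=definition,
        run_values=values,
        mcb=float(np.mean(values)),
        mean_crease_count=float(np.mean(counts)),
        span_mm=float(np.mean(spans)),
        lines=list(lines),
    )
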