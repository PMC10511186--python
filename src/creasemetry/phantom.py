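"""Synthetic phantoms of crease impressions on clay.

No scanned impressions ship with this package, so every downstream stage
is exercised on phantoms with known ground truth: patches of quasi-
parallel sinusoidal ridges (finger-ridge analogues) or rectangular
grooves (toolmark analogues) on a planar or gently spherical substrate,
available both as analytic surface meshes and as voxelized grayscale
stacks with two intensity modes (dark air, bright clay), brighter
spherical mineral inclusions, Gaussian noise, and optional linear firing
shrinkage.

Ground truth (:class:`PhantomTruth`) records the post-shrinkage crease
period — the quantity the measurement stages must recover — along with
the exact voxel-wise clay mask and the geometry needed to place
measurement transects programmatically.

Conventions: analytic ridge meshes are height fields ``z = h(x, y)``;
voxel phantoms are slabs with the clay surface as a height field
``y = h(x, z)`` so that every reconstructed slice (constant z) contains
both air and clay, as real cross-sectional slices do.  Everything is
deterministic given the spec's seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .mesh import SurfaceMesh
from .volume import MAX_VOXELS, VoxelStack

AIR_INTENSITY = 50.0
CLAY_INTENSITY = 200.0
GRAIN_INTENSITY = 255.0


@dataclass
class PhantomSpec:
    """Parameters of a synthetic ridge patch.

    ``ridge_period`` is the centre-to-centre crease spacing before
    shrinkage — the ground-truth breadth is ``ridge_period * (1 - ts)``.
    ``ridge_depth`` is the peak-to-trough relief amplitude.  Defaults
    describe a young-adult-scale fingermark (0.5 mm period) pressed into
    fine sculpting clay scanned at 0.025 mm voxels.
    """

    ridge_period: float = 0.5  # mm
    ridge_depth: float = 0.12  # mm, peak to trough
    n_ridges: int = 8
    orientation_deg: float = 0.0
    substrate: str = "plane"  # "plane" | "sphere"
    sphere_radius_mm: float = 25.0
    grain_density: float = 0.5  # expected inclusions per mm^3
    grain_radius_mm: float = 0.04
    shrinkage_ts: float = 0.0
    noise_sd: float = 10.0  # intensity units
    voxel_mm: float = 0.025
    seed: int = 0
    cross_extent_mm: Optional[float] = None  # patch width along the ridges

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.ridge_period <= 0:
            raise ValueError("ridge_period must be positive")
        if self.ridge_depth <= 0:
            raise ValueError("ridge_depth must be positive")
        if self.n_ridges < 1:
            raise ValueError("n_ridges must be at least 1")
        if not 0.0 <= self.shrinkage_ts <= 0.2:
            raise ValueError("shrinkage_ts must lie in [0, 0.2]")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")
        if self.voxel_mm > self.ridge_period / 4:
            raise ValueError(
                "voxel_mm too coarse: ridges need at least 4 voxels per "
                "period to be resolvable"
            )
        if self.substrate not in ("plane", "sphere"):
            raise ValueError("substrate must be 'plane' or 'sphere'")
        if self.substrate == "sphere" and self.sphere_radius_mm <= 0:
            raise ValueError("sphere_radius_mm must be positive")
        if self.grain_density < 0:
            raise ValueError("grain_density must be non-negative")
        if self.grain_radius_mm <= 0:
            raise ValueError("grain_radius_mm must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def cross_extent(self) -> float:
        if self.cross_extent_mm is not None:
            return self.cross_extent_mm
        return max(1.5, 0.4 * self.n_ridges * self.ridge_period)


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom artifact.

    ``true_breadth_mm`` is the post-shrinkage crease period; the geometry
    fields (in the artifact's own mm frame) let tests and the pipeline
    place perpendicular measurement transects without interaction.
    """

    spec: PhantomSpec
    true_breadth_mm: float
    true_crease_count: int
    mask: Optional[np.ndarray] = None  # voxel-wise clay labels
    ridge_normal: np.ndarray = field(default_factory=lambda: np.zeros(3))
    ridge_axis: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    transect_halflength: float = 0.0
    cross_halfwidth: float = 0.0
    crop_lo: Optional[np.ndarray] = None
    crop_hi: Optional[np.ndarray] = None

    def manifest(self) -> dict:
        d = asdict(self.spec)
        out = {
            "spec": d,
            "true_breadth_mm": self.true_breadth_mm,
            "true_crease_count": self.true_crease_count,
            "ridge_normal": list(map(float, self.ridge_normal)),
            "ridge_axis": list(map(float, self.ridge_axis)),
            "center": list(map(float, self.center)),
            "transect_halflength": float(self.transect_halflength),
            "cross_halfwidth": float(self.cross_halfwidth),
        }
        if self.crop_lo is not None:
            out["crop_lo"] = list(map(float, self.crop_lo))
            out["crop_hi"] = list(map(float, self.crop_hi))
        return out


def write_truth(truth: PhantomTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.manifest(), fh, indent=1, sort_keys=True)


def _grid_mesh(x1d: np.ndarray, y1d: np.ndarray, z2d: np.ndarray) -> SurfaceMesh:
    """Triangulate a height field sampled on a regular grid."""
    nx, ny = len(x1d), len(y1d)
    xx, yy = np.meshgrid(x1d, y1d, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), z2d.ravel()])
    idx = np.arange(nx * ny).reshape(nx, ny)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    faces = np.concatenate(
        [np.column_stack([a, b, c]), np.column_stack([a, c, d])]
    )
    return SurfaceMesh(vertices=verts, faces=faces)


def _substrate_height(spec: PhantomSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    if spec.substrate == "plane":
        return np.zeros(np.broadcast(x, y).shape)
    r2 = x**2 + y**2
    R = spec.sphere_radius_mm
    r2 = np.minimum(r2, (0.9 * R) ** 2)  # keep the cap well-defined
    return np.sqrt(R**2 - r2) - R


def _ridge_profile(spec: PhantomSpec, s: np.ndarray) -> np.ndarray:
    return 0.5 * spec.ridge_depth * np.cos(2 * np.pi * s / spec.ridge_period)


def make_ridged_mesh(spec: PhantomSpec) -> tuple[SurfaceMesh, PhantomTruth]:
    """Analytic sinusoidal ridge patch as a triangulated height field.

    The height field is substrate plus a sinusoid of period
    ``ridge_period`` and peak-to-trough amplitude ``ridge_depth`` along
    ``orientation_deg``; the whole geometry is scaled by ``(1 - ts)``,
    and the truth records the post-shrinkage period.
    """
    spec.validate()
    pitch = spec.voxel_mm
    half_s = spec.n_ridges * spec.ridge_period / 2.0
    half_c = spec.cross_extent / 2.0
    s1d = np.arange(-half_s, half_s + pitch / 2, pitch)
    c1d = np.arange(-half_c, half_c + pitch / 2, pitch)
    ss, cc = np.meshgrid(s1d, c1d, indexing="ij")
    theta = np.deg2rad(spec.orientation_deg)
    # (s, c) -> (x, y): s runs across the ridges, c along them
    x = ss * np.cos(theta) - cc * np.sin(theta)
    y = ss * np.sin(theta) + cc * np.cos(theta)
    z = _substrate_height(spec, x, y) + _ridge_profile(spec, ss)
    scale = 1.0 - spec.shrinkage_ts
    mesh = _grid_mesh(s1d, c1d, z)
    verts = np.column_stack([x.ravel(), y.ravel(), z.ravel()]) * scale
    mesh = SurfaceMesh(vertices=verts, faces=mesh.faces)
    truth = PhantomTruth(
        spec=spec,
        true_breadth_mm=spec.ridge_period * scale,
        true_crease_count=spec.n_ridges,
        ridge_normal=np.array([np.cos(theta), np.sin(theta), 0.0]),
        ridge_axis=np.array([-np.sin(theta), np.cos(theta), 0.0]),
        center=np.zeros(3),
        transect_halflength=0.98 * half_s * scale,
        cross_halfwidth=half_c * scale,
    )
    return mesh, truth


def make_toolmark_mesh(
    tooth_width_mm: float,
    n_teeth: int,
    depth_mm: float = 0.15,
    seed: int = 0,
) -> tuple[SurfaceMesh, PhantomTruth]:
    """Parallel rectangular-profile grooves of equal width.

    Emulates the strokes of a toothed modelling tool: each tooth cuts a
    flat-bottomed groove; groove centres repeat every ``tooth_width_mm``,
    which is therefore the ground-truth crease breadth.
    """
    if tooth_width_mm <= 0:
        raise ValueError("tooth_width_mm must be positive")
    if n_teeth < 1:
        raise ValueError("n_teeth must be at least 1")
    if depth_mm <= 0:
        raise ValueError("depth_mm must be positive")
    w = tooth_width_mm
    pitch = min(0.025, w / 24)
    half_s = n_teeth * w / 2.0
    half_c = max(1.5, 0.4 * n_teeth * w) / 2.0
    s1d = np.arange(-half_s, half_s + pitch / 2, pitch)
    c1d = np.arange(-half_c, half_c + pitch / 2, pitch)
    phase = np.mod(s1d + half_s, w) / w
    profile = np.where((phase > 0.15) & (phase < 0.85), -depth_mm, 0.0)
    z = np.tile(profile[:, None], (1, len(c1d)))
    mesh = _grid_mesh(s1d, c1d, z)
    spec = PhantomSpec(
        ridge_period=w,
        ridge_depth=depth_mm,
        n_ridges=n_teeth,
        voxel_mm=min(0.025, w / 8),
        seed=seed,
    )
    truth = PhantomTruth(
        spec=spec,
        true_breadth_mm=w,
        true_crease_count=n_teeth,
        ridge_normal=np.array([1.0, 0.0, 0.0]),
        ridge_axis=np.array([0.0, 1.0, 0.0]),
        center=np.zeros(3),
        transect_halflength=0.98 * half_s,
        cross_halfwidth=half_c,
    )
    return mesh, truth


def make_voxel_phantom(spec: PhantomSpec) -> tuple[VoxelStack, PhantomTruth]:
    """Voxelized slab of clay bearing the ridged surface.

    The stack has two dominant intensity modes (air low, clay high) plus
    brighter spherical mineral inclusions and Gaussian noise.  Inclusions
    are kept a small clearance away from the clay/air interface: grains
    embedded in the clay body and loose grains in air are modelled,
    surface-piercing grains are not (impressions crossed by such grains
    are the ones an analyst discards).  The returned mask is the exact
    voxel-wise clay label.
    """
    spec.validate()
    scale = 1.0 - spec.shrinkage_ts
    vox = spec.voxel_mm
    period = spec.ridge_period * scale
    depth = spec.ridge_depth * scale
    theta = np.deg2rad(spec.orientation_deg)

    margin = 8 * vox
    span_s = spec.n_ridges * period
    span_c = spec.cross_extent * scale
    # axis-aligned extents of the rotated patch in the (x, z) plane
    ext_x = abs(span_s * np.cos(theta)) + abs(span_c * np.sin(theta))
    ext_z = abs(span_s * np.sin(theta)) + abs(span_c * np.cos(theta))
    Lx = ext_x + 2 * margin
    Lz = max(ext_z + 2 * margin, 6 * vox)

    slab = 0.5  # mm of clay under the lowest point of the surface
    # substrate droop across the patch (spherical cap sagitta)
    if spec.substrate == "sphere":
        half_diag = 0.5 * np.hypot(ext_x, ext_z)
        sag = spec.sphere_radius_mm - np.sqrt(
            max(spec.sphere_radius_mm**2 - half_diag**2, 0.0)
        )
    else:
        sag = 0.0
    y0 = slab + sag * scale + depth / 2  # mean surface level
    Ly = y0 + depth / 2 + 12 * vox

    nx = int(np.ceil(Lx / vox))
    ny = int(np.ceil(Ly / vox))
    nz = max(int(np.ceil(Lz / vox)), 2)
    if nx * ny * nz > MAX_VOXELS:
        raise ValueError(
            f"phantom volume {nx * ny * nz} voxels exceeds budget {MAX_VOXELS}"
        )

    x = (np.arange(nx) + 0.5) * vox
    y = (np.arange(ny) + 0.5) * vox
    z = (np.arange(nz) + 0.5) * vox
    cx, cz = Lx / 2.0, Lz / 2.0
    xg, zg = np.meshgrid(x - cx, z - cz, indexing="ij")  # (nx, nz)
    s = xg * np.cos(theta) + zg * np.sin(theta)
    c = -xg * np.sin(theta) + zg * np.cos(theta)
    surf = y0 + scale * (
        _substrate_height(spec, s / scale, c / scale)
        + _ridge_profile(spec, s / scale)
    )  # (nx, nz)

    # mask indexed (slice=z, row=y, col=x)
    mask = y[None, :, None] < surf.T[:, None, :]

    rng = np.random.default_rng(spec.seed)
    intensities = np.where(mask, CLAY_INTENSITY, AIR_INTENSITY).astype(
        np.float32
    )

    if spec.grain_density > 0:
        volume_mm3 = Lx * Ly * Lz
        n_grains = rng.poisson(spec.grain_density * volume_mm3)
        clearance = spec.grain_radius_mm + 2 * vox
        r_vox = spec.grain_radius_mm / vox
        for _ in range(n_grains):
            gx = rng.uniform(0, Lx)
            gy = rng.uniform(0, Ly)
            gz = rng.uniform(0, Lz)
            gs = (gx - cx) * np.cos(theta) + (gz - cz) * np.sin(theta)
            gc = -(gx - cx) * np.sin(theta) + (gz - cz) * np.cos(theta)
            y_surf = y0 + scale * (
                _substrate_height(
                    spec, np.array(gs / scale), np.array(gc / scale)
                )
                + _ridge_profile(spec, np.array(gs / scale))
            )
            if abs(gy - float(y_surf)) < clearance:
                continue  # keep the interface clean of inclusions
            iz, iy, ix = gz / vox - 0.5, gy / vox - 0.5, gx / vox - 0.5
            zlo = max(int(np.floor(iz - r_vox)), 0)
            zhi = min(int(np.ceil(iz + r_vox)) + 1, nz)
            ylo = max(int(np.floor(iy - r_vox)), 0)
            yhi = min(int(np.ceil(iy + r_vox)) + 1, ny)
            xlo = max(int(np.floor(ix - r_vox)), 0)
            xhi = min(int(np.ceil(ix + r_vox)) + 1, nx)
            zz, yy, xx = np.meshgrid(
                np.arange(zlo, zhi),
                np.arange(ylo, yhi),
                np.arange(xlo, xhi),
                indexing="ij",
            )
            inside = (
                (zz - iz) ** 2 + (yy - iy) ** 2 + (xx - ix) ** 2
            ) <= r_vox**2
            block = intensities[zlo:zhi, ylo:yhi, xlo:xhi]
            block[inside] = GRAIN_INTENSITY
            intensities[zlo:zhi, ylo:yhi, xlo:xhi] = block

    if spec.noise_sd > 0:
        intensities = intensities + rng.normal(
            0.0, spec.noise_sd, size=intensities.shape
        ).astype(np.float32)

    stack = VoxelStack(intensities=intensities, voxel_mm=vox)
    truth = PhantomTruth(
        spec=spec,
        true_breadth_mm=period,
        true_crease_count=spec.n_ridges,
        mask=mask,
        ridge_normal=np.array([np.cos(theta), 0.0, np.sin(theta)]),
        ridge_axis=np.array([-np.sin(theta), 0.0, np.cos(theta)]),
        center=np.array([cx, y0, cz]),
        transect_halflength=0.98 * span_s / 2.0,
        cross_halfwidth=span_c / 2.0,
        crop_lo=np.array(
            [margin / 2, float(surf.min()) - 0.3 * depth - 2 * vox, margin / 2]
        ),
        crop_hi=np.array([Lx - margin / 2, Ly + 1.0, Lz - margin / 2]),
    )
    return stack, truth


def make_breadth_table(
    seed: int,
    n_impressions: int,
    breadth_range: tuple[float, float] = (0.35, 0.8),
) -> pd.DataFrame:
    """Random observed-MCB rows for exercising the demographics stage.

    Returns a table with columns ``label, area_mm2, definition, mcb_o_mm``
    (the same schema as a measured report), breadths drawn uniformly from
    ``breadth_range``.
    """
    lo, hi = breadth_range
    if not (0 < lo < hi <= 2.0):
        raise ValueError("breadth_range must lie within (0, 2] with lo < hi")
    if n_impressions < 1:
        raise ValueError("n_impressions must be at least 1")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_impressions):
        rows.append(
            {
                "label": f"S_{i + 1:02d}",
                "area_mm2": round(float(rng.uniform(4.0, 30.0)), 1),
                "definition": str(rng.choice(["kamp", "penrose"])),
                "mcb_o_mm": round(float(rng.uniform(lo, hi)), 4),
            }
        )
    return pd.DataFrame(rows)


def transect_lines(truth: PhantomTruth, n_lines: int = 3, seed: int = 0):
    """Perpendicular measurement transects across a phantom's ridges.

    Lines run along the ridge normal through the patch, offset along the
    ridge axis so repeated runs probe different locations, mirroring the
    repeated manual line placements of the measurement protocol.
    """
    from .breadth import MeasurementLine

    rng = np.random.default_rng(seed)
    offsets = rng.uniform(
        -0.3 * truth.cross_halfwidth, 0.3 * truth.cross_halfwidth, n_lines
    )
    lines = []
    for off in offsets:
        origin = (
            truth.center
            + off * truth.ridge_axis
            - truth.transect_halflength * truth.ridge_normal
        )
        lines.append(
            MeasurementLine(
                origin=origin,
                direction=truth.ridge_normal.copy(),
                length=2.0 * truth.transect_halflength,
            )
        )
    return lines
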