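"""Grayscale slice stacks to cleaned binary volumes and surface meshes.

The segmentation chain mirrors how micro-CT reconstructions of clay
objects are usually processed: each reconstructed slice is a grayscale
image in which clay and mineral grains are bright and air is dark.
Otsu's criterion turns intensity into a material/air label, small
spurious islands (loose grain speckle in air, trapped-air specks in
clay) are removed, borders are smoothed morphologically, and the
material/air interface is triangulated into a surface mesh in mm.

Coordinate convention: the voxel at index ``(i, j, k)`` (slice, row,
column) has its centre at ``((i + 0.5), (j + 0.5), (k + 0.5)) *
voxel_mm`` and the mesh is emitted in right-handed ``(x, y, z) =
(column, row, slice)`` mm coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import tifffile
from scipy import ndimage
from skimage import filters, measure, morphology

from .mesh import SurfaceMesh, mesh_area  # noqa: F401  (re-exported)

#: hard cap on addressable volume size, voxels
MAX_VOXELS = 2**28


@dataclass
class VoxelStack:
    """A 3D grayscale intensity grid with isotropic physical pitch."""

    intensities: np.ndarray  # (slices, rows, cols)
    voxel_mm: float
    slice_axis: int = 0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")
        if self.intensities.shape[self.slice_axis] < 2:
            raise ValueError("stack needs at least 2 slices")
        if not np.isfinite(np.asarray(self.intensities, float)).all():
            raise ValueError("intensities contain non-finite values")

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[self.slice_axis]


@dataclass
class BinaryStack:
    """Material/air labels (True = clay or grain) for a voxel stack."""

    labels: np.ndarray  # (slices, rows, cols) bool
    voxel_mm: float
    threshold_used: np.ndarray  # scalar (global) or per-slice array
    slice_axis: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")


def read_stack(path, voxel_mm: float) -> VoxelStack:
    """Read a multi-page TIFF as a slice stack (page = slice).

    Intensities are kept in their stored dtype; no rescaling is applied.
    """
    with tifffile.TiffFile(path) as tf:
        shapes = {page.shape for page in tf.pages}
        if len(shapes) > 1:
            raise ValueError(f"pages have mixed shapes: {sorted(shapes)}")
        data = tf.asarray()
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] < 2:
        raise ValueError("stack needs at least 2 slices")
    return VoxelStack(intensities=data, voxel_mm=voxel_mm)


def write_stack(stack: VoxelStack, path) -> None:
    """Write one TIFF page per slice, lossless."""
    data = np.moveaxis(stack.intensities, stack.slice_axis, 0)
    tifffile.imwrite(path, data, photometric="minisblack", software="")


def trim_slices(stack: VoxelStack, n_first: int, n_last: int) -> VoxelStack:
    """Drop slices from both ends (support material, stitching edges)."""
    if n_first < 0 or n_last < 0:
        raise ValueError("trim counts must be non-negative")
    if n_first + n_last >= stack.n_slices:
        raise ValueError(
            f"cannot trim {n_first}+{n_last} slices from a "
            f"{stack.n_slices}-slice stack"
        )
    sl = [slice(None)] * 3
    sl[stack.slice_axis] = slice(n_first, stack.n_slices - n_last)
    return replace(stack, intensities=stack.intensities[tuple(sl)])


def otsu_from_histogram(counts, bin_centers) -> float:
    """Otsu threshold computed from a histogram.

    Returns the bin centre separating the two classes such that the
    weighted intra-class variance is minimal (equivalently, between-class
    variance is maximal); voxels strictly above the threshold are material.
    """
    counts = np.asarray(counts, dtype=float)
    bin_centers = np.asarray(bin_centers, dtype=float)
    if np.count_nonzero(counts) < 2:
        raise ValueError("histogram needs at least two populated bins")
    return float(filters.threshold_otsu(hist=(counts, bin_centers)))


def otsu_threshold(stack: VoxelStack, mode: str = "per_slice") -> BinaryStack:
    """Binarize a stack with Otsu's criterion.

    ``per_slice`` thresholds every slice independently (each slice is its
    own intensity unit, as when slices come from separately reconstructed
    tiles); ``global`` uses one threshold for the whole volume.
    """
    data = np.moveaxis(stack.intensities, stack.slice_axis, 0)
    if mode == "global":
        if np.unique(data).size < 2:
            raise ValueError("volume is constant; Otsu threshold undefined")
        thr = float(filters.threshold_otsu(data))
        labels = data > thr
        thresholds = np.asarray(thr)
    elif mode == "per_slice":
        labels = np.empty(data.shape, dtype=bool)
        thresholds = np.empty(data.shape[0], dtype=float)
        for i, sl in enumerate(data):
            if np.unique(sl).size < 2:
                raise ValueError(
                    f"slice {i} is constant; Otsu threshold undefined"
                )
            thresholds[i] = float(filters.threshold_otsu(sl))
            labels[i] = sl > thresholds[i]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    labels = np.moveaxis(labels, 0, stack.slice_axis)
    return BinaryStack(
        labels=labels,
        voxel_mm=stack.voxel_mm,
        threshold_used=thresholds,
        slice_axis=stack.slice_axis,
    )


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


def _remove_islands(labels: np.ndarray, min_voxels: int) -> np.ndarray:
    """Flip connected components (of either phase) below ``min_voxels``."""
    out = labels.copy()
    for phase in (True, False):
        comp, n = ndimage.label(out == phase, structure=_STRUCT26)
        if n == 0:
            continue
        sizes = np.bincount(comp.ravel())
        small = np.flatnonzero(sizes[1:] < min_voxels) + 1
        if len(small):
            out[np.isin(comp, small)] = not phase
    return out


def clean_binary(
    binary: BinaryStack,
    min_island_voxels: int = 27,
    smooth_radius_voxels: int = 1,
) -> BinaryStack:
    """Remove small islands of either phase, then smooth borders.

    Components (26-connectivity) strictly smaller than
    ``min_island_voxels`` are flipped to the surrounding phase;
    morphological closing-then-opening with a ball structuring element
    smooths the boundary.  The whole filter is iterated to a fixed point
    (almost always reached after one pass), so the operation is
    idempotent on its own output by construction.
    """
    if min_island_voxels < 0:
        raise ValueError("min_island_voxels must be non-negative")
    labels = binary.labels
    ball = (
        morphology.ball(smooth_radius_voxels)
        if smooth_radius_voxels > 0
        else None
    )
    for _ in range(8):
        prev = labels
        labels = _remove_islands(labels, min_island_voxels)
        if ball is not None:
            labels = morphology.closing(labels, ball)
            labels = morphology.opening(labels, ball)
        if np.array_equal(labels, prev):
            break
    return replace(binary, labels=labels)


def extract_mesh(
    binary: BinaryStack, smooth_sigma_voxels: float = 1.0
) -> SurfaceMesh:
    """Triangulate the material/air interface into a surface mesh in mm.

    A marching-cubes isosurface is taken at the 0.5 level of the (mildly
    Gaussian-smoothed) indicator volume; smoothing gives sub-voxel vertex
    placement instead of the half-voxel staircase a raw binary volume
    produces.  Vertices come out in ``(x, y, z) = (col, row, slice)`` mm
    with voxel centres at ``(index + 0.5) * voxel_mm``.
    """
    labels = np.moveaxis(binary.labels, binary.slice_axis, 0)
    n_true = int(labels.sum())
    if n_true == 0 or n_true == labels.size:
        raise ValueError("volume is single-phase; no interface to mesh")
    field = labels.astype(np.float32)
    if smooth_sigma_voxels > 0:
        field = ndimage.gaussian_filter(field, smooth_sigma_voxels)
        # keep the level inside the smoothed range
        lo, hi = float(field.min()), float(field.max())
        level = min(max(0.5, lo + 1e-6), hi - 1e-6)
    else:
        level = 0.5
    verts, faces, _, _ = measure.marching_cubes(
        field, level=level, spacing=(binary.voxel_mm,) * 3
    )
    verts = verts + 0.5 * binary.voxel_mm  # voxel-centre convention
    # (slice, row, col) -> (x, y, z) = (col, row, slice)
    verts = verts[:, ::-1]
    faces = faces[:, ::-1]  # preserve outward orientation after axis flip
    return SurfaceMesh(vertices=verts, faces=faces)
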