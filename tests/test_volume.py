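"""Segmentation chain: stack IO, Otsu, binary cleanup, meshing, areas."""

import numpy as np
import pytest
import trimesh
from oracles import otsu_bruteforce

from creasemetry import phantom
from creasemetry.mesh import SurfaceMesh, mesh_area
from creasemetry.volume import (
    BinaryStack,
    VoxelStack,
    clean_binary,
    extract_mesh,
    otsu_from_histogram,
    otsu_threshold,
    read_stack,
    trim_slices,
    write_stack,
)


class TestStackIO:
    @pytest.mark.parametrize("dtype", [np.float32, np.uint16])
    def test_round_trip_preserves_values(self, tmp_path, dtype):
        rng = np.random.default_rng(0)
        data = (rng.uniform(0, 60000, (4, 8, 9))).astype(dtype)
        stack = VoxelStack(intensities=data, voxel_mm=0.025)
        path = tmp_path / "s.tif"
        write_stack(stack, path)
        back = read_stack(path, voxel_mm=0.025)
        assert back.intensities.dtype == dtype
        assert np.array_equal(back.intensities, data)
        assert back.intensities.min() == data.min()
        assert back.intensities.max() == data.max()

    def test_single_slice_rejected(self, tmp_path):
        import tifffile

        path = tmp_path / "one.tif"
        tifffile.imwrite(path, np.zeros((5, 5), dtype=np.uint8))
        with pytest.raises(ValueError, match="2 slices"):
            read_stack(path, voxel_mm=0.025)

    def test_missing_file(self, tmp_path):
        with pytest.raises((FileNotFoundError, OSError)):
            read_stack(tmp_path / "nope.tif", voxel_mm=0.025)


class TestTrim:
    def setup_method(self):
        self.stack = VoxelStack(
            intensities=np.arange(10 * 4 * 4, dtype=np.uint16).reshape(10, 4, 4),
            voxel_mm=0.025,
        )

    def test_trims_both_ends(self):
        out = trim_slices(self.stack, 1, 1)
        assert out.n_slices == 8
        assert np.array_equal(out.intensities, self.stack.intensities[1:9])
        assert out.voxel_mm == self.stack.voxel_mm

    def test_zero_trim_is_identity(self):
        out = trim_slices(self.stack, 0, 0)
        assert np.array_equal(out.intensities, self.stack.intensities)

    def test_over_trim_rejected(self):
        with pytest.raises(ValueError):
            trim_slices(self.stack, 5, 5)


class TestOtsu:
    def test_two_valued_volume_splits_exactly(self):
        rng = np.random.default_rng(1)
        data = rng.choice([10.0, 200.0], size=(3, 6, 6))
        data[0, 0, 0], data[0, 0, 1] = 10.0, 200.0  # both phases per slice
        data[1, 0, 0], data[1, 0, 1] = 10.0, 200.0
        data[2, 0, 0], data[2, 0, 1] = 10.0, 200.0
        binary = otsu_threshold(VoxelStack(data, 0.025), mode="per_slice")
        assert np.array_equal(binary.labels, data == 200.0)

    def test_eight_voxel_example_matches_exhaustive_search(self):
        values = np.array([0, 0, 1, 1, 200, 200, 201, 201], dtype=float)
        centers, counts = np.unique(values, return_counts=True)
        thr = otsu_from_histogram(counts, centers)
        assert thr == pytest.approx(otsu_bruteforce(counts, centers))
        assert ((values > thr) == (values >= 200)).all()

    @pytest.mark.parametrize("seed", range(6))
    def test_random_histograms_match_bruteforce(self, seed):
        from oracles import otsu_intraclass

        rng = np.random.default_rng(seed)
        n_bins = rng.integers(8, 64)
        counts = rng.integers(0, 50, n_bins)
        counts[rng.integers(0, n_bins)] += 1  # ensure two populated bins
        counts[rng.integers(0, n_bins)] += 1
        centers = np.sort(rng.uniform(0, 255, n_bins))
        thr = otsu_from_histogram(counts, centers)
        # the threshold must achieve the brute-force minimum intra-class
        # variance (near-ties admit multiple equally optimal cuts)
        best = otsu_intraclass(counts, centers, otsu_bruteforce(counts, centers))
        achieved = otsu_intraclass(counts, centers, thr)
        assert achieved <= best * (1 + 1e-9)

    def test_constant_slice_names_slice(self):
        data = np.zeros((3, 4, 4))
        data[0] = np.arange(16).reshape(4, 4)
        data[2] = np.arange(16).reshape(4, 4)
        with pytest.raises(ValueError, match="slice 1"):
            otsu_threshold(VoxelStack(data, 0.025), mode="per_slice")

    def test_noise_free_phantom_reproduces_mask(self):
        spec = phantom.PhantomSpec(
            n_ridges=6, cross_extent_mm=1.2, noise_sd=0.0, grain_density=0.0
        )
        stack, truth = phantom.make_voxel_phantom(spec)
        binary = otsu_threshold(stack, mode="per_slice")
        assert np.array_equal(binary.labels, truth.mask)


class TestCleanBinary:
    def _wrap(self, labels):
        return BinaryStack(labels=labels, voxel_mm=0.025, threshold_used=np.array(0.5))

    def test_lone_voxel_removed(self):
        labels = np.zeros((7, 7, 7), dtype=bool)
        labels[3, 3, 3] = True
        out = clean_binary(self._wrap(labels), min_island_voxels=2,
                           smooth_radius_voxels=0)
        assert not out.labels.any()

    def test_large_component_untouched_without_smoothing(self):
        labels = np.zeros((9, 9, 9), dtype=bool)
        labels[2:7, 2:7, 2:7] = True
        out = clean_binary(self._wrap(labels), min_island_voxels=27,
                           smooth_radius_voxels=0)
        assert np.array_equal(out.labels, labels)

    def test_idempotent_on_own_output(self, small_voxel_spec):
        stack, _ = phantom.make_voxel_phantom(small_voxel_spec)
        binary = otsu_threshold(stack)
        once = clean_binary(binary)
        twice = clean_binary(once)
        assert np.array_equal(once.labels, twice.labels)

    def test_grain_phantom_small_islands_removed(self):
        spec = phantom.PhantomSpec(
            n_ridges=6, cross_extent_mm=1.5, grain_density=3.0, seed=8
        )
        stack, truth = phantom.make_voxel_phantom(spec)
        binary = otsu_threshold(stack)
        from scipy import ndimage

        struct = np.ones((3, 3, 3), bool)
        min_island = 27
        cleaned = clean_binary(binary, min_island_voxels=min_island)
        for phase in (True, False):
            comp, n = ndimage.label(cleaned.labels == phase, structure=struct)
            sizes = np.bincount(comp.ravel())[1:]
            assert (sizes >= min_island).all() or n <= 1


class TestExtractMesh:
    def test_cube_area_close_to_analytic(self):
        n = 32
        labels = np.zeros((n + 4, n + 4, n + 4), dtype=bool)
        labels[2:-2, 2:-2, 2:-2] = True  # n^3 cube in air
        voxel = 1.0 / n  # unit cube
        binary = BinaryStack(labels, voxel_mm=voxel, threshold_used=np.array(0.5))
        mesh = extract_mesh(binary, smooth_sigma_voxels=0.0)
        # marching cubes chamfers the 12 edges at one-voxel scale, an
        # O(voxel) perimeter deficit relative to the analytic 6 L^2
        assert mesh_area(mesh) == pytest.approx(6 * 1.0**2, rel=0.05)

    def test_single_phase_rejected(self):
        for fill in (False, True):
            labels = np.full((4, 4, 4), fill)
            binary = BinaryStack(labels, 0.1, np.array(0.5))
            with pytest.raises(ValueError, match="single-phase"):
                extract_mesh(binary)

    def test_vertices_in_mm_and_centered_on_voxels(self):
        labels = np.zeros((6, 6, 6), dtype=bool)
        labels[2:4, 2:4, 2:4] = True
        binary = BinaryStack(labels, voxel_mm=0.5, threshold_used=np.array(0.5))
        mesh = extract_mesh(binary, smooth_sigma_voxels=0.0)
        # interface lies between centres of voxel 1 (air) and 2 (clay)
        assert mesh.vertices.min() == pytest.approx(0.5 * 0.5 * (1 + 2), abs=0.26)


class TestMeshArea:
    def test_unit_square(self):
        mesh = SurfaceMesh(
            vertices=np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float),
            faces=np.array([[0, 1, 2], [0, 2, 3]]),
        )
        assert mesh_area(mesh) == pytest.approx(1.0)

    def test_additive_over_disjoint_copies(self):
        mesh = SurfaceMesh(
            vertices=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float),
            faces=np.array([[0, 1, 2]]),
        )
        shifted = mesh.translated([5.0, 0.0, 0.0])
        combined = SurfaceMesh(
            vertices=np.vstack([mesh.vertices, shifted.vertices]),
            faces=np.vstack([mesh.faces, shifted.faces + 3]),
        )
        assert mesh_area(combined) == pytest.approx(2 * mesh_area(mesh))

    def test_icosphere_approaches_analytic_sphere_area(self):
        ico = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        mesh = SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
        assert mesh_area(mesh) == pytest.approx(4 * np.pi, rel=0.01)

    def test_degenerate_triangle_warns_and_contributes_zero(self):
        mesh = SurfaceMesh(
            vertices=np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0]], float),
            faces=np.array([[0, 1, 2], [0, 1, 3]]),
        )
        with pytest.warns(UserWarning, match="degenerate"):
            area = mesh_area(mesh)
        assert area == pytest.approx(0.5)
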