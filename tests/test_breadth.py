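"""Transect intersection geometry and the two breadth definitions."""

import numpy as np
import pytest
from conftest import rotation_matrix
from oracles import ray_triangle_oracle

from creasemetry import phantom, relief
from creasemetry.breadth import (
    CreaseProfile,
    MeasurementLine,
    intersect_line_mesh,
    kamp_breadth,
    measure_impression,
    moller_trumbore,
    penrose_breadth,
)
from creasemetry.mesh import SurfaceMesh


class TestMollerTrumbore:
    tri = np.array([[[0, 0, 0], [1, 0, 0], [0, 1, 0]]], dtype=float)

    def test_straight_down_hit_at_known_distance(self):
        t = moller_trumbore(
            np.array([0.2, 0.2, 1.0]), np.array([0.0, 0.0, -1.0]), self.tri
        )
        assert len(t) == 1
        assert t[0] == pytest.approx(1.0, abs=1e-12)

    def test_ray_parallel_to_plane_misses(self):
        t = moller_trumbore(
            np.array([0.2, 0.2, 1.0]), np.array([1.0, 0.0, 0.0]), self.tri
        )
        assert len(t) == 0

    def test_backward_hits_rejected(self):
        t = moller_trumbore(
            np.array([0.2, 0.2, -1.0]), np.array([0.0, 0.0, -1.0]), self.tri
        )
        assert len(t) == 0

    def test_agrees_with_bruteforce_oracle_on_random_pairs(self):
        rng = np.random.default_rng(1234)
        n_checked = 0
        for k in range(1000):
            tri = rng.uniform(-1, 1, (3, 3))
            origin = rng.uniform(-2, 2, 3)
            if k % 2:  # aim at the triangle so real hits are exercised
                w = rng.dirichlet(np.ones(3))
                direction = w @ tri - origin
            else:
                direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            expected = ray_triangle_oracle(origin, direction, tri)
            got = moller_trumbore(origin, direction, tri[None])
            if expected is None:
                assert len(got) == 0
            else:
                assert len(got) == 1
                assert got[0] == pytest.approx(expected, abs=1e-9)
                n_checked += 1
        assert n_checked > 200  # sanity: the sample exercised real hits


class TestProfiles:
    def test_five_ridges_give_ten_intersections(self):
        spec = phantom.PhantomSpec(n_ridges=5, cross_extent_mm=1.2)
        mesh, truth = phantom.make_ridged_mesh(spec)
        patch = relief.fit_surface(mesh)
        profile = intersect_line_mesh(
            phantom.transect_lines(truth, 1, seed=0)[0], patch
        )
        assert len(profile.hits) == 10
        assert profile.crease_count == 5
        assert (np.diff(profile.hits) > 0).all()

    def test_missing_line_gives_empty_profile(self, ridged_patch_and_truth):
        patch, truth = ridged_patch_and_truth
        line = MeasurementLine(
            origin=truth.center + np.array([0.0, 100.0, 0.0]),
            direction=truth.ridge_normal,
            length=1.0,
        )
        profile = intersect_line_mesh(line, patch)
        assert len(profile.hits) == 0
        assert profile.crease_count == 0

    def test_non_unit_direction_normalized_with_warning(self):
        with pytest.warns(UserWarning, match="normaliz"):
            line = MeasurementLine(
                origin=np.zeros(3), direction=np.array([0.0, 0.0, 3.0]), length=1.0
            )
        assert np.linalg.norm(line.direction) == pytest.approx(1.0)


class TestKampBreadth:
    def test_span_over_pairs_arithmetic(self):
        hits = np.linspace(0.0, 2.5, 11)  # 5 complete ridge-furrow pairs
        profile = CreaseProfile(hits=hits, crease_count=5)
        assert kamp_breadth(profile) == pytest.approx(0.5)

    def test_too_few_crossings_rejected(self):
        profile = CreaseProfile(hits=np.array([0.0, 0.4]), crease_count=1)
        with pytest.raises(ValueError, match="pair"):
            kamp_breadth(profile)

    def test_sinusoid_recovers_period(self, ridged_patch_and_truth):
        patch, truth = ridged_patch_and_truth
        profile = intersect_line_mesh(
            phantom.transect_lines(truth, 1, seed=0)[0], patch
        )
        assert kamp_breadth(profile) == pytest.approx(
            truth.true_breadth_mm, rel=0.05
        )


class TestPenroseBreadth:
    def test_mean_trough_spacing(self):
        profile = CreaseProfile(
            hits=np.linspace(0, 1.5, 7),
            crease_count=3,
            trough_positions=np.array([0.0, 0.5, 1.0]),
        )
        assert penrose_breadth(profile) == pytest.approx(0.5)

    def test_single_trough_rejected(self):
        profile = CreaseProfile(
            hits=np.array([0.0, 0.5]),
            crease_count=1,
            trough_positions=np.array([0.25]),
        )
        with pytest.raises(ValueError, match="furrow centres"):
            penrose_breadth(profile)

    def test_definitions_agree_on_pure_sinusoid(self, ridged_patch_and_truth):
        patch, truth = ridged_patch_and_truth
        profile = intersect_line_mesh(
            phantom.transect_lines(truth, 1, seed=0)[0], patch
        )
        assert penrose_breadth(profile) == pytest.approx(
            kamp_breadth(profile), rel=0.05
        )


@pytest.fixture(scope="module")
def patch_truth():
    spec = phantom.PhantomSpec(n_ridges=8, cross_extent_mm=6.0)
    mesh, truth = phantom.make_ridged_mesh(spec)
    return relief.fit_surface(mesh), truth


class TestObliquity:
    """An oblique transect inflates breadth by 1/cos(angle)."""

    def _breadth_at(self, patch, truth, angle_deg):
        a = np.deg2rad(angle_deg)
        direction = np.cos(a) * truth.ridge_normal + np.sin(a) * truth.ridge_axis
        half = truth.transect_halflength * 0.7
        line = MeasurementLine(
            origin=truth.center - half * direction,
            direction=direction,
            length=2 * half,
        )
        return kamp_breadth(intersect_line_mesh(line, patch))

    @pytest.mark.parametrize("angle", [30, 60])
    def test_oblique_breadth_matches_secant_law(self, patch_truth, angle):
        patch, truth = patch_truth
        expected = truth.true_breadth_mm / np.cos(np.deg2rad(angle))
        assert self._breadth_at(patch, truth, angle) == pytest.approx(
            expected, rel=0.05
        )

    def test_breadth_increases_with_obliquity(self, patch_truth):
        patch, truth = patch_truth
        values = [self._breadth_at(patch, truth, a) for a in (0, 30, 60)]
        assert values[0] < values[1] < values[2]


class TestMeasureImpression:
    def test_identical_lines_average_to_single_run(self, ridged_patch_and_truth):
        patch, truth = ridged_patch_and_truth
        line = phantom.transect_lines(truth, 1, seed=0)[0]
        m = measure_impression(patch, [line, line, line], "kamp")
        assert len(m.run_values) == 3
        assert m.mcb == pytest.approx(m.run_values[0])
        assert m.mcb == pytest.approx(np.mean(m.run_values))

    def test_three_runs_recover_truth(self, ridged_patch_and_truth):
        patch, truth = ridged_patch_and_truth
        lines = phantom.transect_lines(truth, 3, seed=21)
        for definition in ("kamp", "penrose"):
            m = measure_impression(patch, lines, definition)
            assert m.mcb == pytest.approx(truth.true_breadth_mm, rel=0.05)
            assert m.mean_crease_count == pytest.approx(
                truth.true_crease_count, abs=1.0
            )

    def test_failing_run_is_named(self, ridged_patch_and_truth):
        patch, truth = ridged_patch_and_truth
        good = phantom.transect_lines(truth, 1, seed=0)[0]
        miss = MeasurementLine(
            origin=truth.center + np.array([0.0, 50.0, 0.0]),
            direction=truth.ridge_normal,
            length=1.0,
        )
        with pytest.raises(ValueError, match="run 2"):
            measure_impression(patch, [good, miss, good], "kamp")

    def test_unknown_definition_rejected(self, ridged_patch_and_truth):
        patch, truth = ridged_patch_and_truth
        with pytest.raises(ValueError, match="definition"):
            measure_impression(
                patch, phantom.transect_lines(truth, 1, seed=0), "fourier"
            )

    def test_rigid_motion_invariance(self):
        spec = phantom.PhantomSpec(n_ridges=6, cross_extent_mm=1.5)
        mesh, truth = phantom.make_ridged_mesh(spec)
        lines = phantom.transect_lines(truth, 3, seed=4)
        patch = relief.fit_surface(mesh)
        m0 = measure_impression(patch, lines, "kamp")

        R = rotation_matrix([0.3, 1.0, 0.2], np.deg2rad(20))
        shift = np.array([5.0, -2.0, 1.0])
        moved = SurfaceMesh(mesh.vertices @ R.T + shift, mesh.faces)
        moved_lines = [
            MeasurementLine(
                origin=R @ ln.origin + shift,
                direction=R @ ln.direction,
                length=ln.length,
            )
            for ln in lines
        ]
        m1 = measure_impression(relief.fit_surface(moved), moved_lines, "kamp")
        assert m1.mcb == pytest.approx(m0.mcb, abs=1e-6)
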