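import warnings

import numpy as np
import pytest

from creasemetry import phantom, relief


@pytest.fixture(autouse=True)
def _quiet_truncation_warnings():
    # transects legitimately end inside a crease on many phantoms
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="transect ends inside a crease"
        )
        yield


@pytest.fixture(scope="session")
def ridged_patch_and_truth():
    """Detrended reverse-cast patch from the default analytic ridge mesh."""
    spec = phantom.PhantomSpec(seed=7)
    mesh, truth = phantom.make_ridged_mesh(spec)
    patch = relief.invert_cast(relief.fit_surface(mesh))
    return patch, truth


@pytest.fixture(scope="session")
def small_voxel_spec():
    """A compact voxel phantom spec used by segmentation tests."""
    return phantom.PhantomSpec(
        ridge_period=0.5, n_ridges=6, cross_extent_mm=1.2, seed=11
    )


def mean_detrended_patch(mesh):
    """ReliefPatch whose residual is the raw height minus its mean.

    Bypasses the polynomial fit: for single-crease patches the crease IS
    the lowest-frequency content, so detrending would swallow it; the
    analytic oracle is the height field itself.
    """
    pts = mesh.vertices
    uv = pts[:, :2]
    z = pts[:, 2]
    return relief.ReliefPatch(
        points=pts,
        frame_origin=np.zeros(3),
        frame_axes=np.eye(3),
        uv=uv,
        uv_mid=uv.mean(axis=0),
        uv_half=np.ptp(uv, axis=0) / 2 + 1e-12,
        coeffs=np.zeros(relief.N_COEFFS),
        residuals=z - z.mean(),
        triangles=mesh.faces.copy(),
    )


def rotation_matrix(axis, angle_rad):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * K @ K
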