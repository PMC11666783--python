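import numpy as np
import pytest

from meiotrack.simulate import SceneConfig, render_scene, simulate_congression, simulate_mii_egg

VOXEL = (0.32, 0.1, 0.1)


@pytest.fixture(scope="session")
def mii_scene():
    """One rendered euploid porcine metaphase-II egg (default noise)."""
    cfg = SceneConfig(stage="metaphase_II", seed=101)
    gt = simulate_mii_egg(cfg)
    return render_scene(gt)


@pytest.fixture(scope="session")
def mi_truth_small():
    """Short noise-free metaphase-I ground truth (4 frames)."""
    cfg = SceneConfig(stage="metaphase_I", seed=7, n_frames=4, noise=False)
    return simulate_congression(cfg)


def gaussian_blob_image(shape, voxel_size, centers_um, sigma_um, amplitudes=None):
    """Sum of 3D Gaussian blobs on a voxel grid (test helper, independent of
    the package's renderer)."""
    img = np.zeros(shape)
    coords = [(np.arange(n) + 0.5) * s for n, s in zip(shape, voxel_size)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij", sparse=True)
    sigma = np.broadcast_to(np.asarray(sigma_um, dtype=float), (3,))
    if amplitudes is None:
        amplitudes = [1.0] * len(centers_um)
    for c, a in zip(centers_um, amplitudes):
        img += a * np.exp(-(((zz - c[0]) / sigma[0]) ** 2
                            + ((yy - c[1]) / sigma[1]) ** 2
                            + ((xx - c[2]) / sigma[2]) ** 2) / 2.0)
    return img
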