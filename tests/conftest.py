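"""Shared fixtures: all volumes are generated programmatically at test time.

Most image-based tests run at half/coarse resolution (1.02 mm in-plane,
1.5 mm slices on a 256^2 grid) to keep the suite fast; the MTF tests use
analytically blurred cube volumes at the native 0.51 mm pitch where the
sampling geometry actually matters.
"""

from __future__ import annotations

import numpy as np
import pytest

import lungqct as lq

COARSE_SPACING = (1.02, 1.02, 1.5)
COARSE_SHAPE = (256, 256, 100)


@pytest.fixture(scope="session")
def layout_i():
    return lq.build_layout("i")


@pytest.fixture(scope="session")
def coarse_truth_i(layout_i):
    """Noiseless configuration-i phantom at coarse resolution."""
    return lq.rasterize(layout_i, spacing=COARSE_SPACING,
                        grid_shape=COARSE_SHAPE, texture_seed=7)


@pytest.fixture(scope="session")
def coarse_scan_i(coarse_truth_i):
    """Simulated reference-noise scan of configuration i."""
    truth, labels = coarse_truth_i
    scan = lq.simulate_scan(truth, lq.AcquisitionModel(seed=11))
    return scan, labels


@pytest.fixture(scope="session")
def layout_iv():
    return lq.build_layout("iv")


@pytest.fixture(scope="session")
def coarse_scan_iv(layout_iv):
    truth, labels = lq.rasterize(layout_iv, spacing=COARSE_SPACING,
                                 grid_shape=(256, 256, 140), texture_seed=3)
    scan = lq.simulate_scan(truth, lq.AcquisitionModel(seed=5))
    return scan, labels, truth


@pytest.fixture(scope="session")
def uniform_noise_volume():
    """Pure white-noise volume for NPS estimator tests."""
    rng = np.random.default_rng(42)
    vox = rng.normal(0.0, 10.0, (160, 160, 40))
    vol = lq.VoxelVolume(vox, spacing=(0.5, 0.5, 0.5))
    mask = lq.ROIMask("uniform", np.ones(vol.shape, dtype=bool))
    return vol, mask
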