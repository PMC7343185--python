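import numpy as np
import pytest

import prfval as pv


@pytest.fixture(scope="session")
def grid():
    return pv.make_grid()


@pytest.fixture(scope="session")
def sweep_stimulus(grid):
    """The default bar-sweep stimulus (101 x 101 x 200, 20 deg field)."""
    return pv.generate_aperture(pv.BarSweepSpec(), grid)


@pytest.fixture(scope="session")
def canonical_hrf():
    return pv.HRFSpec()


@pytest.fixture(scope="session")
def fig_truth():
    """The reference ground-truth pRF: circular, center (3, 3) deg, 2 deg radius."""
    return pv.GaussianPRF(x0=3.0, y0=3.0, sigma_major=2.0, gain=1.0)


@pytest.fixture(scope="session")
def noise_free_voxel(fig_truth, sweep_stimulus, canonical_hrf):
    return pv.synthesize_voxel(
        fig_truth, sweep_stimulus, canonical_hrf, pv.noise_preset("none")
    )


@pytest.fixture(scope="session")
def small_grid():
    return pv.make_grid(10.0, 21)
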