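import numpy as np
import pytest

import ewa


@pytest.fixture(scope="session")
def default_phantom():
    """One default phantom shared by read-only tests."""
    return ewa.generate(ewa.PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, blur-free, flat-coil phantom: every stage is exact."""
    spec = ewa.PhantomSpec(noise_sd=0.0, psf_sd_mm=0.0,
                           coil_coeffs=(1, 0, 0, 0, 0, 0), seed=5)
    return ewa.generate(spec)


def annulus_segmentation(n_slices=3, grid=48, endo_r=8.0, epi_r=14.0):
    """Small circular-annulus LV segmentation for unit tests."""
    c = (grid - 1) / 2
    th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    endo = {s: np.column_stack([c + endo_r * np.cos(th),
                                c + endo_r * np.sin(th)])
            for s in range(n_slices)}
    epi = {s: np.column_stack([c + epi_r * np.cos(th),
                               c + epi_r * np.sin(th)])
           for s in range(n_slices)}
    return ewa.LVSegmentation.from_contours(endo, epi, (n_slices, grid, grid))


@pytest.fixture()
def small_seg():
    return annulus_segmentation()
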