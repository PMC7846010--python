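"""Shared fixtures for the nanolayers test suite.

Heavy fixtures are session-scoped so expensive simulations (SRRF
stacks, membrane pairs) are built once and shared.
"""

from __future__ import annotations

import numpy as np
import pytest

from nanolayers import synthgen

PSF_SIGMA_NM = 120.0
PIXEL_NM = 100.0
FWHM_NM = 2.0 * np.sqrt(2.0 * np.log(2.0)) * PSF_SIGMA_NM
QUIET = synthgen.NoiseSpec(poisson=False, read_sigma=0.0, background=0.0)


@pytest.fixture(scope="session")
def two_point_stack():
    """100-frame blinking stack of two emitters at 0.6 x FWHM separation."""
    sep = 0.6 * FWHM_NM
    window = 2400.0
    cx = window / 2.0
    pos = np.array([[cx - sep / 2, cx], [cx + sep / 2, cx]])
    field = synthgen.EmitterField(pos, brightness=500.0, on_probability=0.3,
                                  window_nm=(window, window),
                                  on_dwell_frames=3.0)
    noise = synthgen.NoiseSpec(poisson=True, read_sigma=1.0, background=5.0)
    stack = synthgen.simulate_blinking_stack(
        field, 100, PSF_SIGMA_NM, PIXEL_NM, noise=noise, seed=7)
    return stack, pos


@pytest.fixture(scope="session")
def csr_curve_ensemble():
    """200 delta-rasterized CSR fields, each analyzed against its own
    100-permutation null: the calibration ensemble for envelope coverage
    and K-tilde variance checks."""
    from nanolayers import ripley

    grid = ripley.RadiusGrid(25.0, 400.0)
    curves = []
    for seed in range(200):
        spec = synthgen.PointProcessSpec(
            kind="csr", window_um=(1.6, 1.6), intensity_per_um2=60.0,
            seed=1000 + seed)
        img = synthgen.simulate_point_field(spec, 0.0, 25.0, brightness=1.0)
        curves.append(ripley.analyze_field(
            ripley.IntensityField.from_image(img), grid,
            n_simulations=100, seed=seed))
    return curves


@pytest.fixture(scope="session")
def deformed_membrane_pair():
    """One two-channel membrane pair, test layer at -26 nm, with noise."""
    model = synthgen.MembraneModel(
        window_nm=(10_000.0, 5_000.0), layer_offsets_nm=(0.0, -26.0),
        deformation_amplitude_nm=200.0,
        deformation_correlation_length_nm=1000.0,
        emitter_density_per_um=50.0, brightness=200.0)
    noise = synthgen.NoiseSpec(poisson=True, read_sigma=1.0, background=2.0)
    return synthgen.simulate_membrane_pair(
        model, psf_sigma_nm=40.0, pixel_size_nm=25.0, seed=11, noise=noise)
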