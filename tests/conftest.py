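"""Shared fixtures: parametric phantom factory used across the imaging tests."""

import numpy as np
import pytest

from ssn_poro import BoundaryStress, PhantomConfig, PressureProfileParams, generate_ssc_map


@pytest.fixture
def phantom_factory():
    """Build a centered spherical-inclusion SSc map phantom.

    Returns a callable ``make(alpha, snr_db, seed, radius_px=32, pad_px=4)``
    yielding ``(map, center_mm, radius_mm, truth)``.  Defaults: pixel spacing
    0.125 mm, boundary stress -1 kPa, amplitude Psi = 1 kPa, zero background.
    """

    def make(alpha, snr_db=np.inf, seed=0, radius_px=32, pad_px=4, psi_kpa=1.0, s_rr_a=-1.0):
        pixel_mm = 0.125  # binary-exact spacing keeps the geometry exactly symmetric
        a_mm = radius_px * pixel_mm
        center = (a_mm + pad_px * pixel_mm, a_mm + pad_px * pixel_mm)
        shape = (2 * radius_px + 2 * pad_px + 1, 2 * radius_px + 2 * pad_px + 1)
        cfg = PhantomConfig(
            grid_shape=shape,
            pixel_mm=pixel_mm,
            center_mm=center,
            radius_mm=a_mm,
            pressure=PressureProfileParams(alpha=alpha, psi_kpa=psi_kpa, a_mm=a_mm),
            boundary=BoundaryStress(s_RR_a=s_rr_a, s_thth_a=s_rr_a),
            background_value_kpa=0.0,
            snr_db=snr_db,
            seed=seed,
        )
        smap, truth = generate_ssc_map(cfg)
        return smap, center, a_mm, truth

    return make
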