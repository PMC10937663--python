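"""Shared fixtures: small phantoms exercising every pipeline stage."""

import numpy as np
import pytest

from octl.phantom import PhantomSpec, Vessel, make_calibration_volume


def ideal_spec(**overrides) -> PhantomSpec:
    """Noiseless, flat-response phantom spec for analytic checks.

    The noise floor is pushed to -120 dB so the rendered signal is the
    pure single-scattering decay over the whole fit window.
    """
    defaults = dict(
        shape=(8, 8, 256),
        axial_pitch_um=5.46875,
        lateral_pitch_um=(10.0, 10.0),
        mu_t=2.0,
        speckle_contrast=0.0,
        source_level_db=45.0,
        noise_floor_db=-120.0,
        confocal_rayleigh_um=1e12,
        rolloff_db_per_mm=0.0,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


def realistic_spec(**overrides) -> PhantomSpec:
    """Speckled phantom spec with the default system response."""
    defaults = dict(
        shape=(64, 32, 384),
        axial_pitch_um=5.46875,
        lateral_pitch_um=(10.0, 10.0),
        mu_t=4.0,
        speckle_contrast=1.0,
        source_level_db=45.0,
        surface_offset_px=20,
        seed=7,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


def straight_tube(x: float, z: float, ny: int, radius_um: float = 50.0,
                  deficit_db: float = 15.0) -> Vessel:
    """A horizontal cylinder along y at lateral position x, depth z."""
    return Vessel(
        centerline=np.array([[x, 0.0, z], [x, ny - 1.0, z]]),
        radius_um=radius_um,
        deficit_db=deficit_db,
    )


@pytest.fixture(scope="session")
def flat_calibration():
    """Noiseless calibration scan with zero attenuation and flat response.

    With the noise floor pushed far below the signal the absolute dB scale
    is already the noise-referenced one, so the volume is marked
    normalized.
    """
    vol = make_calibration_volume(ideal_spec(mu_t=0.0))
    vol.noise_normalized = True
    return vol
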