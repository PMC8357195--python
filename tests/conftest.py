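import numpy as np
import pytest

from drslut import (
    build_lut,
    generate_calibration_set,
    generate_validation_set,
    load_extinction_table,
)
from drslut.phantoms import (
    PIXELS_PER_NM,
    channel_noise_sigma,
    forward_reflectance,
    simulate_liftoff,
)

STUDY_SEED = 7
SDS_CHANNELS = (0.75, 2.00, 3.00, 4.00)


@pytest.fixture(scope="session")
def ext_table():
    return load_extinction_table()


@pytest.fixture(scope="session")
def calibration_noiseless():
    return generate_calibration_set(seed=0, snr_db=None)


@pytest.fixture(scope="session")
def study():
    """Full noisy synthetic study inputs at the standard conditions.

    Calibration and validation phantom sets at the 15-dB SNR floor with
    five-spectrum averaging, and the per-SDS lookup tables built from the
    calibration spectra.  Shared across test modules because the build and
    the 36 validation fits are the expensive part of the suite.
    """
    cal = generate_calibration_set(seed=STUDY_SEED, sds_mm=SDS_CHANNELS)
    val = generate_validation_set(seed=STUDY_SEED + 1, sds_mm=SDS_CHANNELS)
    luts = {}
    for sds in SDS_CHANNELS:
        clean = [forward_reflectance(r.musp, r.mua, sds) for r in cal.recipes]
        sigma = channel_noise_sigma(clean, 15.0) / np.sqrt(5 * PIXELS_PER_NM)
        luts[sds] = build_lut(
            [(r, cal.spectrum(r.label, sds)) for r in cal.recipes],
            sds,
            noise_sigma=sigma,
        )
    return {"calibration": cal, "validation": val, "luts": luts}


@pytest.fixture(scope="session")
def validation_report(study):
    from drslut.inverse import validate_luts

    return validate_luts(study["validation"], study["luts"])


@pytest.fixture(scope="session")
def liftoff_curves(calibration_noiseless):
    """Liftoff simulations for a representative subset of recipes/channels."""
    cal = calibration_noiseless
    out = {}
    for sds in SDS_CHANNELS:
        for recipe in cal.recipes:
            out[(recipe.label, sds)] = simulate_liftoff(recipe, sds)
    return cal, out
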