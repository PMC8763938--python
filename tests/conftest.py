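import numpy as np
import pytest

from dualpath import synthgen


@pytest.fixture
def fast_photometry_cfg():
    """Desk-scale session: 20 s at 5 kHz (10x the 500 Hz carrier)."""
    return synthgen.SynthPhotometryConfig(
        duration=20.0,
        fs_raw=5_000.0,
        transient_rate=0.3,
        noise_sd=0.0,
        autofluor_gain=0.0,
        bleach_poly_coeffs=(2.0, -0.4, 0.1, 0.0),
        seed=7,
    )


@pytest.fixture
def clean_session(fast_photometry_cfg):
    return synthgen.gen_photometry_session(fast_photometry_cfg)


@pytest.fixture
def default_cellmap():
    return synthgen.gen_cellmap(synthgen.SynthCellMapConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(123)
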