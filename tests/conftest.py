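import numpy as np
import pytest

import laurdanspec as ls


@pytest.fixture(scope="session")
def grid():
    """Default acquisition grid: 400-600 nm at 0.4 nm spacing."""
    return np.arange(400.0, 600.0 + 1e-9, 0.4)


@pytest.fixture(scope="session")
def dehydration_set():
    """Noise-free dehydration preset, one spot per condition."""
    cfg = ls.make_config("dehydration", spots=1, noise=False, seed=11)
    sset, truth = ls.generate(cfg)
    return sset, truth


@pytest.fixture(scope="session")
def cholesterol_set():
    cfg = ls.make_config("cholesterol", spots=1, noise=False, seed=11)
    sset, truth = ls.generate(cfg)
    return sset, truth


@pytest.fixture(scope="session")
def dehydration_global(dehydration_set):
    """Global fit of the noise-free dehydration series (shared peaks)."""
    sset, _ = dehydration_set
    return ls.fit_global(sset)


def make_two_band(i_long=1.0, i_short=1.0, peak_long_nm=475.0, peak_short_nm=427.0,
                  h_long=3400.0, h_short=2800.0, rho_long=1.3, rho_short=1.2):
    return ls.TwoBandModel(
        band_long=ls.LogNormalBand.from_shape(i_long, 1e7 / peak_long_nm,
                                              h_long, rho_long),
        band_short=ls.LogNormalBand.from_shape(i_short, 1e7 / peak_short_nm,
                                               h_short, rho_short),
    )
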