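import numpy as np
import pytest

from ctthermo import PhantomConfig, synthesize_series


@pytest.fixture(scope="session")
def noiseless_cfg():
    """Small clean phantom: no noise, motion, gas, or probe; 2-scan upslope."""
    return PhantomConfig(
        shape=(80, 80, 40),
        noise_sd_hu=0.0,
        gas_enabled=False,
        probe_radius_mm=0.0,
        motion_sd_mm=0.0,
        n_upslope=2,
        upslope_interval_s=300.0,
        n_post=0,
        sigma_mm_at_peak=10.0,
    )


@pytest.fixture(scope="session")
def noiseless_case(noiseless_cfg):
    """(cfg, series, trace, truth) for the clean two-scan phantom."""
    series, trace, truth = synthesize_series(noiseless_cfg)
    return noiseless_cfg, series, trace, truth


@pytest.fixture(scope="session")
def full_noiseless_cfg():
    """Clean phantom with the full 10+10 scan protocol and a probe."""
    return PhantomConfig(
        shape=(64, 64, 40),
        noise_sd_hu=0.0,
        gas_enabled=False,
        probe_radius_mm=1.0,
        motion_sd_mm=0.0,
        sigma_mm_at_peak=8.0,
    )


@pytest.fixture(scope="session")
def full_noiseless_case(full_noiseless_cfg):
    series, trace, truth = synthesize_series(full_noiseless_cfg)
    return full_noiseless_cfg, series, trace, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20231114)
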