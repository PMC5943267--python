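"""Shared fixtures: tiny handmade streams and cached simulated acquisitions.

Simulated streams are session-scoped because the Monte-Carlo generator is
the expensive part of the suite; every test that can share a stream does.
"""

import numpy as np
import pytest

from fpfa.photons import AcquisitionMeta, PhotonStream
from fpfa.simulate import SimConfig, simulate_stream


@pytest.fixture()
def meta():
    return AcquisitionMeta(sync_rate_hz=80e6, macro_tick_s=12.5e-9,
                           micro_bin_ns=12.5 / 1024, duration_s=1.0,
                           dark_cps=0.0, label="fixture")


@pytest.fixture()
def tiny_stream(meta):
    """Six handmade photons, three per channel, sorted macro times."""
    return PhotonStream(
        macro_time=np.array([0, 10, 1000, 2000, 64_000_000, 64_000_010]),
        micro_time=np.array([0, 511, 100, 1023, 5, 900]),
        channel=np.array([0, 1, 0, 1, 0, 1]),
        meta=meta,
    )


def _venus_config(**overrides):
    base = dict(duration_s=5.0, seed=2024, r0=0.38, r_inf=0.05)
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def venus_config():
    return _venus_config()


@pytest.fixture(scope="session")
def venus_stream(venus_config):
    """5 s Venus-homogenate-like acquisition (~2e5 photons)."""
    return simulate_stream(venus_config)


@pytest.fixture(scope="session")
def fluorescein_config():
    return SimConfig(n_molecules_mean=20, D_um2_s=436.0, eta_cpms=2500.0,
                     lifetime_components=((1.0, 4.0),), r0=0.38,
                     theta_rot_ns=0.15, r_inf=0.0, duration_s=5.0,
                     seed=77, dark_cps=300.0)


@pytest.fixture(scope="session")
def fluorescein_stream(fluorescein_config):
    """Fast-rotor diffusion-standard acquisition for g / omega calibration."""
    return simulate_stream(fluorescein_config)
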