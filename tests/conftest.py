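import numpy as np
import pytest

from slabkq.protocol import SamplingConfig, build_protocol, generate_caipi_masks


@pytest.fixture(scope="session")
def protocol66():
    """The full 3-shell, 22-direction protocol at scanner geometry."""
    return build_protocol([1000.0, 2000.0, 6000.0], 22)


@pytest.fixture(scope="session")
def protocol66_small():
    """3-shell, 22-direction protocol matched to the small test phantom."""
    return build_protocol([1000.0, 2000.0, 6000.0], 22, Ny=33, FOVz=6.0)


@pytest.fixture(scope="session")
def protocol_mde():
    """B-tensor-diverse protocol (one spherical-encoding shell) that makes
    the compartment fit globally identifiable."""
    return build_protocol([1000.0, 2000.0, 6000.0, 3000.0],
                          [22, 22, 22, 12], betas=[1.0, 1.0, 1.0, 0.0],
                          Ny=33, FOVz=6.0)


@pytest.fixture(scope="session")
def protocol_tiny():
    """6-volume protocol for operator-level tests."""
    return build_protocol([1000.0, 2000.0, 6000.0], [2, 2, 2],
                          Ny=33, FOVz=6.0)


@pytest.fixture(scope="session")
def caipi_cfg():
    return SamplingConfig(seed=0)


@pytest.fixture(scope="session")
def masks66(protocol66, caipi_cfg):
    return generate_caipi_masks(protocol66, caipi_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
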