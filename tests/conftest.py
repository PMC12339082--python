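"""Shared fixtures: small synthetic phantoms kept fast for unit tests."""

import numpy as np
import pytest

from osteoquant.pipeline import RunConfig
from osteoquant.synthetic import SyntheticConfig, generate_bone_image


def small_config(**overrides) -> SyntheticConfig:
    """A narrow, short phantom (~700×300 px) that still has every zone."""
    defaults = dict(
        image_width_px=520,  # wide enough for several secondary-spongiosa rods
        metaphysis_um=700.0,  # full primary band + a short secondary stretch
        epiphysis_um=200.0,
        subchondral_plate_um=25.0,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_phantom(small_cfg):
    """(raw, ground_truth) for the default small noisy phantom."""
    return generate_bone_image(small_cfg, seed=101)


@pytest.fixture(scope="session")
def noisefree_phantom():
    cfg = small_config(noise_gl_sd=0.0)
    return cfg, generate_bone_image(cfg, seed=102)


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
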