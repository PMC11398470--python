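"""Shared fixtures: small synthetic libraries and screens.

Everything is generated programmatically from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

import ciberseq as cs


@pytest.fixture(scope="session")
def small_cfg() -> cs.SimConfig:
    """A small, clean screen: no sequencing noise, Poisson counts."""
    return cs.SimConfig(seed=7, n_constructs=30, n_nontargeting=3, depth=30_000,
                        substitution_error_rate=0.0, pcr_duplication_rate=0.0,
                        dispersion=0.0)


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return cs.simulate_library(small_cfg)


@pytest.fixture(scope="session")
def small_screen(small_cfg, small_truth):
    return cs.simulate_screen(small_truth, small_cfg)


@pytest.fixture(scope="session")
def noisy_cfg() -> cs.SimConfig:
    """A small screen with realistic noise: errors, duplicates, NB counts."""
    return cs.SimConfig(seed=19, n_constructs=40, n_nontargeting=4, depth=60_000,
                        substitution_error_rate=0.005, pcr_duplication_rate=0.5,
                        dispersion=0.05, baseline_bias_sd=0.35)


@pytest.fixture(scope="session")
def noisy_screen(noisy_cfg):
    truth = cs.simulate_library(noisy_cfg)
    return cs.simulate_screen(truth, noisy_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
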