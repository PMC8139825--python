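"""Shared fixtures: small synthetic sessions and raster builders."""
import numpy as np
import pandas as pd
import pytest

from gctaste import GeneratorConfig, generate_ensemble
from gctaste.datamodel import TASTES


@pytest.fixture(scope="session")
def default_dataset():
    """Default taste-specific ensemble: 10 units, 30 trials/taste."""
    return generate_ensemble(GeneratorConfig.taste_specific(10, rng_seed=1))


@pytest.fixture(scope="session")
def null_dataset():
    """Taste-nonspecific ensemble (chance-level decodable)."""
    return generate_ensemble(GeneratorConfig.null(10, rng_seed=1))


@pytest.fixture(scope="session")
def trial_table_120():
    """Canonical 120-trial table: 30/taste, alternating 15 Off + 15 On."""
    tastes = np.repeat(TASTES, 30)
    laser = np.tile(np.r_[np.zeros(15, bool), np.ones(15, bool)], 4)
    return pd.DataFrame(
        {"trial_index": np.arange(120), "taste": tastes, "laser_on": laser}
    )


def bernoulli_raster(rate_profile_hz, n_trials, rng):
    """Binary raster (n_trials x 4500) from a 1-ms rate profile in Hz."""
    p = np.asarray(rate_profile_hz, float) * 1e-3
    return (rng.random((n_trials, p.size)) < p[None, :]).astype(np.uint8)


def unit_raster_off_on(off_hz, on_hz, laser_flags, rng, evoked_only=True,
                       baseline_hz=None, onset_ms=0):
    """Raster for one unit whose evoked rate differs by laser condition.

    Rates apply from ``onset_ms`` after stimulus delivery (before it, the
    Off rate applies over the evoked period); baseline rate (default the Off
    rate) fills the 2-s pre-stimulus period unless ``evoked_only``.
    """
    n = laser_flags.size
    x = np.zeros((n, 4500), dtype=np.uint8)
    base = off_hz if baseline_hz is None else baseline_hz
    if not evoked_only:
        x[:, :2000] = rng.random((n, 2000)) < base * 1e-3
    i_on = 2000 + int(onset_ms)
    pre = np.full((n, i_on - 2000), off_hz * 1e-3)
    post = np.where(laser_flags[:, None], on_hz, off_hz)[:, :1] * 1e-3
    x[:, 2000:i_on] = rng.random(pre.shape) < pre
    x[:, i_on:] = rng.random((n, 4500 - i_on)) < post
    return x
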