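"""Thin seeded wrapper around emcee's affine-invariant ensemble sampler.

All Bayesian stages (hierarchical Poisson GLM, logistic-curve fits) sample
their posteriors through :func:`sample_posterior`, which fixes the walker
initialization and the sampler's random state so that results are
reproducible for a given seed.
"""
from __future__ import annotations

import numpy as np
import emcee

__all__ = ["sample_posterior"]


def sample_posterior(
    log_prob,
    center: np.ndarray,
    scales: np.ndarray,
    n_walkers: int,
    n_burn: int,
    n_steps: int,
    seed: int,
    thin: int = 1,
):
    """Run an ensemble MCMC and return (flat_samples, mean_acceptance).

    ``log_prob`` must accept a (n_walkers, ndim) array and return a
    (n_walkers,) array of log posterior densities (vectorized).  Walkers
    start in a Gaussian ball around ``center`` with per-dimension ``scales``.
    """
    center = np.asarray(center, float)
    scales = np.asarray(scales, float)
    ndim = center.size
    rng = np.random.RandomState(seed % (2**31 - 1))
    p0 = center[None, :] + scales[None, :] * rng.standard_normal((n_walkers, ndim))
    # make sure every walker starts at finite log-probability
    lp = log_prob(p0)
    for _ in range(100):
        bad = ~np.isfinite(lp)
        if not bad.any():
            break
        p0[bad] = center[None, :] + 0.1 * scales[None, :] * rng.standard_normal(
            (int(bad.sum()), ndim)
        )
        lp = log_prob(p0)
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob, vectorize=True)
    sampler.random_state = rng.get_state()
    state = sampler.run_mcmc(p0, n_burn, skip_initial_state_check=True)
    sampler.reset()
    sampler.run_mcmc(state, n_steps, skip_initial_state_check=True)
    flat = sampler.get_chain(flat=True, thin=thin)
    return flat, float(np.mean(sampler.acceptance_fraction))
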