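"""Poisson ensemble hidden Markov models and trial realignment.

The ensemble's trial-by-trial dynamics are modeled as a discrete latent
state sequence: each hidden state is a vector of per-unit firing rates, and
within a state every unit emits spike counts independently as Poisson in
small (default 10 ms) bins.  Baum-Welch EM fits the initial distribution,
the (unconstrained) state-transition matrix, and the emission-rate vectors
to the trials of one taste x laser condition; the forward-backward recursion
then yields smoothed posterior state probabilities per trial.

The "palatability" state is identified as the state with the greatest mean
posterior mass over 500-1500 ms post-stimulus (the window where hedonic
correlations asymptote); its per-trial onset is the first time its posterior
reaches 0.5.  Re-zeroing every trial to that onset exposes the sharp
single-trial transition that stimulus-aligned averages blur.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .datamodel import EnsembleDataset, _normalize_condition

__all__ = [
    "HmmModel",
    "TrialAlignment",
    "RealignedRasters",
    "fit_hmm",
    "fit_taste_hmm",
    "decode",
    "identify_palatability_state",
    "transition_onset",
    "compute_alignment",
    "realign",
]

_RATE_FLOOR = 1e-6


@dataclass
class HmmModel:
    """A fitted ensemble HMM.

    ``rates`` are expected spike counts per emission bin (state x unit);
    divide by ``emission_bin_ms``/1000 for Hz.  ``t_start_ms`` is the time
    of the left edge of the first emission bin.
    """

    n_states: int
    initial: np.ndarray
    transition: np.ndarray
    rates: np.ndarray
    emission_bin_ms: float
    t_start_ms: float
    loglik_trace: np.ndarray
    converged: bool
    restart_index: int
    seed: int
    restart_logliks: np.ndarray | None = None

    def __post_init__(self):
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(self.rates < 0):
            raise ValueError("emission rates must be non-negative")
        if np.any(np.diff(self.loglik_trace) < -1e-6):
            raise ValueError("EM log-likelihood decreased")

    @property
    def rates_hz(self) -> np.ndarray:
        return self.rates / (self.emission_bin_ms / 1000.0)


def _log_emission(counts: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """logB[r, s, t] for counts (R, U, T) under per-unit Poisson rates (S, U)."""
    lam = np.maximum(rates, _RATE_FLOOR)
    # (R, 1, U, T) x (1, S, U, 1)
    ll = (
        counts[:, None, :, :] * np.log(lam)[None, :, :, None]
        - lam[None, :, :, None]
        - gammaln(counts + 1.0)[:, None, :, :]
    )
    return ll.sum(axis=2)  # (R, S, T)


def _forward_backward(logB: np.ndarray, pi: np.ndarray, A: np.ndarray):
    """Scaled forward-backward, vectorized over trials.

    Returns (gamma (R,S,T), xi_sum (S,S), loglik_per_trial (R,)).
    """
    R, S, T = logB.shape
    m = logB.max(axis=1, keepdims=True)          # (R,1,T)
    B = np.exp(logB - m)
    alpha = np.empty((R, S, T))
    c = np.empty((R, T))
    a = pi[None, :] * B[:, :, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, :, 0] = a / c[:, [0]]
    for t in range(1, T):
        a = (alpha[:, :, t - 1] @ A) * B[:, :, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, :, t] = a / c[:, [t]]
    beta = np.empty((R, S, T))
    beta[:, :, T - 1] = 1.0
    xi_sum = np.zeros((S, S))
    for t in range(T - 2, -1, -1):
        bb = B[:, :, t + 1] * beta[:, :, t + 1]
        beta[:, :, t] = (bb @ A.T) / c[:, [t + 1]]
        # xi_t[r, i, j] = alpha[r,i,t] A[i,j] bb[r,j] / c[r,t+1]
        xi_sum += np.einsum("ri,rj->ij", alpha[:, :, t], bb / c[:, [t + 1]]) * A
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = np.log(c).sum(axis=1) + m[:, 0, :].sum(axis=1)
    return gamma, xi_sum, loglik


def _em_run(counts, n_states, pi0, A0, rates0, max_iter, tol):
    pi, A, rates = pi0.copy(), A0.copy(), rates0.copy()
    trace = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        logB = _log_emission(counts, rates)
        gamma, xi_sum, ll_trials = _forward_backward(logB, pi, A)
        ll = float(ll_trials.sum())
        trace.append(ll)
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
        # M step
        pi = gamma[:, :, 0].mean(axis=0)
        pi = pi / pi.sum()
        A = xi_sum / np.maximum(xi_sum.sum(axis=1, keepdims=True), 1e-300)
        occ = gamma.sum(axis=(0, 2))                       # (S,)
        num = np.einsum("rst,rut->su", gamma, counts)      # (S, U)
        rates = np.maximum(num / np.maximum(occ[:, None], 1e-300), _RATE_FLOOR)
    return pi, A, rates, np.array(trace), converged


def fit_hmm(
    counts: np.ndarray,
    n_states: int = 4,
    emission_bin_ms: float = 10.0,
    restarts: int = 20,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    t_start_ms: float = 0.0,
) -> HmmModel:
    """Baum-Welch fit to binned spike counts (trials x units x bins).

    Emissions are independent Poisson per unit per bin.  The best of
    ``restarts`` random initializations (by final log-likelihood) wins;
    identical seed gives identical output.  Non-convergent runs return the
    best iterate, flagged via ``converged``.
    """
    counts = np.asarray(counts, float)
    if counts.ndim != 3:
        raise ValueError("counts must be trials x units x bins")
    R, U, T = counts.shape
    if R < 5:
        raise ValueError("need at least 5 trials")
    if n_states < 2:
        raise ValueError("need at least 2 states")
    rng = np.random.default_rng(seed)

    # initialize state rates from contiguous temporal segments of the mean
    # response (states unfold in time), jittered across restarts; alternate
    # equal-width edges with front-compressed ones (early response phases
    # are short relative to the late ones)
    def seg_rates(power: float) -> np.ndarray:
        fr = (np.arange(n_states + 1) / n_states) ** power
        edges = np.unique((fr * T).astype(int))
        while edges.size < n_states + 1:  # guard tiny T
            edges = np.unique(np.r_[edges, edges[-1] + 1])
        return np.stack(
            [
                np.maximum(counts[:, :, a:b].mean(axis=(0, 2)), _RATE_FLOOR)
                for a, b in zip(edges[:-1], edges[1:])
            ]
        )

    seg = {1.0: seg_rates(1.0), 1.7: seg_rates(1.7)}
    best = None
    finals: list[float] = []
    for r in range(restarts):
        pi0 = rng.dirichlet(np.full(n_states, 5.0))
        A0 = np.full((n_states, n_states), 0.05 / max(n_states - 1, 1))
        np.fill_diagonal(A0, 0.95)
        base = seg[1.0] if r % 2 == 0 else seg[1.7]
        rates0 = base * rng.lognormal(0.0, 0.25, (n_states, U))
        fit = _em_run(counts, n_states, pi0, A0, rates0, max_iter, tol)
        finals.append(fit[3][-1])
        if best is None or fit[3][-1] > best[0][3][-1]:
            best = (fit, r)
    (pi, A, rates, trace, converged), r_best = best
    return HmmModel(
        n_states=n_states,
        initial=pi,
        transition=A,
        rates=rates,
        emission_bin_ms=emission_bin_ms,
        t_start_ms=t_start_ms,
        loglik_trace=trace,
        converged=converged,
        restart_index=r_best,
        seed=seed,
        restart_logliks=np.array(finals),
    )


def fit_taste_hmm(
    dataset: EnsembleDataset,
    taste: str,
    laser,
    window: tuple[float, float] = (0.0, 2000.0),
    n_states: int = 4,
    emission_bin_ms: float = 10.0,
    restarts: int = 20,
    seed: int = 0,
    **kwargs,
) -> HmmModel:
    """Fit an HMM to the trials of one taste in one laser condition."""
    mask = dataset.trial_mask(taste=taste, laser=laser)
    counts = dataset.bin_counts(window, int(emission_bin_ms), trials=mask)
    return fit_hmm(
        counts,
        n_states=n_states,
        emission_bin_ms=emission_bin_ms,
        restarts=restarts,
        seed=seed,
        t_start_ms=window[0],
        **kwargs,
    )


def decode(model: HmmModel, counts: np.ndarray) -> np.ndarray:
    """Smoothed posterior state probabilities for one trial.

    ``counts`` is (units x bins) on the model's emission grid; the returned
    posterior is (states x bins) and each column sums to 1.
    """
    counts = np.asarray(counts, float)
    if counts.ndim != 2 or counts.shape[0] != model.rates.shape[1]:
        raise ValueError("trial has wrong number of units for this model")
    logB = _log_emission(counts[None], model.rates)
    gamma, _, _ = _forward_backward(logB, model.initial, model.transition)
    return gamma[0]


def _window_bins(model: HmmModel, window: tuple[float, float], n_bins: int):
    b0 = int(max((window[0] - model.t_start_ms) // model.emission_bin_ms, 0))
    b1 = int(min((window[1] - model.t_start_ms) // model.emission_bin_ms, n_bins))
    if b1 <= b0:
        raise ValueError("state-identification window outside decoded range")
    return b0, b1


def identify_palatability_state(
    model: HmmModel,
    posteriors: np.ndarray,
    window: tuple[float, float] = (500.0, 1500.0),
    exclude_initial_ms: float = 100.0,
    initial_occupancy_max: float = 0.5,
) -> int:
    """State with the highest mean posterior mass in ``window`` across trials.

    ``posteriors`` is (trials x states x bins).  Ties resolve to the lower
    state index.  With the default 500-1500 ms window this picks the
    late/palatability state; a 100-600 ms window picks the identity state.

    Two robustness refinements over plain in-window dominance: a state that
    is already occupied at the start of the trial (mean posterior over the
    first ``exclude_initial_ms`` above ``initial_occupancy_max``) has no
    transition *into* it and is skipped unless every state is; and in-window
    mass is scored against out-of-window mass, so a state that dominates the
    whole trial does not outrank one specific to the window.  Pass
    ``exclude_initial_ms=0`` to disable both and recover the plain argmax.
    """
    posteriors = np.asarray(posteriors, float)
    b0, b1 = _window_bins(model, window, posteriors.shape[2])
    inside = posteriors[:, :, b0:b1].mean(axis=(0, 2))
    if exclude_initial_ms <= 0:
        return int(np.argmax(inside))
    out = np.concatenate(
        [posteriors[:, :, :b0], posteriors[:, :, b1:]], axis=2
    )
    outside = out.mean(axis=(0, 2)) if out.shape[2] else np.zeros_like(inside)
    score = inside - outside
    nb = max(int(exclude_initial_ms // model.emission_bin_ms), 1)
    init = posteriors[:, :, :nb].mean(axis=(0, 2))
    eligible = init < initial_occupancy_max
    if not eligible.any():
        return int(np.argmax(inside))
    return int(np.argmax(np.where(eligible, score, -np.inf)))


def transition_onset(
    posterior: np.ndarray,
    state: int,
    threshold: float = 0.5,
    t_start_ms: float = 0.0,
    bin_ms: float = 10.0,
    min_dwell_bins: int = 5,
):
    """Time at which a state's posterior first reaches ``threshold``.

    To guard against momentary posterior blips, the crossing must begin a
    run of at least ``min_dwell_bins`` consecutive above-threshold bins
    (pass 1 for the literal first crossing).  Returns the onset in ms (left
    edge of the crossing bin), or None if no qualifying crossing exists
    (an invalid trial).
    """
    p = np.asarray(posterior, float)[state]
    above = p >= threshold
    i = 0
    n = above.size
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_dwell_bins:
                return float(t_start_ms + i * bin_ms)
            i = j
        else:
            i += 1
    return None


@dataclass
class TrialAlignment:
    """Per-trial palatability-state onsets used to re-zero rasters."""

    trial_indices: np.ndarray
    state: int
    onset_ms: np.ndarray          # NaN where invalid
    valid: np.ndarray             # bool

    def __post_init__(self):
        ok = self.valid & np.isfinite(self.onset_ms)
        if not np.array_equal(ok, self.valid):
            raise ValueError("valid trials must carry finite onsets")


def compute_alignment(
    model: HmmModel,
    dataset: EnsembleDataset,
    taste: str,
    laser,
    window: tuple[float, float] = (500.0, 1500.0),
    fit_window: tuple[float, float] = (0.0, 2000.0),
    threshold: float = 0.5,
    state: int | None = None,
    exclude_unit: int | None = None,
) -> TrialAlignment:
    """Decode each trial of a taste x condition, identify the target state
    (unless given), and extract per-trial threshold-crossing onsets.

    ``exclude_unit`` drops one unit's spikes from the decoding (leave-one-
    unit-out alignment): aligning a unit's trials by the other units'
    posterior removes the self-selection step that threshold-based
    realignment otherwise imprints on that unit's own PSTH.
    """
    mask = dataset.trial_mask(taste=taste, laser=laser)
    counts = dataset.bin_counts(fit_window, int(model.emission_bin_ms), trials=mask)
    rates = model.rates
    if exclude_unit is not None:
        keep = np.arange(dataset.n_units) != exclude_unit
        counts = counts[:, keep]
        rates = rates[:, keep]
    logB = _log_emission(counts, rates)
    posteriors, _, _ = _forward_backward(logB, model.initial, model.transition)
    if state is None:
        state = identify_palatability_state(model, posteriors, window)
    onsets = np.full(counts.shape[0], np.nan)
    for i in range(counts.shape[0]):
        o = transition_onset(posteriors[i], state, threshold,
                             model.t_start_ms, model.emission_bin_ms)
        if o is not None:
            onsets[i] = o
    valid = np.isfinite(onsets)
    return TrialAlignment(
        trial_indices=np.nonzero(mask)[0],
        state=int(state),
        onset_ms=onsets,
        valid=valid,
    )


@dataclass
class RealignedRasters:
    """Rasters re-zeroed to per-trial state onsets.

    ``data`` is (valid trials x units x span ms), float with NaN where the
    requested span fell outside the recorded range; ``t_start_ms`` is the
    span start relative to the transition (negative = before it).
    """

    data: np.ndarray
    trial_indices: np.ndarray
    onsets_ms: np.ndarray
    t_start_ms: float
    padded: np.ndarray            # bool per trial: any missing samples

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def realign(
    dataset: EnsembleDataset,
    alignment: TrialAlignment,
    span: tuple[float, float] = (-1000.0, 1500.0),
) -> RealignedRasters:
    """Re-window each valid trial's raster about its state onset.

    Samples requested beyond the recorded -2000..+2500 ms range are padded
    as missing (NaN) and the trial flagged ``padded``.
    """
    keep = alignment.valid
    if not keep.any():
        raise ValueError("no valid trials to realign")
    idx = alignment.trial_indices[keep]
    onsets = alignment.onset_ms[keep]
    span_len = int(span[1] - span[0])
    out = np.full((idx.size, dataset.n_units, span_len), np.nan)
    padded = np.zeros(idx.size, bool)
    for k, (tr, onset) in enumerate(zip(idx, onsets)):
        start = int(round(onset + span[0])) - dataset.t_start_ms
        stop = start + span_len
        lo = max(start, 0)
        hi = min(stop, dataset.n_bins)
        out[k, :, lo - start : hi - start] = dataset.rasters[tr, :, lo:hi]
        padded[k] = (lo > start) or (hi < stop)
    return RealignedRasters(
        data=out,
        trial_indices=idx,
        onsets_ms=onsets,
        t_start_ms=span[0],
        padded=padded,
    )
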