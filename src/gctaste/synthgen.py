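"""Ground-truth-labeled synthetic spike-train ensembles.

The generator emulates the epochal structure of cortical taste responses:
baseline firing before stimulus delivery, a nonspecific "detection" phase
(0-200 ms), taste-specific "identity" firing from 200 ms, and a switch into
palatability-ranked "late" firing at a per-trial random transition time.
Optogenetic perturbation is modeled per unit as a multiplicative rate factor
(suppression or enhancement, never both) applied from a per-unit onset time
on laser trials, optionally accompanied by a blurring of the identity->late
rate switch (a linear ramp replacing the step) or by a per-unit decoupling
jitter of the transition time.

Spikes are drawn as independent Bernoulli events per 1-ms bin with
probability rate x 1 ms, which at cortical rates is an inhomogeneous Poisson
process to excellent approximation and matches the Poisson assumptions of
the GLM and HMM stages downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import TASTES, PALATABILITY_RANKS, T_START_MS, T_STOP_MS, EnsembleDataset

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_ensemble",
    "generate_latencies",
]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic ensemble generator.

    Rates are in Hz; times in ms relative to stimulus delivery.  Per-unit
    fields are arrays of length ``n_units``; ``identity_rates_hz`` is
    (n_units, 4) in the canonical taste order (Sucrose, NaCl, Acid, QHCl).

    The late ("palatability") rate of unit u for taste T is::

        late_rate_hz[u] + palatability_sign[u] * palatability_gain
                          * (rank_T - 2.5)

    i.e. the late state has its own per-unit base rate — the ensemble
    switches coherently into a new firing-rate vector at the transition —
    modulated by the centred hedonic rank, so a positive-sign unit fires
    fastest to Sucrose and slowest to QHCl.  When ``late_rate_hz`` is not
    given it defaults to each unit's mean identity rate (rank modulation
    only, no coherent rate jump).
    """

    n_units: int
    baseline_rate_hz: np.ndarray
    detection_rate_hz: np.ndarray
    identity_rates_hz: np.ndarray
    late_rate_hz: np.ndarray | None = None
    palatability_gain: float = 4.0
    palatability_sign: np.ndarray | None = None
    n_trials_per_taste: int = 30
    laser_fraction: float = 0.5
    transition_mean_ms: float = 700.0
    transition_sd_ms: float = 150.0
    identity_onset_ms: float = 200.0
    laser_factor: np.ndarray | None = None
    laser_onset_ms: np.ndarray | None = None
    blur_ms: float = 0.0
    decouple_jitter_sd_ms: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        self.baseline_rate_hz = np.atleast_1d(np.asarray(self.baseline_rate_hz, float))
        self.detection_rate_hz = np.atleast_1d(np.asarray(self.detection_rate_hz, float))
        self.identity_rates_hz = np.asarray(self.identity_rates_hz, float)
        if self.late_rate_hz is None:
            self.late_rate_hz = self.identity_rates_hz.mean(axis=1)
        self.late_rate_hz = np.atleast_1d(np.asarray(self.late_rate_hz, float))
        if self.palatability_sign is None:
            self.palatability_sign = np.ones(self.n_units)
        self.palatability_sign = np.asarray(self.palatability_sign, float)
        if self.laser_factor is None:
            self.laser_factor = np.ones(self.n_units)
        self.laser_factor = np.asarray(self.laser_factor, float)
        if self.laser_onset_ms is None:
            self.laser_onset_ms = np.zeros(self.n_units)
        self.laser_onset_ms = np.asarray(self.laser_onset_ms, float)
        self.validate()

    def validate(self) -> None:
        n = self.n_units
        if n < 1:
            raise ValueError("n_units must be >= 1")
        for name in ("baseline_rate_hz", "detection_rate_hz", "late_rate_hz",
                     "palatability_sign", "laser_factor", "laser_onset_ms"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
        if self.identity_rates_hz.shape != (n, len(TASTES)):
            raise ValueError(f"identity_rates_hz must have shape ({n}, {len(TASTES)})")
        if np.any(self.baseline_rate_hz < 0) or np.any(self.detection_rate_hz < 0) \
                or np.any(self.identity_rates_hz < 0) or np.any(self.late_rate_hz < 0):
            raise ValueError("rates must be non-negative")
        if np.any(self.laser_factor < 0):
            raise ValueError("laser factors must be non-negative")
        if not 0.0 <= self.laser_fraction <= 1.0:
            raise ValueError("laser_fraction must lie in [0, 1]")
        if self.blur_ms < 0 or self.transition_sd_ms < 0 or self.decouple_jitter_sd_ms < 0:
            raise ValueError("durations/SDs must be non-negative")

    # -- canned study configurations ------------------------------------
    @classmethod
    def taste_specific(
        cls,
        n_units: int = 10,
        rng_seed: int = 0,
        laser: bool = False,
        blur_ms: float = 0.0,
        decouple_jitter_sd_ms: float = 0.0,
        **overrides,
    ) -> "GeneratorConfig":
        """Default taste-specific ensemble.

        Per-unit baselines are uniform on 2-8 Hz; the detection phase adds a
        nonspecific 3 Hz; identity rates add an independent Gamma(2, 5 Hz)
        taste-specific excess per (unit, taste); the late state has its own
        per-unit base rate (baseline plus an independent Gamma(2, 6 Hz)
        draw, so the ensemble jumps coherently into a new rate vector at the
        transition, the sudden multi-Hz state switch these analyses target)
        modulated by a palatability gain of 4 Hz per rank step with random
        per-unit sign (rank spacing comparable to the single-trial 250-ms
        rate SD, so late-epoch rank correlations clear the chance level set
        by identity tuning).  With ``laser=True`` each
        unit is either suppressed (x0.5, 60% of units) or enhanced (x1.5),
        with onsets drawn from the empirical bimodal impact-latency mixture
        (means 347.28 / 754.39 ms, SDs 110 / 179 ms).
        """
        rng = np.random.default_rng([int(rng_seed), 101])
        baseline = rng.uniform(2.0, 8.0, n_units)
        detection = baseline + 3.0
        identity = baseline[:, None] + rng.gamma(2.0, 5.0, (n_units, len(TASTES)))
        late = baseline + rng.gamma(2.0, 6.0, n_units)
        sign = rng.choice([-1.0, 1.0], n_units)
        if laser:
            factor = np.where(rng.random(n_units) < 0.6, 0.5, 1.5)
            onset = generate_latencies(
                (0.5, 0.5), (347.28, 754.39), (110.0, 179.0), n_units, rng=rng
            )
        else:
            factor = np.ones(n_units)
            onset = np.zeros(n_units)
        kwargs = dict(
            n_units=n_units,
            baseline_rate_hz=baseline,
            detection_rate_hz=detection,
            identity_rates_hz=identity,
            late_rate_hz=late,
            palatability_gain=4.0,
            palatability_sign=sign,
            laser_factor=factor,
            laser_onset_ms=onset,
            blur_ms=blur_ms,
            decouple_jitter_sd_ms=decouple_jitter_sd_ms,
            rng_seed=rng_seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def null(cls, n_units: int = 10, rng_seed: int = 0, **overrides) -> "GeneratorConfig":
        """Taste-nonspecific ensemble: identical rate profiles for all four
        tastes, zero palatability gain, no laser effect."""
        rng = np.random.default_rng([int(rng_seed), 202])
        baseline = rng.uniform(2.0, 8.0, n_units)
        identity = np.repeat((baseline + 4.0)[:, None], len(TASTES), axis=1)
        kwargs = dict(
            n_units=n_units,
            baseline_rate_hz=baseline,
            detection_rate_hz=baseline + 3.0,
            identity_rates_hz=identity,
            palatability_gain=0.0,
            palatability_sign=np.ones(n_units),
            rng_seed=rng_seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Latent variables of a generated ensemble, for parameter recovery."""

    transition_ms: np.ndarray            # (n_trials,) ensemble switch time
    unit_transition_ms: np.ndarray       # (n_trials, n_units) per-unit switch
    laser_factor: np.ndarray             # (n_units,)
    laser_onset_ms: np.ndarray           # (n_units,)
    laser_direction: list[str]           # 'suppressed' | 'enhanced' | 'none'
    taste_specific: np.ndarray           # (n_units,) bool
    palatability_sign: np.ndarray        # (n_units,)
    late_rates_hz: np.ndarray            # (n_units, 4) configured late rates

    def to_frame(self) -> pd.DataFrame:
        """Per-trial ground truth as a DataFrame (transition times)."""
        return pd.DataFrame({"transition_ms": self.transition_ms})


def _late_rates(cfg: GeneratorConfig) -> np.ndarray:
    ranks = np.array([PALATABILITY_RANKS[t] for t in TASTES], float)
    late = cfg.late_rate_hz[:, None] + np.outer(
        cfg.palatability_sign * cfg.palatability_gain, ranks - 2.5
    )
    return np.maximum(late, 0.05)


def _draw_transitions(cfg: GeneratorConfig, n: int, rng) -> np.ndarray:
    """Gaussian transition times truncated to (identity_onset+50, 2400) ms."""
    lo, hi = cfg.identity_onset_ms + 50.0, 2400.0
    out = np.empty(n)
    for i in range(n):
        t = rng.normal(cfg.transition_mean_ms, cfg.transition_sd_ms)
        while not lo < t < hi:
            t = rng.normal(cfg.transition_mean_ms, cfg.transition_sd_ms)
        out[i] = t
    return out


def generate_ensemble(cfg: GeneratorConfig):
    """Generate one synthetic session.

    Returns ``(EnsembleDataset, GroundTruth)``.  Identical seed (and config)
    produce identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    n_time = T_STOP_MS - T_START_MS
    i_stim = -T_START_MS                       # index of t = 0
    i_ident = i_stim + int(cfg.identity_onset_ms)

    # trial table: n_trials_per_taste per taste, laser_fraction of each On
    tastes, lasers = [], []
    for taste in TASTES:
        n = cfg.n_trials_per_taste
        n_on = int(round(cfg.laser_fraction * n))
        flags = np.zeros(n, bool)
        flags[:n_on] = True
        rng.shuffle(flags)
        tastes += [taste] * n
        lasers += list(flags)
    order = rng.permutation(len(tastes))
    tastes = [tastes[i] for i in order]
    lasers = np.array(lasers)[order]
    n_trials = len(tastes)

    tau = _draw_transitions(cfg, n_trials, rng)
    unit_tau = np.repeat(tau[:, None], cfg.n_units, axis=1)
    if cfg.decouple_jitter_sd_ms > 0:
        # decoupling: each unit transitions sharply but at a consistent
        # per-unit lag relative to the ensemble time on laser trials —
        # individual dynamics intact, cross-neuron simultaneity lost
        offsets = rng.normal(0.0, cfg.decouple_jitter_sd_ms, cfg.n_units)
        unit_tau = np.where(lasers[:, None], unit_tau + offsets[None, :],
                            unit_tau)
        unit_tau = np.clip(unit_tau, cfg.identity_onset_ms + 10.0, 2450.0)

    late = _late_rates(cfg)
    taste_idx = {t: k for k, t in enumerate(TASTES)}
    t_ms = np.arange(n_time) + T_START_MS      # bin start times

    rasters = np.empty((n_trials, cfg.n_units, n_time), dtype=np.uint8)
    for i in range(n_trials):
        k = taste_idx[tastes[i]]
        rate = np.empty((cfg.n_units, n_time))
        rate[:, :i_stim] = cfg.baseline_rate_hz[:, None]
        rate[:, i_stim:i_ident] = cfg.detection_rate_hz[:, None]
        ident = cfg.identity_rates_hz[:, k]
        late_k = late[:, k]
        # identity -> late switch per unit (step, or ramp on blurred trials)
        post = t_ms[i_ident:]
        if lasers[i] and cfg.blur_ms > 0:
            half = cfg.blur_ms / 2.0
            w = np.clip(
                (post[None, :] - (unit_tau[i][:, None] - half)) / cfg.blur_ms,
                0.0,
                1.0,
            )
        else:
            w = (post[None, :] >= unit_tau[i][:, None]).astype(float)
        rate[:, i_ident:] = ident[:, None] * (1 - w) + late_k[:, None] * w
        if lasers[i]:
            for u in range(cfg.n_units):
                j = i_stim + int(max(cfg.laser_onset_ms[u], 0.0))
                rate[u, j:] *= cfg.laser_factor[u]
        p = rate * 1e-3
        if p.max() > 1.0:
            raise ValueError(
                "rate x bin exceeds 1 spike/bin; reduce rates below 1000 Hz"
            )
        rasters[i] = rng.random(rate.shape) < p

    trial_table = pd.DataFrame(
        {
            "trial_index": np.arange(n_trials, dtype=np.int64),
            "taste": tastes,
            "laser_on": lasers,
        }
    )
    half_width = rng.uniform(0.15, 0.65, cfg.n_units)
    unit_table = pd.DataFrame(
        {
            "unit_id": [f"u{u:03d}" for u in range(cfg.n_units)],
            "half_width_ms": half_width,
            "session_id": [f"synth-{cfg.rng_seed}"] * cfg.n_units,
        }
    )
    dataset = EnsembleDataset(rasters=rasters, trial_table=trial_table,
                              unit_table=unit_table)

    direction = [
        "suppressed" if f < 1 else ("enhanced" if f > 1 else "none")
        for f in cfg.laser_factor
    ]
    specific = (
        (np.ptp(cfg.identity_rates_hz, axis=1) > 1e-9)
        | ((cfg.palatability_gain != 0) & (cfg.palatability_sign != 0))
    )
    truth = GroundTruth(
        transition_ms=tau,
        unit_transition_ms=unit_tau,
        laser_factor=cfg.laser_factor.copy(),
        laser_onset_ms=cfg.laser_onset_ms.copy(),
        laser_direction=direction,
        taste_specific=specific,
        palatability_sign=cfg.palatability_sign.copy(),
        late_rates_hz=late,
    )
    return dataset, truth


def generate_latencies(weights, means_ms, sds_ms, n, rng_seed=None, rng=None):
    """Draw ``n`` latencies (ms) from a k-component Gaussian mixture,
    truncated by rejection to [0, 2500] ms."""
    if n <= 0:
        raise ValueError("n must be positive")
    weights = np.asarray(weights, float)
    means = np.asarray(means_ms, float)
    sds = np.asarray(sds_ms, float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("mixture weights must sum to 1")
    if np.any(sds <= 0):
        raise ValueError("mixture SDs must be positive")
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    comp = rng.choice(len(weights), size=n, p=weights)
    out = rng.normal(means[comp], sds[comp])
    bad = (out < 0) | (out > 2500)
    while bad.any():
        comp_bad = rng.choice(len(weights), size=int(bad.sum()), p=weights)
        out[bad] = rng.normal(means[comp_bad], sds[comp_bad])
        bad = (out < 0) | (out > 2500)
    return out
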