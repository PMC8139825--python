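"""Per-unit statistics of taste responses and optogenetic impact.

Five families of analyses, each consuming a single unit's raster
(trials x 1-ms bins, time axis -2000..+2500 ms) plus the trial table:

* taste responsivity — paired t-test of evoked (0-2 s) vs baseline (-2-0 s)
  mean rates across trials, collapsed over tastes;
* taste specificity — mixed two-way ANOVA (taste between trials, time within:
  four 500-ms bins of the first 2 s), significant if the taste main effect or
  the taste x time interaction is;
* palatability correlation — moving-window (250 ms window, 25 ms step)
  Spearman correlation of single-trial rates against hedonic ranks, a unit
  being flagged when >= 3 consecutive windows reach p < .05;
* laser impact — hierarchical Bayesian Poisson GLM on whole-trial (0-2.5 s)
  spike counts with taste, laser, and taste x laser effects; a taste response
  is "impacted" when the 95% credible interval of its On - Off firing-rate
  contrast excludes zero, plus nonparametric per-bin latency/direction
  profiles of the impact;
* neuron-type split — putative interneuron vs pyramidal cell at the 0.35 ms
  spike half-width boundary.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import TASTES, PALATABILITY_RANKS
from ._mcmc import sample_posterior

__all__ = [
    "taste_responsive",
    "taste_specific",
    "classify_unit_type",
    "palatability_correlation",
    "laser_impact_glm",
    "impact_latency",
    "direction_profile",
    "PalatabilityTrace",
    "LaserImpactResult",
    "DirectionProfile",
]

_T0 = -2000  # raster time origin (ms)


def _win_rates(unit_raster: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Per-trial mean firing rate (Hz) in [t0, t1) ms post-stimulus axis."""
    i0, i1 = int(t0 - _T0), int(t1 - _T0)
    return unit_raster[:, i0:i1].sum(axis=1) / ((t1 - t0) / 1000.0)


def taste_responsive(unit_raster: np.ndarray, trial_table: pd.DataFrame,
                     alpha: float = 0.05):
    """Paired t-test of evoked (0-2000 ms) against baseline (-2000-0 ms) rate.

    Collapses across all tastes; a unit that raises firing to some tastes and
    equally lowers it to others can be non-responsive here yet taste-specific.
    Returns ``(flag, t_statistic, p_value)``.
    """
    if len(trial_table) == 0 or unit_raster.shape[0] == 0:
        raise ValueError("no trials supplied")
    baseline = _win_rates(unit_raster, -2000, 0)
    evoked = _win_rates(unit_raster, 0, 2000)
    t, p = stats.ttest_rel(evoked, baseline)
    return bool(p < alpha), float(t), float(p)


def taste_specific(unit_raster: np.ndarray, trial_table: pd.DataFrame,
                   alpha: float = 0.05):
    """Mixed two-way ANOVA on four 500-ms bins of the first 2 s of firing.

    Taste is a between-trial factor, time a within-trial factor (trials are
    the subjects).  Returns ``(flag, anova_table)``; the flag is True when
    the taste main effect or the taste x time interaction has p < alpha.
    """
    import pingouin as pg

    counts = {t: int(np.sum(trial_table["taste"] == t)) for t in TASTES}
    missing = [t for t, n in counts.items() if n < 2]
    if missing:
        raise ValueError(f"need >= 2 trials per taste; missing {missing}")
    rows = []
    for b in range(4):
        rates = _win_rates(unit_raster, 500 * b, 500 * (b + 1))
        for i, (taste, r) in enumerate(zip(trial_table["taste"], rates)):
            rows.append((i, taste, b, r))
    long = pd.DataFrame(rows, columns=["trial", "taste", "time", "rate"])
    aov = pg.mixed_anova(data=long, dv="rate", within="time",
                         subject="trial", between="taste")
    pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
    p_taste = float(aov.loc[aov["Source"] == "taste", pcol].iloc[0])
    p_inter = float(aov.loc[aov["Source"] == "Interaction", pcol].iloc[0])
    flag = (p_taste < alpha) or (p_inter < alpha)
    return bool(flag), aov


def classify_unit_type(half_width_ms: float) -> str:
    """Putative cell type from spike half-width: 'IN' below 0.35 ms,
    'PC' at or above it (the boundary itself is assigned to PC)."""
    if not half_width_ms > 0:
        raise ValueError("half-width must be positive")
    return "IN" if half_width_ms < 0.35 else "PC"


@dataclass
class PalatabilityTrace:
    """Moving-window Spearman correlation of firing with hedonic rank."""

    time_centers_ms: np.ndarray
    rho: np.ndarray                 # NaN where rate variance is zero
    p: np.ndarray
    significant_run: np.ndarray     # window is part of a >=3-long p<.05 run
    flagged: bool                   # unit shows palatability-related firing


def _runs_of_significance(p: np.ndarray, alpha: float, min_run: int) -> np.ndarray:
    sig = np.asarray((p < alpha) & np.isfinite(p))
    in_run = np.zeros_like(sig)
    i = 0
    while i < sig.size:
        if sig[i]:
            j = i
            while j < sig.size and sig[j]:
                j += 1
            if j - i >= min_run:
                in_run[i:j] = True
            i = j
        else:
            i += 1
    return in_run


def palatability_correlation(
    unit_raster: np.ndarray,
    trial_table: pd.DataFrame,
    palatability_map: dict[str, int] | None = None,
    window_ms: float = 250.0,
    step_ms: float = 25.0,
    span: tuple[float, float] = (0.0, 2500.0),
    alpha: float = 0.05,
    min_run: int = 3,
) -> PalatabilityTrace:
    """Spearman rho between single-trial rates and palatability ranks,
    on a 250-ms window advanced in 25-ms steps across [0, 2500) ms.

    Windows with zero rate variance have undefined rho (recorded as NaN,
    never significant).  The unit is flagged palatability-related iff at
    least ``min_run`` consecutive windows reach p < alpha (sign-agnostic).
    """
    if palatability_map is None:
        palatability_map = PALATABILITY_RANKS
    present = set(trial_table["taste"])
    if present != set(TASTES):
        raise ValueError("all four tastes must be present")
    ranks = trial_table["taste"].map(palatability_map).to_numpy(float)
    starts = np.arange(span[0], span[1] - window_ms + 1e-9, step_ms)
    rho = np.full(starts.size, np.nan)
    pval = np.full(starts.size, np.nan)
    for k, t0 in enumerate(starts):
        rates = _win_rates(unit_raster, t0, t0 + window_ms)
        if np.ptp(rates) == 0:
            continue
        r, p = stats.spearmanr(rates, ranks)
        rho[k], pval[k] = r, p
    run = _runs_of_significance(pval, alpha, min_run)
    return PalatabilityTrace(
        time_centers_ms=starts + window_ms / 2.0,
        rho=rho,
        p=pval,
        significant_run=run,
        flagged=bool(run.any()),
    )


# ---------------------------------------------------------------------------
# hierarchical Poisson GLM for the laser contrast
# ---------------------------------------------------------------------------

@dataclass
class LaserImpactResult:
    """Posterior On - Off firing-rate contrast per taste for one unit.

    ``table`` has one row per taste: posterior mean of the contrast (Hz),
    95% credible-interval bounds, a significance flag (interval excludes 0)
    and a direction ('suppressed' / 'enhanced' / 'none').
    """

    table: pd.DataFrame
    acceptance_fraction: float
    warning: str | None = None

    @property
    def impacted(self) -> bool:
        """True when one or more taste responses is significantly changed."""
        return bool(self.table["significant"].any())

    def __post_init__(self):
        t = self.table
        bad = (t["ci_low"] > t["mean"]) | (t["mean"] > t["ci_high"])
        if bad.any():
            raise ValueError("credible interval must bracket the posterior mean")


def _glm_log_prob_factory(sums: np.ndarray, ns: np.ndarray, exposure_s: float,
                          mu0: float):
    """Vectorized log posterior for the hierarchical Poisson GLM.

    Parameters (18): mu, alpha[4] (taste), beta[2] (laser), gamma[4,2]
    (interaction), log-scales for the three effect families.  Counts enter
    through per-(taste, laser) sufficient statistics ``sums`` and ``ns``.
    log rate(T,O) = mu + alpha_T + beta_O + gamma_TO; effects have Normal(0,
    sigma_fam) priors with HalfNormal(1) family scales; mu ~ Normal(mu0, 3).
    """

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        mu = theta[:, 0]
        a = theta[:, 1:5]
        b = theta[:, 5:7]
        g = theta[:, 7:15].reshape(-1, 4, 2)
        ls = theta[:, 15:18]
        sig = np.exp(ls)
        # priors
        lp = -0.5 * ((mu - mu0) / 3.0) ** 2
        lp += np.sum(-0.5 * (sig ** 2), axis=1) + np.sum(ls, axis=1)  # HalfN(1) + Jacobian
        lp += np.sum(-0.5 * (a / sig[:, [0]]) ** 2, axis=1) - 4 * ls[:, 0]
        lp += np.sum(-0.5 * (b / sig[:, [1]]) ** 2, axis=1) - 2 * ls[:, 1]
        lp += np.sum(-0.5 * (g / sig[:, 2, None, None]) ** 2, axis=(1, 2)) - 8 * ls[:, 2]
        # likelihood
        eta = mu[:, None, None] + a[:, :, None] + b[:, None, :] + g
        eta = np.minimum(eta, 8.0)
        lp += np.sum(sums[None] * eta - ns[None] * exposure_s * np.exp(eta),
                     axis=(1, 2))
        return lp

    return log_prob


def laser_impact_glm(
    unit_raster: np.ndarray,
    trial_table: pd.DataFrame,
    window: tuple[float, float] = (0.0, 2500.0),
    n_walkers: int = 40,
    n_burn: int = 1000,
    n_steps: int = 2000,
    seed: int = 0,
    thin: int = 2,
) -> LaserImpactResult:
    """Posterior taste-by-taste On - Off firing-rate contrasts for one unit.

    Spike counts are aggregated per trial over ``window`` (default the full
    2.5-s laser period) and modeled as Poisson with a log link; the linear
    predictor decomposes into a grand mean, taste and laser main effects, and
    their interaction, with hierarchical normal priors (HalfNormal(1) scales).
    The contrast exp(eta_{T,On}) - exp(eta_{T,Off}) is summarized by its
    posterior mean and central 95% credible interval; the response to taste T
    is deemed impacted when that interval excludes zero.
    """
    laser = trial_table["laser_on"].to_numpy(bool)
    if laser.all() or (~laser).all():
        raise ValueError("both laser conditions must be present")
    exposure_s = (window[1] - window[0]) / 1000.0
    counts = _win_rates(unit_raster, *window) * exposure_s  # spike counts
    sums = np.zeros((4, 2))
    ns = np.zeros((4, 2))
    tastes = trial_table["taste"].to_numpy()
    for ti, taste in enumerate(TASTES):
        for oi, flag in enumerate((False, True)):
            m = (tastes == taste) & (laser == flag)
            sums[ti, oi] = counts[m].sum()
            ns[ti, oi] = m.sum()
    if np.any(ns == 0):
        raise ValueError("every taste x laser cell needs at least one trial")

    mean_rate = max(counts.mean() / exposure_s, 0.05)
    mu0 = float(np.log(mean_rate))
    log_prob = _glm_log_prob_factory(sums, ns, exposure_s, mu0)
    center = np.zeros(18)
    center[0] = mu0
    center[15:18] = np.log(0.3)
    scales = np.full(18, 0.05)
    flat, acc = sample_posterior(log_prob, center, scales, n_walkers, n_burn,
                                 n_steps, seed=seed, thin=thin)
    mu = flat[:, 0]
    a = flat[:, 1:5]
    b = flat[:, 5:7]
    g = flat[:, 7:15].reshape(-1, 4, 2)
    eta = mu[:, None, None] + a[:, :, None] + b[:, None, :] + g
    rate = np.exp(np.minimum(eta, 8.0))            # Hz
    contrast = rate[:, :, 1] - rate[:, :, 0]       # On - Off
    lo, hi = np.percentile(contrast, [2.5, 97.5], axis=0)
    mean = contrast.mean(axis=0)
    sig = (lo > 0) | (hi < 0)
    direction = np.where(~sig, "none", np.where(mean < 0, "suppressed", "enhanced"))
    table = pd.DataFrame(
        {
            "taste": TASTES,
            "mean": mean,
            "ci_low": lo,
            "ci_high": hi,
            "significant": sig,
            "direction": direction,
        }
    ).set_index("taste")
    warning = None
    if acc < 0.1:
        warning = f"low MCMC acceptance fraction ({acc:.3f}); treat CIs with caution"
    return LaserImpactResult(table=table, acceptance_fraction=acc, warning=warning)


def impact_latency(
    unit_raster: np.ndarray,
    trial_table: pd.DataFrame,
    bin_ms: float = 100.0,
    alpha: float = 0.05,
    min_run: int = 2,
):
    """Earliest onset of the laser's impact on firing, or None.

    The 2.5-s response is cut into 100-ms bins; per bin, Off and On trial
    rates are compared with a Welch t-test.  The latency is the start time of
    the first run of >= 2 consecutive significant bins; None if no such run.
    """
    laser = trial_table["laser_on"].to_numpy(bool)
    starts = np.arange(0.0, 2500.0, bin_ms)
    p = np.full(starts.size, np.nan)
    for k, t0 in enumerate(starts):
        rates = _win_rates(unit_raster, t0, t0 + bin_ms)
        off, on = rates[~laser], rates[laser]
        if np.ptp(off) == 0 and np.ptp(on) == 0:
            continue
        p[k] = stats.ttest_ind(off, on, equal_var=False).pvalue
    run = _runs_of_significance(p, alpha, min_run)
    if not run.any():
        return None
    return float(starts[int(np.argmax(run))])


@dataclass
class DirectionProfile:
    """On - Off mean rate differences in ten 250-ms bins, with per-bin
    Welch tests and a direction-consistency flag."""

    bin_starts_ms: np.ndarray
    diff_hz: np.ndarray
    t: np.ndarray
    p: np.ndarray
    consistent: bool


def direction_profile(
    unit_raster: np.ndarray,
    trial_table: pd.DataFrame,
    alpha: float = 0.05,
) -> DirectionProfile:
    """Signed laser impact across ten 250-ms bins of the 2.5-s response.

    ``consistent`` is True when every significant bin shares one sign —
    perturbation either suppresses or enhances a neuron, not both.
    """
    laser = trial_table["laser_on"].to_numpy(bool)
    starts = np.arange(0.0, 2500.0, 250.0)
    diff = np.zeros(starts.size)
    tv = np.full(starts.size, np.nan)
    pv = np.full(starts.size, np.nan)
    for k, t0 in enumerate(starts):
        rates = _win_rates(unit_raster, t0, t0 + 250.0)
        off, on = rates[~laser], rates[laser]
        diff[k] = on.mean() - off.mean()
        if np.ptp(rates) > 0:
            res = stats.ttest_ind(on, off, equal_var=False)
            tv[k], pv[k] = res.statistic, res.pvalue
    sig = (pv < alpha) & np.isfinite(pv)
    signs = np.sign(diff[sig])
    consistent = bool(signs.size == 0 or np.all(signs == signs[0]))
    return DirectionProfile(bin_starts_ms=starts, diff_hz=diff, t=tv, p=pv,
                            consistent=consistent)
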