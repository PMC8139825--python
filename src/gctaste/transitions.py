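"""Sharpness and coherence of ensemble state transitions.

Given rasters re-zeroed to per-trial HMM state onsets, this module
quantifies how abruptly the ensemble enters the new state:

* a moving-window Spearman trace of firing vs hedonic rank around the
  transition, summarized per condition by a Bayesian 4-parameter logistic
  fit whose growth-rate ("slope") posterior carries a 95% credible interval
  — two conditions differ when their slope intervals fail to overlap;
* per-unit peri-transition PSTH slopes (100 ms window, 20 ms step, within
  +/-160 ms of the onset): the maximum |slope| and the latency at which it
  occurs;
* Off-vs-On comparisons of those per-unit records: an OLS regression of On
  on Off slopes tested against the unity line, an Off-slope quintile table,
  a chi-squared comparison of max-slope latency histograms, and a test of
  per-ensemble latency means.

Running the same machinery on the identity-state onsets (dominant over
100-600 ms) instead of the palatability-state onsets (dominant over
500-1500 ms) asks whether a perturbation that blurs the late transition
spares the earlier one.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import TASTES, PALATABILITY_RANKS, EnsembleDataset
from .hmm import (
    HmmModel,
    RealignedRasters,
    compute_alignment,
    fit_taste_hmm,
    realign,
)
from ._mcmc import sample_posterior

__all__ = [
    "AlignedTrace",
    "SigmoidFit",
    "SlopeComparison",
    "TransitionAnalysis",
    "aligned_palatability_trace",
    "fit_sigmoid",
    "slopes_differ",
    "peri_transition_slopes",
    "compare_slope_conditions",
    "transition_pipeline",
]


# ---------------------------------------------------------------------------
# realigned palatability correlation
# ---------------------------------------------------------------------------

@dataclass
class AlignedTrace:
    """Per-unit Spearman rho vs time relative to the state transition."""

    time_centers_ms: np.ndarray
    rho: np.ndarray               # (units, windows), NaN where undefined
    p: np.ndarray
    mean_abs_rho: np.ndarray      # (windows,) mean |rho| across units


def aligned_palatability_trace(
    realigned_sets: list[tuple[RealignedRasters, np.ndarray]],
    palatability_map: dict[str, int] | None = None,
    window_ms: float = 250.0,
    step_ms: float = 25.0,
) -> AlignedTrace:
    """Moving-window rank correlation on transition-aligned trials.

    ``realigned_sets`` is a list of ``(RealignedRasters, taste_labels)``
    pairs (one per taste, same condition); trials are pooled across tastes so
    the correlation is computed over the full palatability range.  Windows
    containing any missing (padded) samples for a trial drop that trial;
    windows with zero rate variance have undefined rho (NaN).
    """
    if palatability_map is None:
        palatability_map = PALATABILITY_RANKS
    data = np.concatenate([r.data for r, _ in realigned_sets], axis=0)
    labels = np.concatenate([np.asarray(l) for _, l in realigned_sets])
    ranks = np.array([palatability_map[t] for t in labels], float)
    t0 = realigned_sets[0][0].t_start_ms
    n_time = data.shape[2]
    starts = np.arange(0.0, n_time - window_ms + 1e-9, step_ms).astype(int)
    n_units = data.shape[1]
    rho = np.full((n_units, starts.size), np.nan)
    pv = np.full((n_units, starts.size), np.nan)
    for k, s in enumerate(starts):
        seg = data[:, :, s : s + int(window_ms)]
        rates = seg.sum(axis=2) / (window_ms / 1000.0)     # NaN if any pad
        for u in range(n_units):
            r_u = rates[:, u]
            ok = np.isfinite(r_u)
            if ok.sum() < 5 or np.ptp(r_u[ok]) == 0 or np.ptp(ranks[ok]) == 0:
                continue
            r, p = stats.spearmanr(r_u[ok], ranks[ok])
            rho[u, k], pv[u, k] = r, p
    centers = t0 + starts + window_ms / 2.0
    with np.errstate(invalid="ignore"):
        mean_abs = np.nanmean(np.abs(rho), axis=0)
    return AlignedTrace(time_centers_ms=centers, rho=rho, p=pv,
                        mean_abs_rho=mean_abs)


# ---------------------------------------------------------------------------
# Bayesian sigmoid fit
# ---------------------------------------------------------------------------

@dataclass
class SigmoidFit:
    """Posterior of a 4-parameter logistic fitted to a correlation trace.

    y(t) = lower + (upper - lower) / (1 + exp(-k (t - t0))), Gaussian noise.
    ``slope`` is the logistic growth rate k (1/ms); ``max_rate`` is the
    curve's maximum derivative k (upper - lower) / 4 (units of y per ms).
    """

    summary: pd.DataFrame         # rows lower/upper/t0/slope/sigma
    samples: np.ndarray           # (draws, 5): lower, delta, t0, k, sigma
    acceptance_fraction: float
    warning: str | None = None

    def _row(self, name):
        return self.summary.loc[name]

    @property
    def slope_ci(self) -> tuple[float, float]:
        r = self._row("slope")
        return float(r["ci_low"]), float(r["ci_high"])

    @property
    def slope_mean(self) -> float:
        return float(self._row("slope")["mean"])

    def __post_init__(self):
        if (self.summary.loc["upper", "mean"]
                < self.summary.loc["lower", "mean"] - 1e-12):
            raise ValueError("upper asymptote below lower asymptote")
        lo, hi = self.slope_ci
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError("slope credible interval must be finite")


def fit_sigmoid(
    time_ms: np.ndarray,
    y: np.ndarray,
    n_walkers: int = 30,
    n_burn: int = 800,
    n_steps: int = 1200,
    seed: int = 0,
    thin: int = 3,
) -> SigmoidFit:
    """Bayesian 4-parameter logistic fit of a rho-vs-time trace.

    Priors: lower ~ N(0, 1); upper - lower ~ HalfNormal(1); inflection time
    uniform over the trace span; growth rate k ~ HalfNormal(0.1 /ms); noise
    SD ~ HalfNormal(0.5) bounded below at 1e-4.  Two fits are "significantly
    different" when their 95% slope credible intervals do not overlap.
    """
    t = np.asarray(time_ms, float)
    yv = np.asarray(y, float)
    ok = np.isfinite(yv)
    t, yv = t[ok], yv[ok]
    if t.size < 20:
        raise ValueError("need at least 20 trace windows to fit")
    t_lo, t_hi = float(t.min()), float(t.max())

    def log_prob(theta):
        theta = np.atleast_2d(theta)
        L, D, t0, k, sig = (theta[:, i] for i in range(5))
        bad = (D < 0) | (k < 0) | (sig < 1e-4) | (t0 < t_lo) | (t0 > t_hi)
        sig_safe = np.where(bad, 1.0, sig)
        lp = (
            -0.5 * L**2
            - 0.5 * D**2
            - 0.5 * (k / 0.1) ** 2
            - 0.5 * (sig / 0.5) ** 2
        )
        z = np.clip(k[:, None] * (t[None, :] - t0[:, None]), -50.0, 50.0)
        pred = L[:, None] + D[:, None] / (1.0 + np.exp(-z))
        resid = yv[None, :] - pred
        lp += -0.5 * np.sum((resid / sig_safe[:, None]) ** 2, axis=1) \
            - t.size * np.log(sig_safe)
        lp[bad] = -np.inf
        return lp

    # rough moment-based start
    lo0 = float(np.percentile(yv, 10))
    hi0 = float(np.percentile(yv, 90))
    d0 = max(hi0 - lo0, 0.05)
    half = lo0 + d0 / 2.0
    above = np.nonzero(yv >= half)[0]
    t00 = float(t[above[0]]) if above.size else float(np.median(t))
    t00 = min(max(t00, t_lo), t_hi)
    center = np.array([lo0, d0, t00, 0.02, max(np.std(yv) * 0.3, 5e-3)])
    scales = np.array([0.02, 0.02, 20.0, 0.005, 2e-3])
    flat, acc = sample_posterior(log_prob, center, scales, n_walkers, n_burn,
                                 n_steps, seed=seed, thin=thin)
    L, D, t0, k, sig = flat.T
    rows = {}
    for name, s in (
        ("lower", L),
        ("upper", L + D),
        ("t0", t0),
        ("slope", k),
        ("max_rate", k * D / 4.0),
        ("sigma", sig),
    ):
        lo, hi = np.percentile(s, [2.5, 97.5])
        rows[name] = (float(np.mean(s)), float(lo), float(hi))
    summary = pd.DataFrame.from_dict(
        rows, orient="index", columns=["mean", "ci_low", "ci_high"]
    )
    warning = None
    if acc < 0.1:
        warning = f"low MCMC acceptance fraction ({acc:.3f})"
    return SigmoidFit(summary=summary, samples=flat,
                      acceptance_fraction=acc, warning=warning)


def slopes_differ(fit_a: SigmoidFit, fit_b: SigmoidFit) -> bool:
    """Non-overlap of the two 95% slope credible intervals."""
    a_lo, a_hi = fit_a.slope_ci
    b_lo, b_hi = fit_b.slope_ci
    return bool(a_hi < b_lo or b_hi < a_lo)


# ---------------------------------------------------------------------------
# per-unit peri-transition slopes
# ---------------------------------------------------------------------------

def peri_transition_slopes(
    realigned: RealignedRasters,
    window_ms: float = 100.0,
    step_ms: float = 20.0,
    period_ms: float = 160.0,
    condition: str = "",
) -> pd.DataFrame:
    """Max |PSTH slope| and its latency per unit around the transition.

    The transition-aligned PSTH (NaN-aware trial mean, 1-ms resolution, Hz)
    is scanned with 100-ms windows centred within +/- ``period_ms`` of the
    onset, advancing 20 ms; the slope of each window is the least-squares
    regression of rate on time.  Returns a frame with columns
    ``max_abs_slope`` (Hz/ms), ``slope`` (signed, at the max), ``latency_ms``
    (window centre), ``condition``.
    """
    data = realigned.data
    if data.shape[0] == 0:
        raise ValueError("no valid trials")
    with np.errstate(invalid="ignore"):
        psth = np.nanmean(data, axis=0) * 1000.0           # (units, time) Hz
    t = np.arange(data.shape[2]) + realigned.t_start_ms    # ms, bin starts
    half = window_ms / 2.0
    centers = np.arange(-period_ms, period_ms + 1e-9, step_ms)
    rows = []
    for u in range(psth.shape[0]):
        best_s, best_abs, best_c = 0.0, -1.0, np.nan
        for c in centers:
            sel = (t >= c - half) & (t < c + half)
            y = psth[u, sel]
            x = t[sel].astype(float)
            ok = np.isfinite(y)
            if ok.sum() < int(window_ms) // 2:
                continue
            x, y = x[ok], y[ok]
            xc = x - x.mean()
            denom = np.sum(xc**2)
            if denom == 0:
                continue
            s = float(np.sum(xc * (y - y.mean())) / denom)
            if abs(s) > best_abs:
                best_abs, best_s, best_c = abs(s), s, float(c)
        rows.append((best_abs if best_abs >= 0 else np.nan, best_s, best_c))
    return pd.DataFrame(
        rows, columns=["max_abs_slope", "slope", "latency_ms"]
    ).assign(condition=condition)


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------

@dataclass
class SlopeComparison:
    """Off-vs-On comparison of per-unit peri-transition slope records."""

    regression_slope: float
    regression_intercept: float
    slope_se: float
    t_vs_unity: float
    p_vs_unity: float
    deming_slope: float
    deming_ci: tuple[float, float]
    n_units: int
    group_table: pd.DataFrame | None      # Off-slope quintiles
    latency_chi2: float
    latency_p: float
    latency_mean_off: float
    latency_mean_on: float
    latency_sem_off: float
    latency_sem_on: float
    ensemble_t: float
    ensemble_p: float
    grouping_skipped: bool = False


def compare_slope_conditions(
    records_off: pd.DataFrame,
    records_on: pd.DataFrame,
    latency_bin_ms: float = 20.0,
    period_ms: float = 160.0,
    ensemble_ids: np.ndarray | None = None,
) -> SlopeComparison:
    """Compare paired per-unit slope records between laser conditions.

    * OLS of On max-|slope| on Off max-|slope|, with a t-test of the fitted
      slope against 1 (unity = no perturbation effect).  Because both axes
      carry comparable estimation noise (which attenuates OLS toward zero
      even for identical conditions), an errors-in-variables Deming slope
      (error-variance ratio 1, jackknife 95% CI over units) is reported
      alongside; it is the appropriate estimate when testing slope = 1.
    * Off-slope quintile grouping with per-group paired t-tests (skipped,
      flagged, when fewer than 5 units).
    * Chi-squared comparison of the two max-slope latency histograms
      (20-ms bins across the peri-transition period).
    * Paired t-test of per-ensemble latency means when >= 2 ensembles are
      given; otherwise a Welch t across units.
    """
    off = records_off["max_abs_slope"].to_numpy(float)
    on = records_on["max_abs_slope"].to_numpy(float)
    if off.shape != on.shape:
        raise ValueError("slope records must be paired per unit")
    n = off.size

    def deming(x, y):
        sxx = np.var(x, ddof=1)
        syy = np.var(y, ddof=1)
        sxy = np.cov(x, y, ddof=1)[0, 1]
        if sxy == 0:
            return np.nan
        return (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)

    dem = deming(off, on)
    if n >= 5 and np.isfinite(dem):
        jack = np.array([
            deming(np.delete(off, i), np.delete(on, i)) for i in range(n)
        ])
        se_j = np.sqrt((n - 1) / n * np.sum((jack - jack.mean()) ** 2))
        dem_ci = (dem - 1.96 * se_j, dem + 1.96 * se_j)
    else:
        dem_ci = (np.nan, np.nan)
    res = stats.linregress(off, on)
    se = res.stderr if np.isfinite(res.stderr) else np.nan
    if np.isfinite(se) and se > 0:
        t_unity = (res.slope - 1.0) / se
        p_unity = 2.0 * stats.t.sf(abs(t_unity), df=n - 2)
    elif se == 0:  # exact fit: slope either is 1 or differs with certainty
        t_unity = 0.0 if np.isclose(res.slope, 1.0) else np.inf
        p_unity = 1.0 if np.isclose(res.slope, 1.0) else 0.0
    else:
        t_unity, p_unity = np.nan, np.nan

    grouping_skipped = n < 5
    group_table = None
    if not grouping_skipped:
        order = np.argsort(off)
        groups = np.array_split(order, 5)
        rows = []
        for gi, g in enumerate(groups):
            a, b = off[g], on[g]
            if g.size >= 2 and np.ptp(a - b) > 0:
                tt = stats.ttest_rel(a, b)
                tstat, pval = float(tt.statistic), float(tt.pvalue)
            else:
                tstat, pval = np.nan, np.nan
            rows.append((gi, g.size, a.mean(), b.mean(), tstat, pval))
        group_table = pd.DataFrame(
            rows,
            columns=["group", "n", "mean_off", "mean_on", "t", "p"],
        )

    lat_off = records_off["latency_ms"].to_numpy(float)
    lat_on = records_on["latency_ms"].to_numpy(float)
    edges = np.arange(-period_ms, period_ms + latency_bin_ms, latency_bin_ms)
    h_off, _ = np.histogram(lat_off[np.isfinite(lat_off)], edges)
    h_on, _ = np.histogram(lat_on[np.isfinite(lat_on)], edges)
    keep = (h_off + h_on) > 0
    if keep.sum() >= 2 and h_off.sum() > 0 and h_on.sum() > 0:
        chi2, p_chi, _, _ = stats.chi2_contingency(
            np.stack([h_off[keep], h_on[keep]])
        )
    else:
        chi2, p_chi = np.nan, np.nan

    if ensemble_ids is not None and len(np.unique(ensemble_ids)) >= 2:
        ids = np.asarray(ensemble_ids)
        means_off = [lat_off[ids == e].mean() for e in np.unique(ids)]
        means_on = [lat_on[ids == e].mean() for e in np.unique(ids)]
        te = stats.ttest_rel(means_off, means_on)
    else:
        te = stats.ttest_ind(lat_off, lat_on, equal_var=False)

    sem = lambda v: float(np.std(v, ddof=1) / np.sqrt(max(v.size, 1))) \
        if v.size > 1 else np.nan
    return SlopeComparison(
        regression_slope=float(res.slope),
        regression_intercept=float(res.intercept),
        slope_se=float(se),
        t_vs_unity=float(t_unity),
        p_vs_unity=float(p_unity),
        deming_slope=float(dem),
        deming_ci=(float(dem_ci[0]), float(dem_ci[1])),
        n_units=n,
        group_table=group_table,
        latency_chi2=float(chi2),
        latency_p=float(p_chi),
        latency_mean_off=float(np.nanmean(lat_off)),
        latency_mean_on=float(np.nanmean(lat_on)),
        latency_sem_off=sem(lat_off[np.isfinite(lat_off)]),
        latency_sem_on=sem(lat_on[np.isfinite(lat_on)]),
        ensemble_t=float(te.statistic),
        ensemble_p=float(te.pvalue),
        grouping_skipped=grouping_skipped,
    )


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------

@dataclass
class TransitionAnalysis:
    """Everything the transition stage computes for one state window."""

    state_window: tuple[float, float]
    sigmoid_off: SigmoidFit
    sigmoid_on: SigmoidFit
    sigmoid_slopes_differ: bool
    comparison: SlopeComparison
    trace_off: AlignedTrace
    trace_on: AlignedTrace
    slopes_off: pd.DataFrame
    slopes_on: pd.DataFrame


def transition_pipeline(
    dataset: EnsembleDataset,
    state_window: tuple[float, float] = (500.0, 1500.0),
    span: tuple[float, float] = (-1000.0, 1500.0),
    n_states: int = 4,
    emission_bin_ms: float = 10.0,
    restarts: int = 8,
    fit_window: tuple[float, float] = (0.0, 2000.0),
    seed: int = 0,
    period_ms: float = 160.0,
    sigmoid_span: tuple[float, float] | None = (-400.0, 600.0),
    mcmc_kwargs: dict | None = None,
    models: dict | None = None,
) -> TransitionAnalysis:
    """Fit per-taste/per-condition HMMs, realign, and compare conditions.

    For each taste and laser condition an HMM is fitted (or taken from
    ``models[(taste, cond)]``), trials are decoded and aligned to the onset
    of the state dominating ``state_window``, and the sigmoid/slope/latency
    comparisons are assembled.  Per-unit slope records are averaged across
    tastes before the Off-vs-On comparison.
    """
    mcmc_kwargs = mcmc_kwargs or {}
    n_units = dataset.n_units
    traces = {}
    slope_frames = {}
    for ci, cond in enumerate((False, True)):
        # per-unit pooled realigned trials, each unit aligned leave-one-out
        per_unit_sets: list[list] = [[] for _ in range(n_units)]
        for ti, taste in enumerate(TASTES):
            key = (taste, cond)
            if models is not None and key in models:
                model = models[key]
            else:
                model = fit_taste_hmm(
                    dataset, taste, cond, window=fit_window,
                    n_states=n_states, emission_bin_ms=emission_bin_ms,
                    restarts=restarts, seed=seed + 13 * ti + 101 * ci,
                )
            # target state from the full-ensemble posterior, then LOO onsets
            full = compute_alignment(
                model, dataset, taste, cond, window=state_window,
                fit_window=fit_window,
            )
            for u in range(n_units):
                al = compute_alignment(
                    model, dataset, taste, cond, window=state_window,
                    fit_window=fit_window, state=full.state, exclude_unit=u,
                )
                if not al.valid.any():
                    continue
                re = realign(dataset, al, span=span)
                unit_re = RealignedRasters(
                    data=re.data[:, [u], :],
                    trial_indices=re.trial_indices,
                    onsets_ms=re.onsets_ms,
                    t_start_ms=re.t_start_ms,
                    padded=re.padded,
                )
                per_unit_sets[u].append(
                    (unit_re, np.array([taste] * unit_re.n_trials))
                )
        if not any(per_unit_sets):
            raise ValueError("no valid aligned trials in a condition")
        unit_traces = []
        unit_slopes = []
        time_centers = None
        for u in range(n_units):
            if not per_unit_sets[u]:
                continue
            tr = aligned_palatability_trace(per_unit_sets[u])
            time_centers = tr.time_centers_ms
            unit_traces.append(tr.rho[0])
            pooled_re = RealignedRasters(
                data=np.concatenate(
                    [r.data for r, _ in per_unit_sets[u]], axis=0
                ),
                trial_indices=np.concatenate(
                    [r.trial_indices for r, _ in per_unit_sets[u]]
                ),
                onsets_ms=np.concatenate(
                    [r.onsets_ms for r, _ in per_unit_sets[u]]
                ),
                t_start_ms=span[0],
                padded=np.concatenate(
                    [r.padded for r, _ in per_unit_sets[u]]
                ),
            )
            unit_slopes.append(
                peri_transition_slopes(
                    pooled_re, period_ms=period_ms,
                    condition="On" if cond else "Off",
                )
            )
        rho = np.stack(unit_traces)
        with np.errstate(invalid="ignore"):
            mean_abs = np.nanmean(np.abs(rho), axis=0)
        traces[cond] = AlignedTrace(
            time_centers_ms=time_centers, rho=rho,
            p=np.full_like(rho, np.nan), mean_abs_rho=mean_abs,
        )
        slope_frames[cond] = pd.concat(unit_slopes, ignore_index=True)

    # the logistic is fitted to the rise into the target state; restricting
    # the span to the peri-transition region keeps the separate early
    # (identity-epoch) correlation plateau out of the fit
    tc = traces[False].time_centers_ms
    sel = np.ones(tc.size, bool)
    if sigmoid_span is not None:
        sel = (tc >= sigmoid_span[0]) & (tc < sigmoid_span[1])
    fit_off = fit_sigmoid(tc[sel], traces[False].mean_abs_rho[sel],
                          seed=seed + 7, **mcmc_kwargs)
    fit_on = fit_sigmoid(tc[sel], traces[True].mean_abs_rho[sel],
                         seed=seed + 8, **mcmc_kwargs)
    comparison = compare_slope_conditions(slope_frames[False],
                                          slope_frames[True],
                                          period_ms=period_ms)
    return TransitionAnalysis(
        state_window=state_window,
        sigmoid_off=fit_off,
        sigmoid_on=fit_on,
        sigmoid_slopes_differ=slopes_differ(fit_off, fit_on),
        comparison=comparison,
        trace_off=traces[False],
        trace_on=traces[True],
        slopes_off=slope_frames[False],
        slopes_on=slope_frames[True],
    )
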