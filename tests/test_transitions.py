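"""Transition sharpness: sigmoid fits, slope estimators, condition tests."""
import numpy as np
import pandas as pd
import pytest

from gctaste.hmm import RealignedRasters
from gctaste.transitions import (
    aligned_palatability_trace,
    compare_slope_conditions,
    fit_sigmoid,
    peri_transition_slopes,
    slopes_differ,
)
from gctaste.datamodel import PALATABILITY_RANKS, TASTES


def _logistic(t, lower, upper, t0, k):
    return lower + (upper - lower) / (1 + np.exp(-k * (t - t0)))


# -- sigmoid ----------------------------------------------------------------

def test_sigmoid_recovers_noise_free_parameters():
    t = np.arange(-1000, 1500, 25.0)
    y = _logistic(t, 0.1, 0.6, 50.0, 0.02)
    fit = fit_sigmoid(t, y, seed=0)
    s = fit.summary
    assert s.loc["lower", "mean"] == pytest.approx(0.1, rel=0.01, abs=0.002)
    assert s.loc["upper", "mean"] == pytest.approx(0.6, rel=0.01)
    assert s.loc["t0", "mean"] == pytest.approx(50.0, abs=5.0)
    assert s.loc["slope", "mean"] == pytest.approx(0.02, rel=0.05)
    for name, truth in (("lower", 0.1), ("upper", 0.6), ("t0", 50.0),
                        ("slope", 0.02)):
        assert s.loc[name, "ci_low"] <= truth <= s.loc[name, "ci_high"]


def test_ramp_input_yields_lower_slope_than_step():
    t = np.arange(-1000, 1500, 25.0)
    rng = np.random.default_rng(1)
    step = 0.1 + 0.5 * (t >= 0) + rng.normal(0, 0.02, t.size)
    ramp = 0.1 + 0.5 * np.clip((t + 300) / 600.0, 0, 1) + rng.normal(0, 0.02, t.size)
    f_step = fit_sigmoid(t, step, seed=2)
    f_ramp = fit_sigmoid(t, ramp, seed=3)
    assert f_ramp.slope_mean < f_step.slope_mean
    assert slopes_differ(f_step, f_ramp)


def test_sigmoid_requires_enough_windows():
    with pytest.raises(ValueError):
        fit_sigmoid(np.arange(10.0), np.zeros(10))


# -- peri-transition slopes -------------------------------------------------

def _rate_realigned(rate_fn, n_units=1, span=(-1000.0, 1500.0)):
    """RealignedRasters whose 'data' encode exact per-ms rates (Hz/1000)."""
    t = np.arange(span[0], span[1])
    data = np.tile(rate_fn(t) / 1000.0, (1, n_units, 1))
    return RealignedRasters(
        data=data, trial_indices=np.array([0]), onsets_ms=np.array([0.0]),
        t_start_ms=span[0], padded=np.array([False]),
    )


def test_linear_psth_slope_estimated_exactly():
    s = 0.05  # Hz/ms
    re = _rate_realigned(lambda t: 20.0 + s * t)
    rec = peri_transition_slopes(re)
    assert rec.loc[0, "max_abs_slope"] == pytest.approx(s, rel=1e-6)


def test_step_psth_max_slope_located_at_transition():
    re = _rate_realigned(lambda t: 5.0 + 10.0 * (t >= 0))
    rec = peri_transition_slopes(re)
    assert abs(rec.loc[0, "latency_ms"]) <= 20.0
    # LS slope of a centred step of height h over a window w is 1.5 h / w
    assert rec.loc[0, "max_abs_slope"] == pytest.approx(1.5 * 10 / 100, rel=0.05)


def test_slope_comparison_identity_case():
    rng = np.random.default_rng(4)
    off = pd.DataFrame({
        "max_abs_slope": rng.uniform(0.05, 0.3, 20),
        "slope": 0.0, "latency_ms": rng.uniform(-100, 100, 20),
        "condition": "Off",
    })
    on = off.assign(condition="On")
    c = compare_slope_conditions(off, on)
    assert c.regression_slope == pytest.approx(1.0, abs=1e-9)
    assert c.p_vs_unity > 0.9
    assert c.deming_slope == pytest.approx(1.0, abs=1e-9)
    assert c.latency_p > 0.9 or np.isnan(c.latency_p)


def test_slope_comparison_detects_attenuation():
    rng = np.random.default_rng(5)
    base = rng.uniform(0.05, 0.5, 40)
    off = pd.DataFrame({"max_abs_slope": base, "slope": 0.0,
                        "latency_ms": rng.uniform(-150, 150, 40),
                        "condition": "Off"})
    on = pd.DataFrame({"max_abs_slope": 0.4 * base + rng.normal(0, 0.01, 40),
                       "slope": 0.0,
                       "latency_ms": rng.uniform(-150, 150, 40),
                       "condition": "On"})
    c = compare_slope_conditions(off, on)
    assert c.regression_slope == pytest.approx(0.4, abs=0.05)
    assert c.p_vs_unity < 1e-6
    assert c.group_table is not None and len(c.group_table) == 5


def test_slope_comparison_small_sample_skips_grouping():
    off = pd.DataFrame({"max_abs_slope": [0.1, 0.2, 0.3], "slope": 0.0,
                        "latency_ms": [0.0, 20.0, -20.0], "condition": "Off"})
    on = off.assign(condition="On")
    c = compare_slope_conditions(off, on)
    assert c.grouping_skipped and c.group_table is None


def test_deming_corrects_symmetric_noise_attenuation():
    """With equal noise on both axes, OLS attenuates but Deming stays ~1."""
    rng = np.random.default_rng(6)
    true = rng.uniform(0.1, 0.5, 200)
    off = true + rng.normal(0, 0.08, true.size)
    on = true + rng.normal(0, 0.08, true.size)
    mk = lambda v, c: pd.DataFrame({"max_abs_slope": v, "slope": 0.0,
                                    "latency_ms": 0.0, "condition": c})
    c = compare_slope_conditions(mk(off, "Off"), mk(on, "On"))
    assert c.regression_slope < 0.85          # attenuated
    assert c.deming_slope == pytest.approx(1.0, abs=0.15)
    assert c.deming_ci[0] <= 1.0 <= c.deming_ci[1]


# -- aligned palatability trace --------------------------------------------

def _synthetic_realigned(rng, n_per_taste=15, gain=6.0, blur_ms=0.0,
                         span=(-1000.0, 1500.0)):
    """Step (or ramp) into rank-ordered rates at t = 0 for one unit."""
    t = np.arange(span[0], span[1])
    sets = []
    for taste in TASTES:
        rank = PALATABILITY_RANKS[taste]
        late = 8.0 + gain * (rank - 2.5)
        if blur_ms > 0:
            w = np.clip((t + blur_ms / 2) / blur_ms, 0, 1)
        else:
            w = (t >= 0).astype(float)
        rate = (8.0 * (1 - w) + late * w) * 1e-3
        data = (rng.random((n_per_taste, 1, t.size)) < rate[None, None, :])
        re = RealignedRasters(
            data=data.astype(float),
            trial_indices=np.arange(n_per_taste),
            onsets_ms=np.zeros(n_per_taste), t_start_ms=span[0],
            padded=np.zeros(n_per_taste, bool),
        )
        sets.append((re, np.array([taste] * n_per_taste)))
    return sets


def test_trace_rises_at_step_transition():
    rng = np.random.default_rng(7)
    tr = aligned_palatability_trace(_synthetic_realigned(rng))
    early = tr.time_centers_ms < -300
    late = tr.time_centers_ms > 300
    assert np.nanmean(tr.mean_abs_rho[early]) < 0.25
    assert np.nanmean(tr.mean_abs_rho[late]) > 0.5


def test_rank_shuffled_map_flattens_trace():
    rng = np.random.default_rng(8)
    sets = _synthetic_realigned(rng)
    shuffled = {"Sucrose": 2, "NaCl": 4, "Acid": 1, "QHCl": 3}
    tr = aligned_palatability_trace(sets, palatability_map=shuffled)
    late = tr.time_centers_ms > 300
    # monotone-rank correlation drops when ranks are scrambled
    assert np.nanmean(np.abs(tr.mean_abs_rho[late])) < 0.45


def test_blurred_transition_rises_more_slowly():
    rng = np.random.default_rng(9)
    sharp = aligned_palatability_trace(_synthetic_realigned(rng, blur_ms=0))
    blurred = aligned_palatability_trace(
        _synthetic_realigned(rng, blur_ms=600.0)
    )
    window = (sharp.time_centers_ms >= -200) & (sharp.time_centers_ms <= 200)
    rise_sharp = np.nanmax(np.diff(sharp.mean_abs_rho[window]))
    # compare the total change achieved within +/-100 ms of the transition
    near = (sharp.time_centers_ms >= -100) & (sharp.time_centers_ms <= 100)
    d_sharp = np.nanmax(sharp.mean_abs_rho[near]) - np.nanmin(sharp.mean_abs_rho[near])
    d_blur = np.nanmax(blurred.mean_abs_rho[near]) - np.nanmin(blurred.mean_abs_rho[near])
    assert d_blur < d_sharp


def test_decoupling_shifts_per_unit_latencies_but_spares_slopes():
    """Decoupling gives each unit a consistent transition lag on perturbed
    trials: max-slope latencies track the true per-unit offsets and spread
    out, while each unit's transition stays sharp (unlike blurring)."""
    from gctaste import GeneratorConfig, generate_ensemble
    from gctaste.hmm import TrialAlignment, realign

    n = 16
    cfg = GeneratorConfig.taste_specific(
        n, rng_seed=6, laser=True, decouple_jitter_sd_ms=80.0,
        laser_factor=np.ones(n), laser_onset_ms=np.zeros(n),
    )
    ds, truth = generate_ensemble(cfg)

    def records(cond):
        idx = np.nonzero(ds.trial_mask(laser=cond))[0]
        al = TrialAlignment(trial_indices=idx, state=0,
                            onset_ms=truth.transition_ms[idx],
                            valid=np.ones(idx.size, bool))
        return peri_transition_slopes(realign(ds, al))

    rec_off, rec_on = records(False), records(True)
    on_idx = np.nonzero(ds.trial_mask(laser=True))[0]
    delta = (truth.unit_transition_ms[on_idx]
             - truth.transition_ms[on_idx, None]).mean(axis=0)
    lat_on = rec_on["latency_ms"].to_numpy()
    lat_off = rec_off["latency_ms"].to_numpy()
    # On-trial latencies track the per-unit offsets; Off-trial ones do not
    assert np.corrcoef(delta, lat_on)[0, 1] > 0.3
    assert np.corrcoef(delta, lat_off)[0, 1] < 0.3
    # among units with a strong transition the latency spread widens
    jump = np.abs(truth.late_rates_hz.mean(axis=1)
                  - cfg.identity_rates_hz.mean(axis=1))
    strong = jump >= np.median(jump)
    assert np.std(lat_on[strong]) > np.std(lat_off[strong])
    # and the per-unit slopes are not systematically reduced
    c = compare_slope_conditions(rec_off, rec_on)
    assert c.p_vs_unity > 0.05
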