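"""Per-unit statistics: detection power, null calibration, oracle checks."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gctaste.single_unit import (
    classify_unit_type,
    direction_profile,
    impact_latency,
    palatability_correlation,
    taste_responsive,
    taste_specific,
)
from gctaste.datamodel import PALATABILITY_RANKS, TASTES

from conftest import bernoulli_raster, unit_raster_off_on


def _raster(pre_hz, post_hz, n_trials, rng):
    profile = np.r_[np.full(2000, pre_hz), np.full(2500, post_hz)]
    return bernoulli_raster(profile, n_trials, rng)


def _table(n_trials):
    reps = n_trials // 4
    tastes = np.repeat(TASTES, reps)
    laser = np.tile(np.r_[np.zeros(reps // 2, bool), np.ones(reps - reps // 2, bool)], 4)
    return pd.DataFrame({"trial_index": np.arange(n_trials), "taste": tastes,
                         "laser_on": laser})


# -- responsivity -----------------------------------------------------------

def test_strong_evoked_response_detected():
    rng = np.random.default_rng(0)
    flag, t, p = taste_responsive(_raster(2, 12, 60, rng), _table(60))
    assert flag and t > 0 and p < 1e-6


def test_responsivity_type_one_error_calibrated():
    rng = np.random.default_rng(1)
    hits = 0
    n_sim = 1000
    for _ in range(n_sim):
        x = _raster(6, 6, 60, rng)
        hits += taste_responsive(x, _table(60))[0]
    assert 0.03 <= hits / n_sim <= 0.07


def test_opposing_taste_responses_cancel_in_responsivity():
    """Equal-and-opposite evoked changes: non-responsive yet taste-specific."""
    rng = np.random.default_rng(2)
    reps = 30
    x = np.zeros((120, 4500), dtype=np.uint8)
    x[:, :2000] = rng.random((120, 2000)) < 8e-3
    evoked = np.repeat([14.0, 14.0, 2.0, 2.0], reps) * 1e-3  # mean stays 8
    x[:, 2000:] = rng.random((120, 2500)) < evoked[:, None]
    table = _table(120)
    flag, _, p = taste_responsive(x, table)
    assert not flag
    spec, _ = taste_specific(x, table)
    assert spec


# -- specificity ------------------------------------------------------------

def test_one_elevated_taste_detected_as_specific():
    rng = np.random.default_rng(3)
    rates = np.repeat([15.0, 5.0, 5.0, 5.0], 30) * 1e-3
    x = np.zeros((120, 4500), dtype=np.uint8)
    x[:, 2000:] = rng.random((120, 2500)) < rates[:, None]
    flag, aov = taste_specific(x, _table(120))
    assert flag
    assert set(aov["Source"]) >= {"taste", "time", "Interaction"}


def test_time_course_difference_detected_via_interaction():
    """Tastes with equal 2-s means but crossing time courses."""
    rng = np.random.default_rng(4)
    x = np.zeros((120, 4500), dtype=np.uint8)
    up = np.r_[np.full(1000, 4.0), np.full(1500, 12.0)] * 1e-3
    down = np.r_[np.full(1000, 12.0 + 4.0), np.full(1500, 4.0 + 4.0 / 3)] * 1e-3
    for i, taste in enumerate(_table(120)["taste"]):
        prof = up if taste in ("Sucrose", "NaCl") else down
        x[i, 2000:] = rng.random(2500) < prof
    flag, aov = taste_specific(x, _table(120))
    pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
    p_inter = float(aov.loc[aov["Source"] == "Interaction", pcol].iloc[0])
    assert flag and p_inter < 0.05


def test_specificity_type_one_error_calibrated():
    """Component test ~5%; the either-effect flag is a union of two 5%
    tests, so its null rate sits near 1 - 0.95**2 ~ 10%."""
    flag_hits = 0
    taste_hits = 0
    n_sim = 400
    for i in range(n_sim):
        rng = np.random.default_rng(10_000 + i)
        flag, aov = taste_specific(_raster(8, 8, 120, rng), _table(120))
        flag_hits += flag
        pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
        taste_hits += float(
            aov.loc[aov["Source"] == "taste", pcol].iloc[0]
        ) < 0.05
    assert 0.025 <= taste_hits / n_sim <= 0.085
    assert 0.065 <= flag_hits / n_sim <= 0.135


def test_specificity_requires_all_tastes():
    rng = np.random.default_rng(5)
    table = _table(120).copy()
    table.loc[table["taste"] == "QHCl", "taste"] = "Acid"
    with pytest.raises(ValueError):
        taste_specific(_raster(5, 5, 120, rng), table)


# -- neuron type ------------------------------------------------------------

@pytest.mark.parametrize("width,expected",
                         [(0.30, "IN"), (0.50, "PC"), (0.35, "PC"),
                          (0.349, "IN")])
def test_half_width_classification(width, expected):
    assert classify_unit_type(width) == expected


def test_half_width_must_be_positive():
    with pytest.raises(ValueError):
        classify_unit_type(0.0)


# -- palatability correlation ----------------------------------------------

def _ranked_raster(gain_hz, sign, n_per_taste, rng, base_hz=8.0,
                   onset_ms=700):
    table = _table(4 * n_per_taste)
    ranks = table["taste"].map(PALATABILITY_RANKS).to_numpy(float)
    x = np.zeros((len(table), 4500), dtype=np.uint8)
    pre = base_hz * 1e-3
    x[:, :2000 + onset_ms] = rng.random((len(table), 2000 + onset_ms)) < pre
    late = np.maximum(base_hz + sign * gain_hz * (ranks - 2.5), 0.1) * 1e-3
    n_late = 4500 - 2000 - onset_ms
    x[:, 2000 + onset_ms:] = rng.random((len(table), n_late)) < late[:, None]
    return x, table


def test_rank_proportional_rates_flagged_with_high_rho():
    rng = np.random.default_rng(6)
    x, table = _ranked_raster(9.0, +1, 30, rng)
    trace = palatability_correlation(x, table)
    assert trace.flagged
    late = trace.time_centers_ms > 1200
    assert np.nanmean(trace.rho[late]) > 0.8


def test_anti_ordered_rates_still_flagged():
    rng = np.random.default_rng(7)
    x, table = _ranked_raster(9.0, -1, 30, rng)
    trace = palatability_correlation(x, table)
    assert trace.flagged
    late = trace.time_centers_ms > 1200
    assert np.nanmean(trace.rho[late]) < -0.8


def test_zero_variance_windows_are_missing_and_never_significant():
    table = _table(120)
    trace = palatability_correlation(np.zeros((120, 4500), np.uint8), table)
    assert np.all(np.isnan(trace.rho))
    assert not trace.flagged


def test_trace_matches_independent_rank_correlation():
    """Spearman per window equals rank-then-Pearson computed from scratch."""
    rng = np.random.default_rng(8)
    x, table = _ranked_raster(5.0, +1, 15, rng)
    trace = palatability_correlation(x, table)
    ranks = table["taste"].map(PALATABILITY_RANKS).to_numpy(float)
    check_idx = rng.choice(trace.rho.size, 5, replace=False)
    for k in check_idx:
        t0 = trace.time_centers_ms[k] - 125.0
        i0 = int(t0 + 2000)
        rates = x[:, i0 : i0 + 250].sum(axis=1).astype(float)
        if np.ptp(rates) == 0:
            assert np.isnan(trace.rho[k])
            continue
        def midranks(v):
            order = np.argsort(v, kind="mergesort")
            r = np.empty(v.size)
            r[order] = np.arange(1, v.size + 1)
            for val in np.unique(v):
                m = v == val
                r[m] = r[m].mean()
            return r
        rr = np.corrcoef(midranks(rates), midranks(ranks))[0, 1]
        assert trace.rho[k] == pytest.approx(rr, abs=1e-12)


# -- impact latency and direction ------------------------------------------

def test_impact_latency_recovers_delayed_onset():
    rng = np.random.default_rng(9)
    table = _table(120)
    laser = table["laser_on"].to_numpy()
    x = unit_raster_off_on(16.0, 4.0, laser, rng, onset_ms=750)
    lat = impact_latency(x, table)
    assert lat is not None and 650 <= lat <= 850


def test_impact_latency_none_without_effect():
    rng = np.random.default_rng(10)
    table = _table(120)
    x = unit_raster_off_on(10.0, 10.0, table["laser_on"].to_numpy(), rng)
    assert impact_latency(x, table) is None


def test_impact_latency_immediate_onset():
    rng = np.random.default_rng(11)
    table = _table(120)
    x = unit_raster_off_on(16.0, 4.0, table["laser_on"].to_numpy(), rng)
    lat = impact_latency(x, table)
    assert lat is not None and lat <= 100


def test_direction_profile_pure_suppression_is_consistent():
    rng = np.random.default_rng(12)
    table = _table(120)
    x = unit_raster_off_on(16.0, 6.0, table["laser_on"].to_numpy(), rng)
    prof = direction_profile(x, table)
    assert prof.consistent
    assert np.all(prof.diff_hz < 0)


def test_direction_profile_null_has_no_significant_bins():
    rng = np.random.default_rng(13)
    table = _table(120)
    x = unit_raster_off_on(10.0, 10.0, table["laser_on"].to_numpy(), rng)
    prof = direction_profile(x, table)
    assert prof.consistent
    assert np.sum(prof.p < 0.01) <= 1


def test_direction_profile_delayed_suppression_shape():
    rng = np.random.default_rng(14)
    table = _table(120)
    x = unit_raster_off_on(16.0, 4.0, table["laser_on"].to_numpy(), rng,
                           onset_ms=750)
    prof = direction_profile(x, table)
    assert np.all(np.abs(prof.diff_hz[:3]) < 3.0)
    assert np.all(prof.diff_hz[4:] < -6.0)
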