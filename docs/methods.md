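# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limits of the package. It states no empirical result
that the test suite or `scripts/acceptance.py` do not themselves compute.

## Data model

A session is a binary raster (trials × units × 1-ms bins) over −2000…+2500
ms around taste delivery, a trial table (taste ∈ {Sucrose, NaCl, Acid,
QHCl}; laser Off/On), and a unit table (spike half-width, session id).
Windows are half-open `[t0, t1)`; rates are Hz; hedonic ranks are
Sucrose 4 > NaCl 3 > Acid 2 > QHCl 1. Sessions serialize to one HDF5 file
with object timestamps disabled, so identical content yields identical
bytes.

## Synthetic ensembles

Spiking is an independent Bernoulli per 1-ms bin with probability rate ×
1 ms — an inhomogeneous Poisson process to within 1% at cortical rates, and
exactly the emission family the GLM and HMM stages assume. Each trial's
rate profile steps through baseline → detection (0–200 ms, nonspecific) →
identity (200 ms → τ, taste-specific) → late/palatability (τ → end), with
τ ~ Normal(700, 150) ms truncated to (250, 2400).

Default rate structure (the `taste_specific` factory): baselines uniform
2–8 Hz; detection adds a nonspecific 3 Hz; identity adds an independent
Gamma(2, 5 Hz) excess per (unit, taste); the late state has its own
per-unit base rate, baseline + Gamma(2, 6 Hz), modulated by ±4 Hz per
hedonic-rank step with a random per-unit sign. Two of these choices are
worth explaining:

- **The late state is a new rate vector, not a modulation of identity
  firing.** The phenomenon these analyses target is a sudden, coherent,
  multi-Hz ensemble rate switch; with late rates tied to identity rates the
  switch would be invisible for mid-ranked tastes and undetectable by any
  state model. State-to-state jumps of ~5–12 Hz on baselines of 2–8 Hz keep
  all rates in the 0.1–30 Hz cortical range while making the transition a
  real single-trial event, and are required for 15–30-trial PSTH slope
  estimates to carry signal at all (at jumps of ~3 Hz the 100-ms-window
  least-squares slope estimator is noise-dominated and any Off-vs-On
  regression collapses toward zero by attenuation, regardless of the true
  effect).
- **Rank spacing of 4 Hz.** Single-trial firing rates in a 250-ms window at
  ~15 Hz have an SD near 8 Hz, and identity-epoch tuning produces sizeable
  *chance* rank correlations (a random assignment of four distinct rate
  means to four ranks has mean |ρ| ≈ 0.5 before noise attenuation). For the
  realigned correlation trace to *rise* into the late epoch — the effect
  under study — the rank spacing must be comparable to the within-taste
  SD; 4 Hz puts the late-epoch |ρ| near 0.5, above the ~0.28 identity-epoch
  chance floor.

Perturbation (laser) trials support three mechanisms, separately
configurable: a per-unit multiplicative rate factor applied from a per-unit
onset (suppression < 1 or enhancement > 1, never both in one unit — the
factory draws ×0.5 for 60% of units, ×1.5 for the rest, onsets from the
bimodal latency mixture below); *blurring*, which replaces the identity→late
rate step with a linear ramp of configurable duration centred on τ; and
*decoupling*, which offsets each unit's τ by a consistent per-unit lag
on laser trials (drawn once per ensemble) — each neuron still transitions
sharply, but the ensemble no longer does so simultaneously. Blur and decouple
correspond to the two candidate mechanisms for a shallower ensemble
transition — a genuine per-neuron slowing versus a loss of cross-neuron
simultaneity — and the transition stage can discriminate them.

Ground truth (per-trial τ, per-unit-per-trial τ after jitter, laser factors
and onsets, taste-specificity flags, late-state rates) is returned with
every ensemble.

The impact-latency generator draws from a 2-component Gaussian mixture
(reference parameters: equal weights, means 347.28 / 754.39 ms, SDs
110 / 179 ms) truncated by rejection to [0, 2500] ms.

## Single-unit statistics

*Responsivity*: paired *t* across trials of evoked (0–2 s) vs baseline
(−2–0 s) mean rates, collapsed over tastes; two-sided α = 0.05. A unit
whose tastes push firing in opposite directions can be non-responsive yet
taste-specific; that is a property of the definition, not a defect.

*Specificity*: mixed two-way ANOVA (pingouin), trials as subjects, taste
between, time within (four 500-ms bins of the first 2 s); flagged when the
taste main effect *or* the taste × time interaction has p < .05. Because
the flag is a union of two α = 0.05 tests, its null rate is ≈ 1 − 0.95² ≈
10%, not 5%; the test suite asserts exactly that. No sphericity correction
is applied.

*Palatability*: Spearman ρ between single-trial rates and ranks per 250-ms
window stepped 25 ms over [0, 2500); average-rank ties; zero-variance
windows yield missing ρ and can never be significant; a unit is flagged
when ≥3 consecutive windows have p < .05 (sign-agnostic).

*Neuron type*: IN below 0.35 ms half-width, PC at or above (the boundary
value is assigned to PC; the source classification used strict
inequalities on both sides, leaving the boundary open).

## Laser-impact GLM

Per unit, whole-trial (0–2.5 s) spike counts are Poisson with
log λ(T,O) = μ + α_T + β_O + γ_TO; priors α, β, γ ~ Normal(0, σ_fam) with
σ_fam ~ HalfNormal(1), μ ~ Normal(log mean rate, 3). The posterior is
sampled with emcee's affine-invariant ensemble sampler (40 walkers, 1000
burn-in + 2000 kept steps by default, thin 2 — long enough that Monte
Carlo error in the 2.5%/97.5% tail percentiles no longer inflates the
false-positive rate), seeded for reproducibility;
walker initialization is a small ball around the data-scale center. The
per-taste contrast exp η(T,On) − exp η(T,Off) (Hz) is summarized by its
posterior mean and central 95% interval; significance = interval excludes
zero; a unit is *impacted* when any taste is significant. The hierarchical
shrinkage makes the null calibration conservative (fewer than 10% of
laser-inert units are flagged in the test suite's 40-unit run). Low mean
acceptance fraction (< 0.1) is recorded as a warning on the result.

Impact latency uses Welch *t* tests on per-trial rates in 100-ms bins
(pooled across tastes, Off vs On); the latency is the start of the first
run of ≥2 consecutive significant bins. Direction profiles use ten 250-ms
bins with per-bin Welch tests and a same-sign consistency flag.

## Latency-distribution models

The 2-component Gaussian mixture is fitted to the raw latencies by EM
(authored here so the per-iteration log-likelihood trace is available and
checked non-decreasing on every fit), best of `restarts` seeded
initializations, SD floor 1 ms; a degenerate sample or coincident
components are flagged `collapsed`. The exponential A·e^{−λt} is
least-squares fitted to the 25 × 100 ms histogram. Both models are scored
by R² against that histogram, and compared by a paired *t* (df = 24) on
per-bin absolute errors. The mixture is fixed at k = 2; no information
criteria are computed.

## Decoding

Leave-one-trial-out nearest-template classification: features are spike
counts in 250-ms bins over 250–1750 ms (six bins × units, concatenated —
identical to accumulating per-bin unit-space distances); templates are
per-taste means excluding the held-out trial; distance ties break by the
fixed taste order and are counted. Cross-condition classification trains
templates on all trials of one laser condition and scores the other (no
jack-knife needed, the sets being disjoint). A finite-sample caveat the
test suite quantifies: on taste-nonspecific data the leave-one-out rule
scores slightly *below* the nominal 25% chance (≈24–24.5% at 30
trials/taste), so chance-level checks average replicate ensembles rather
than trusting one draw.

## Ensemble HMM and realignment

Emissions are independent Poisson per unit in 10-ms bins (configurable);
the transition matrix is unconstrained (no left-to-right restriction);
fitting is Baum–Welch with scaled forward–backward recursions, vectorized
over trials, floor 10⁻⁶ on rates. Initialization matters at 15–30 trials:
state rates start from contiguous temporal segments of the trial-averaged
response, alternating equal-width and front-compressed segment edges across
restarts (early response phases are short), with lognormal jitter;
transition matrices start sticky (0.95 diagonal). Default 4 states per
taste × condition over the 0–2000 ms fit window; the two-phase recovery
studies in the tests use 2–3 states. The winner of `restarts` runs by final
log-likelihood is returned, with every restart's final log-likelihood, the
EM trace (asserted non-decreasing), and a convergence flag.

State identification for a target window (palatability 500–1500 ms,
identity 100–600 ms) scores each state by in-window minus out-of-window
posterior mass, skipping states already occupied at trial start (which have
no onset to align to); the literal highest-in-window-mass rule is available
via `exclude_initial_ms=0`. Per-trial onsets are the first 0.5 posterior
crossing that begins a ≥5-bin (50 ms) run; the dwell requirement suppresses
single-bin posterior blips that otherwise produce occasional wild onsets
(`min_dwell_bins=1` restores the literal first crossing). Trials that never
cross are invalid and excluded from realignment. Realigned rasters span
−1000…+1500 ms about the onset, NaN-padded where the span leaves the
recorded range.

**Leave-one-unit-out alignment.** Aligning trials by a threshold crossing
computed from the very spikes being averaged imprints a selection
discontinuity at t = 0 on the realigned PSTH — sharp enough, at these
ensemble sizes, to completely mask a genuinely ramped (blurred) transition.
The transition pipeline therefore identifies the state once from the
full-ensemble posterior, then aligns each unit's trials using the posterior
decoded from the *other* units only. Conditional on the other units'
spikes, a unit's own realigned rate profile is an unbiased image of its
true peri-transition dynamics.

## Transition dynamics

The realigned palatability trace is the moving-window (250 ms / 25 ms)
Spearman ρ per unit, trials pooled across the four tastes; windows
containing padded samples drop those trials; the ensemble summary is mean
|ρ| across units. A Bayesian 4-parameter logistic (lower, upper − lower ~
HalfNormal(1), inflection uniform over the span, growth rate k ~
HalfNormal(0.1 /ms), Gaussian noise σ ~ HalfNormal(0.5), σ ≥ 10⁻⁴) is
fitted by seeded ensemble MCMC to the trace restricted to −400…+600 ms
around the transition (the identity-epoch correlation plateau is a separate
feature that otherwise corrupts the fit; the full span is available).
"Slope" is the growth rate k; the maximum derivative k·(upper−lower)/4 is
also reported. Two conditions differ when their 95% slope credible
intervals do not overlap — deliberately the interval-overlap rule, not a
posterior-difference test.

Per-unit peri-transition slopes: the transition-aligned PSTH (NaN-aware
trial mean at 1-ms resolution) is scanned with 100-ms windows stepped 20 ms
within ±160 ms of the onset (the ±160 reading of the "160 ms
peri-transition period"; a half-width switch is a parameter); each window's
slope is the least-squares regression of rate on time; the record is the
maximum |slope| (Hz/ms) and its window-centre latency. For a linear PSTH
the estimator equals the true derivative exactly; for a step of height h it
peaks at 1.5 h / window at the step location.

Condition comparison: OLS of On on Off max-|slope| with a *t* test of the
fitted slope against 1; an errors-in-variables Deming slope (error-variance
ratio 1 — both axes are estimated the same way — with a jackknife-over-units
95% CI), which is the appropriate estimator when *testing* slope = 1
because symmetric estimation noise attenuates OLS below 1 even for
identical conditions; Off-slope quintile means with per-group paired *t*
tests (skipped below 5 units); max-slope latency histograms in 20-ms bins
compared by χ² (empty shared bins dropped); and a paired *t* of
per-ensemble latency means when ≥2 ensembles are supplied, else a Welch *t*
across units. Slope units are Hz/ms throughout.

The identity-transition analysis is the same machinery pointed at the
100–600 ms state window. In the blur-only validation experiment (28 units,
30 trials/taste, blur 400 ms, rate factors 1) the test suite asserts the
four-part pattern in kind: disjoint sigmoid-slope intervals with On
shallower; OLS On-on-Off slope significantly below 1 for the late
transition; statistically indistinguishable max-slope latency histograms;
and an identity-transition Deming slope compatible with unity.

## Problem sizes and runtime

Test-suite simulation sizes are chosen so the full suite runs in minutes on
one CPU: type-I calibrations use 1000 (paired *t*) and 400 (mixed ANOVA)
simulated units; GLM calibration 40 null + 20 effect units at reduced MCMC
length; onset recovery 20 seeded two-state datasets; sigmoid coverage 40
seeded fits; the dissociation experiment one 28-unit session with 8 EM
restarts. The acceptance script averages 50 replicate null ensembles and 5
taste-specific ensembles.

## Known limitations

- The generator's trials are exchangeable: no adaptation, satiety, drift,
  or cross-trial correlation, and no within-state rate dynamics; real
  sessions have all of these, so passing tests validate the estimators'
  logic and calibration, not robustness to nonstationarity.
- Bernoulli/Poisson spiking has no refractoriness or bursting;
  overdispersed units would widen every interval the GLM and HMM report.
- Spike half-widths are synthesized independently of firing properties, so
  the IN/PC split is exercised only as a classification rule.
- The decoder's finite-sample chance level sits slightly below 25% (above).
- The Deming CI uses a normal approximation over a jackknife; at very small
  unit counts it is wide and its endpoints unstable.
- Separate HMMs per taste × condition is the default; a shared-fit mode
  (fit Off, decode On) exists but transition-matrix parameters are then
  biased toward the control dynamics.
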