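# gctaste

Analysis tools for trial-structured ensemble electrophysiology of cortical
taste coding under optogenetic perturbation — and a ground-truth synthetic
spike-train generator for validating every stage of the chain.

## The scientific problem

Gustatory cortex (GC) taste responses unfold in epochs: a nonspecific
"detection" phase (~0–200 ms after taste delivery), taste-specific
"identity" firing (~200–750 ms), and "palatability" firing whose rates
order with the hedonic value of the tastant (Sucrose > NaCl > Citric Acid >
Quinine-HCl). The switch into the palatability epoch is a sudden, coherent
ensemble state transition whose latency varies from trial to trial, so
stimulus-aligned averages blur it; single-trial state inference is needed to
see it. Perturbing an input pathway (e.g. amygdalar axons, via a laser on
half the trials) can change single-neuron firing rates, taste decodability,
palatability correlations — or specifically the *sharpness* of the ensemble
transition. This package implements the full analysis battery needed to
distinguish those outcomes:

- **Single-unit statistics** — taste responsivity (paired *t* of evoked vs
  baseline rate), taste specificity (mixed two-way ANOVA, taste × time),
  moving-window Spearman correlation of firing with hedonic rank (250 ms
  window, 25 ms step, ≥3 consecutive significant windows), and a putative
  interneuron/pyramidal split at 0.35 ms spike half-width.
- **Laser impact** — a hierarchical Bayesian Poisson GLM per neuron:
  log λ(T,O) = μ + α_T + β_O + γ_TO on whole-trial spike counts, with
  Normal(0, σ_fam) effect priors and HalfNormal(1) family scales, sampled by
  MCMC. A taste response is *impacted* when the 95% credible interval of
  its On−Off rate contrast excludes zero. Impact onset latencies are
  profiled in 100-ms bins, and their distribution is compared between a
  2-component Gaussian mixture (EM) and an exponential decay, via histogram
  R² and a paired *t* over the 25 bins of the 100-ms histogram.
- **Taste decoding** — leave-one-trial-out nearest-template classification
  by Euclidean distance on 250-ms binned ensemble responses (250–1750 ms);
  chance is 25% with four tastes. A cross-condition variant trains on one
  laser condition and tests on the other.
- **Ensemble state inference** — Poisson ensemble hidden Markov models
  (Baum–Welch EM, best-of-restarts, 10-ms emission bins). The palatability
  state is the state specific to the 500–1500 ms window; its per-trial
  onset is the first sustained 0.5 posterior crossing; trials are re-zeroed
  to those onsets.
- **Transition dynamics** — realigned palatability-correlation traces with
  Bayesian 4-parameter logistic fits (conditions differ when the 95%
  credible intervals of the slope do not overlap); per-unit peri-transition
  PSTH slopes (100 ms window, 20 ms step, ±160 ms) with OLS and
  errors-in-variables (Deming) Off-vs-On regressions, slope-quintile
  tables, and max-slope latency comparisons.

The synthetic generator produces labeled ensembles with exactly this epochal
structure, per-trial Gaussian transition latencies, and configurable
perturbation modes (per-unit rate scaling with onset latency; transition
*blurring* — a linear ramp replacing the rate step; or transition
*decoupling* — per-unit latency jitter), so every estimator can be checked
against ground truth.

## Worked example

```python
import numpy as np
from gctaste import (GeneratorConfig, generate_ensemble, jackknife_classify,
                     transition_pipeline)

# 28-unit session whose only laser effect is blurring the late transition
n = 28
cfg = GeneratorConfig.taste_specific(n, rng_seed=4, laser=True, blur_ms=400.0,
                                     laser_factor=np.ones(n),
                                     laser_onset_ms=np.zeros(n))
ds, truth = generate_ensemble(cfg)

print(jackknife_classify(ds, "Off").per_taste_accuracy.round(2).to_dict())
ana = transition_pipeline(ds, state_window=(500., 1500.), n_states=4,
                          restarts=8, seed=9)
print(round(ana.sigmoid_off.slope_mean, 4), round(ana.sigmoid_on.slope_mean, 4),
      ana.sigmoid_slopes_differ)
c = ana.comparison
print(round(c.regression_slope, 3), round(c.p_vs_unity, 5), round(c.latency_p, 3))
```

prints

```
{'Sucrose': 1.0, 'NaCl': 1.0, 'Acid': 1.0, 'QHCl': 1.0}
0.0446 0.0066 True
0.434 0.00712 0.06
```

— taste identity stays decodable well above the 25% chance level, while the
rise of the realigned palatability correlation is significantly shallower on
perturbed trials (logistic growth rates 0.045 vs 0.007 /ms, credible
intervals disjoint), per-unit peri-transition slopes regress On-on-Off with
slope 0.43 (significantly below the unity line, p ≈ 0.007), and the
max-slope latency distributions do not differ (χ² p ≈ 0.06): the signature
of a perturbation that blurs the transition without decoupling or silencing
it.

A command-line interface mirrors the stages (`gctaste synth`, `units`,
`latency`, `decode`, `hmm-fit`, `hmm-align`, `transitions`, `pipeline`);
`gctaste pipeline --config run.yaml --out results/` runs everything and
writes a consolidated JSON report.

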