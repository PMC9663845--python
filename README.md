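# numadapt

Behavioral and EEG/ERP analysis of **numerosity adaptation**: does the
brain's electrophysiological response track the *physical* number of items
in a display, or the number we *perceive*?

Prolonged exposure to a high-numerosity dot cloud (an "adaptor") makes a
subsequent test stimulus at that location appear ~20% less numerous than it
is, with no physical change to the stimulus. The analysis this package
implements contrasts three conditions — **Baseline** (no adaptor),
**Adaptation** (48-dot adaptor) and **Neutral** (adaptor matched to the
test numerosity) — in both verbal numerosity estimates and 30-channel
epoched EEG, and asks which ERP components follow the perceptual illusion.
The signature of interest is the posterior **P2p** component (~200–250 ms):
a left-lateralized amplitude reduction under Adaptation only, correlating
with the behavioral underestimation, while the earlier P1/N1 components
follow physical stimulus properties.

The package provides, for users running or simulating such experiments:

- **`numadapt.synthetic`** — generators for behavioral estimate tables and
  epoched EEG with the full effect structure (parametric ERP components on
  Gaussian temporal kernels + 1/f noise + alpha), so the entire analysis is
  testable without any recording.
- **`numadapt.behavior`** — quartile-based response pruning, one-way and
  two-way repeated-measures ANOVAs with Tukey–Kramer post-hocs and η²,
  per-participant adaptation magnitude, and the a-priori noncentral-F
  sample-size computation.
- **`numadapt.preprocess`** — FIR band-pass (1–40 Hz, −6 dB at 0.5/40.5 Hz),
  downsampling to 250 Hz, spherical-spline bad-channel interpolation,
  average reference, epoching (−200..600 ms, baseline −200..0 ms) and
  peak-to-peak epoch rejection.
- **`numadapt.resampling`** — the statistical core: per-time-point paired
  bootstrap tests (participants resampled with replacement, 20,000
  iterations by default), Benjamini–Hochberg FDR across time, and a
  temporal-persistence criterion (≥ 4 consecutive samples = 16 ms at
  250 Hz); window amplitudes with bootstrap intervals; electrode-cluster
  topographies; Spearman brain–behavior correlation.
- **`numadapt.models`** — a statsmodels-style surface:
  `BehavioralAdaptation(table).fit()` and
  `PointwiseContrast.from_erps(...).fit()` return results objects with
  estimates, uncertainties and `summary()`.

## The statistics in brief

For a paired contrast between conditions A and B, each participant
contributes a cluster-averaged ERP; at every post-stimulus time point *t*
the bootstrap resamples participants with replacement and recomputes the
mean difference, giving

&nbsp;&nbsp;p(t) = min(1, 2·min(P(D\*(t) ≤ 0), P(D\*(t) ≥ 0)))

with the (count+1)/(B+1) small-sample correction. BH-FDR is applied across
the post-stimulus time points of the contrast, and surviving points are
reported only in runs of ≥ `min_run` consecutive samples. The a-priori
sample size solves for the smallest *n* with
power(F; df₁=(m−1)ε, df₂=(n−1)(m−1)ε, λ=f²·n·m/(1−ρ)) ≥ target — with
f=0.30, α=0.05, target power 0.90, m=3, ρ=0.5, ε=1 this gives **n = 25**.

## Worked example

```python
from numadapt import (BehavioralAdaptation, PointwiseContrast,
                      default_scenario, simulate_experiment)

scenario = default_scenario(seed=7)
sim = simulate_experiment(scenario, seed=7)
erps = {p: {c: ep.average() for c, ep in d.items()}
        for p, d in sim["epochs"].items()}

print(BehavioralAdaptation(sim["behavior"]).fit().summary())
res = PointwiseContrast.from_erps(erps, ("Adaptation", "Neutral"),
                                  cluster="left").fit(n_boot=2000, seed=7)
print(res.summary())
```

prints

```
Behavioral numerosity adaptation
========================================
  Adaptation   mean estimate   23.4 dots (SEM 0.53)
  Baseline     mean estimate   29.5 dots (SEM 0.25)
  Neutral      mean estimate   29.4 dots (SEM 0.27)
  Condition RM-ANOVA: F(2,48) = 145.14, p = 4.44e-21, eta2 = 0.704
    Adaptation vs Baseline: adjusted p = 4.66e-15
    Adaptation vs Neutral: adjusted p = 4.66e-15
    Baseline vs Neutral: adjusted p = 0.912
  Adaptation magnitude: 20.2% underestimation (Neutral vs Adaptation), 25/25 participants positive
  Filling trials Condition effect: F(1,24) = 0.154, p = 0.698
  Condition x Numerosity interaction: F(3,72) = 0.177, p = 0.912

Point-wise bootstrap contrast: Adaptation - Neutral (left)
====================================================
  150 time points, 2000 bootstrap iterations, alpha = 0.05, persistence >= 4 samples
  significant 176-268 ms, mean diff -0.58 uV
```

Reading: the simulated cohort underestimates the 30-dot test by ~20% after
the high adaptor (all 25 participants), estimates are veridical at Baseline
and after the Neutral adaptor, and the ERP contrast localizes a reliable
Adaptation < Neutral amplitude reduction spanning the P2p range on the
left-posterior cluster. The same fit on `cluster="right"` returns
"no significant windows".

A full run (simulation → preprocessing → statistics → JSON/summary bundle)
is one command:

```bash
numadapt run --out results_dir --seed 7
```

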