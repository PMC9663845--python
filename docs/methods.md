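# Methods

This note documents the generative model, the statistical procedures, the
defaults and the numerical choices behind `numadapt`, in the package's own
terms. It states no empirical numbers beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Study design being modelled

A numerosity-estimation experiment with three within-participant
conditions. On adaptation trials, two adaptor clouds (one of 48 dots, one
matched to the upcoming test) precede a 300 ms test stimulus of 22, 26, 30,
35 or 41 dots presented at one adaptor's location; the **Adaptation**
condition is the test at the high adaptor's location, **Neutral** at the
matched adaptor's location, and **Baseline** trials have no adaptor.
Participants report a verbal estimate on a random third of trials. The
central numerosity (30) carries the EEG contrast of interest; the other
numerosities ("filling trials") map responses to physical numerosity and
are additionally pooled into **LowNum** (22/26) and **HighNum** (35/41)
conditions.

## Behavioral generative model

Estimate = condition mean + participant bias + trial noise, rounded to an
integer count and truncated at 1 dot. The Adaptation mean is
`true_numerosity * (1 - u)` with `u` the underestimation fraction
(default 0.20); Baseline and Neutral share the veridical mean, for every
numerosity. Defaults and rationale:

| parameter | default | why |
|---|---|---|
| `n_participants` | 25 | the cohort size indicated by the a-priori power analysis |
| `underestimation_fraction` | 0.20 | the canonical adaptation aftereffect magnitude |
| `trials_per_condition` | 80 | ≈ 240 presentations of the central numerosity per condition × 1/3 verbal-report rate |
| `filling_trials_per_cell` | 8 | ≈ 24 presentations × 1/3 report rate |
| `participant_bias_sd` | 1.5 dots | stable idiosyncratic over/under-estimation; keeps individual means within a plausible 27–33 range |
| `trial_noise_sd` | 4 dots | estimation noise at a Weber fraction of ~0.15 for a 30-dot stimulus |

Single-trial estimate variability is not externally constrained, so the
last two rows are this package's choices; they are free parameters of the
generator, set once.

In `simulate_experiment` a per-participant latent scales the adaptation
effect (relative SD 0.3, so nearly all participants adapt but by different
amounts). Two correlated copies of the latent (correlation `coupling`,
default 0.8) drive the behavioral underestimation and the left-P2p
amplitude deficit, which is what makes the brain–behavior Spearman
correlation recoverable rather than assumed.

## EEG generative model

`data[trial, ch, t] = Σ_components (A_c(condition) + jitter_trial) ·
w_c(ch) · exp(-(t - μ_c)²/2σ_c²) + 1/f noise + alpha sinusoid`.

- **Temporal kernels** are Gaussians; component windows in the literature
  are approximate, so latencies default to P1 = 100 ms, N1 = 170 ms,
  P2p = 220 ms, P3 = 350 ms with SDs 20–50 ms, inside the conventional
  ranges.
- **Topographies** `w_c` are Gaussian falloffs of great-circle distance
  from a peak electrode on the unit sphere (σ = 0.5–0.8 rad). The analysis
  clusters are given as electrode *sets*, not weight maps, so the falloff
  form is a modelling choice. The P2p is split into a left source (peak
  PO7) and a right source (peak PO8): the adaptation deficit (−1 µV,
  Adaptation only) lives on the left source, physical-numerosity scaling
  (LowNum < HighNum) on the right source; the N1 is bilateral (PO7+PO8)
  and scales with physical numerosity in both hemispheres; the P1 (peak
  POz) is elevated equally in Adaptation and Neutral relative to Baseline,
  emulating a brightness/exposure artifact rather than a numerosity
  effect; the P3 (peak Pz) is condition-invariant.
- **Noise**: 1/f background (spectral shaping of white noise, exponent 1,
  RMS 3 µV per channel — a plausible single-trial posterior EEG noise
  floor after 1–40 Hz band-passing), a 10 Hz alpha sinusoid of 1 µV with
  random phase per trial and channel, and Gaussian per-trial amplitude
  jitter (SD 0.5 µV) on every component. Channels are spatially
  independent, which is unrealistic (real EEG noise is spatially
  correlated) but immaterial for the cluster-level statistics exercised
  here.
- `n_trials_per_condition` defaults to 24, the scaled-down trial regime
  used throughout the validation suite; the recorded experiment being
  emulated collects ten times more central-numerosity trials, so detection
  power at the default is, if anything, understated.
- Determinism: every draw comes from
  `default_rng([seed, crc32(condition), participant])`, so outputs are
  bit-identical for a fixed spec.

What the generator does **not** emulate: ocular/muscle artifacts (the
component-cleaning stage is a structural no-op hook), spatially correlated
noise, between-participant latency/topography variability, and
non-stationary alpha. Passing tests therefore demonstrate the correctness
and calibration of the *analysis*, not robustness to real-world artifact
regimes.

## Preprocessing chain

Downsample (polyphase, anti-aliased) to 250 Hz → windowed-sinc FIR
band-pass, −6 dB at 0.5 and 40.5 Hz (1 Hz transition, Hamming, odd order,
single pass with group-delay compensation so the −6 dB convention is
preserved; a filtfilt double pass would square the response) → bad-channel
spherical-spline interpolation (Perrin-style: Legendre series to order 50,
stiffness m = 4, ridge 1e-5, constant term so weights sum to 1) → average
reference → epochs −500..1000 ms, trimmed to −200..600 ms, per-trial
baseline (−200..0 ms) subtraction → peak-to-peak rejection.

Numerical conventions worth stating:

- Epoch windows are half-open `[start, end)`: −200..600 ms at 250 Hz is
  exactly 200 samples and includes the onset sample.
- Manual artifact screening is replaced by a configurable peak-to-peak
  criterion (default 150 µV), logged as such: a visual-inspection step is
  not reproducible in code.
- Filtering precedes epoching (continuous-data filtering is the default
  path); both orders are possible through the module functions.

## Statistics

**Point-wise bootstrap.** The resampling unit is the participant (the
contrast is between paired condition ERPs). Resample counts are drawn
multinomially — exactly equivalent to resampling participant indices with
replacement — and shared across time points of one contrast, which keeps
memory at `n_boot × n_times`. Two-sided p = `min(1, 2·min(tails))` with
the `(count+1)/(n_boot+1)` correction so p is never 0. Percentile-type
bootstrap tests of this form are mildly anticonservative at n = 25 (their
per-time-point type-I error sits above the nominal 5%, a first-order
accuracy property of the percentile method, not an implementation
artifact); the FDR + persistence stack below is what controls the
experiment-level error, and the calibration tests measure both levels.

**Correction.** BH-FDR is applied across the post-stimulus time points of
one contrast within one cluster (not pooled across contrasts — recorded in
the output metadata), followed by the persistence filter: only runs of
≥ 4 consecutive significant samples (16 ms at 250 Hz) survive. Order:
FDR first, persistence second. α defaults to 0.05.

**Windows.** The P2p window defaults to 200–250 ms (window bounds are a
config parameter; mentions of the component's range vary between ~200–220
and ~200–250 ms). Window amplitude is the mean of samples with
`start ≤ t ≤ end`. The window-difference bootstrap reports a central 95%
percentile interval and whether 0 falls outside it.

**ANOVAs.** Repeated-measures sums of squares are computed from the
participant × condition (× numerosity) cell-mean tables. η² is reported
as SS_effect/SS_total, with partial η² also available. Post-hocs are
Tukey–Kramer on the RM error term via the studentized-range distribution.
Pruning discards estimates outside `[Q1/2, 2·Q3]` per
participant × condition cell (quartiles by linear interpolation); "below
twice the lower quartile" is read as the reciprocal bound, since a literal
`x < 2·Q1` would discard most valid responses. Cells with fewer than 4
values are averaged unpruned.

**Power analysis.** λ = f²·n·m/(1−ρ), df₁ = (m−1)ε, df₂ = (n−1)(m−1)ε,
power = P(F' > F_crit) under the noncentral F; the required n is the
smallest integer reaching the target. This is the convention of the
standard a-priori power software for within-factor RM-ANOVA.

## Validation problem sizes

The statistical validation suite uses: 600 replicate experiments at
n_boot = 2000 for null calibration (the library default stays 20,000;
2000 keeps the bootstrap's p-resolution at 5·10⁻⁴, ample for α = 0.05,
and 600 replicates keep the Monte-Carlo error of the rejection-rate
estimate well inside the tolerance band);
100 simulated experiments for effect detection; 100 seeds for behavioral
parameter recovery; exhaustive enumeration (5⁵ resamples) for oracle
equivalence at n = 5. Independent cross-checks: statsmodels `AnovaRM` for
the repeated-measures F, MNE's spherical-spline interpolation for the
Perrin solve, hand-computed BH step-up, and sort-based quantile/percentile
oracles.

## Known limitations

- The bootstrap's per-point anticonservatism at small n (see above) is
  inherent to the percentile method; users needing exact per-point level
  should raise n or pair the pipeline with a permutation scheme.
- Tukey–Kramer reduces to plain Tukey HSD here because the design is
  balanced after cell-averaging.
- The spherical-spline solve matches other implementations to the level of
  their convention differences (head-radius scaling, series truncation).
- No source localization, no cluster-mass permutation statistics, no
  Bayes factors: all are out of scope.
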