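# Methods

## The model

`spikevar` simulates the spiking of a single cortical-style neuron over
repeated trials of a reaching task and quantifies its trial-to-trial
variability.

**Rate profiles.** Each trial follows a deterministic instantaneous firing
rate λ(t) (spikes/s) over a trial of duration T ms. Two shapes are provided:
a constant rate, and a *task-epoch* profile that stays at a baseline rate
until target onset and then ramps linearly to a peak rate over a rise
interval — the stylized stimulus-locked rise of motor-preparatory activity.
The ramp is linear because nothing in the modelled phenomenology constrains
its shape; its duration is configurable (default 100 ms).

**Pure vs noisy Poisson.** A *pure* trial is an inhomogeneous Poisson
process with intensity λ(t). A *noisy* trial first draws a single Gaussian
offset η_i ~ N(0, σ²) (spikes/s) and then spikes as a Poisson process with
intensity max(0, λ(t) + η_i) — a doubly stochastic (Cox) process. The
offset is additive and constant within a trial. Additive noise was chosen
over multiplicative gain deliberately: with an additive offset the
count Fano factor in a window of w seconds is

    F = 1 + σ² w / λ,

which *decreases* as λ grows — the inverse rate–variability relation the
package reproduces. A multiplicative gain (Var ∝ λ²) would predict the
opposite trend; it is left as an extension point rather than a default.
Rates are clipped at zero (an intensity cannot be negative); the clipping
bias this introduces is quantified below.

**Spike density function (SDF).** Spike trains are aligned to the task
event (target onset for task-epoch sets), each spike is replaced by a
unit-area Gaussian kernel (SD σ_k = 30 ms), and the kernels are summed,
giving a per-trial rate estimate in spikes/s on a uniform grid.

**Normalized variance (NV).** Trial-to-trial variability is the regularized
variance-to-mean ratio of the SDF across trials,

    NV(t) = (k·ε + Var[SDF(t)]) / (k·ε′ + Mean[SDF(t)]),    k = 0.1, ε = ε′ = 0.01,

with the small constants guarding the ratio when activity vanishes (for
all-empty trials NV = ε/ε′ = 1).

## Calibration: why "Poisson NV = 1" needs a correction

For a homogeneous Poisson process, counts in any window have variance equal
to their mean, so the count Fano factor is 1. The variance-to-mean ratio of
a *kernel-smoothed* rate estimate is not: smoothing with a unit-area kernel
K scales the Poisson point variance by ∫K², so

    E[Var SDF] / E[Mean SDF] = 1000·∫K²  =  1000 / (2 σ_k √π)  ≈ 9.40

for σ_k = 30 ms (the factor 1000 converts the ms time base to spikes/s).
`spikevar` therefore ships three explicit NV modes:

* `raw_eq1` — the ratio exactly as defined above, no correction; a pure
  Poisson process sits at ≈ 9.4, not 1.
* `calibrated` (default) — the variance is divided by the kernel constant
  `kernel_correction = 1000·dt·Σk²/(dt·Σk)²` before the ratio, so a pure
  Poisson process has expectation 1 at every t. This mode is used for all
  unity/excess statements.
* `count_fano` — an SDF-free oracle: variance/mean of sliding-window spike
  counts with the same regularizers. A rectangular window of width
  w = 1000/`kernel_correction` = 2σ_k√π ≈ 106 ms has the same Fano scale as
  the kernel, and in tests the two routes agree within a few percent.

Under additive rate noise the calibrated NV has expectation
1 + σ²/(c·λ) with c = `kernel_correction`, matching the count-Fano closed
form at the matched window.

## Parameters and defaults

| parameter | default | units | meaning |
|---|---|---|---|
| `duration` | 1000 | ms | trial length |
| `n_trials` | 100 | — | repetitions per simulated neuron |
| `baseline_rate` | 20 (constant) / 5 (ramp) | spikes/s | pre-onset rate |
| `peak_rate` | 45 | spikes/s | post-rise rate of the ramp profile |
| `target_onset`, `rise_time` | 400, 100 | ms | ramp timing |
| noise `sigma` | 10 (constant fixtures) / 5 (ramp fixtures) | spikes/s | SD of the per-trial rate offset |
| kernel `sigma` | 30 | ms | Gaussian SDF kernel SD |
| kernel `dt` | 1 | ms | evaluation grid step |
| kernel `truncation` | 5 | σ | kernel support half-width |
| `k`, `eps`, `eps_prime` | 0.1, 0.01, 0.01 | — | NV regularizers |

The noisy-fixture σ = 10 spikes/s at λ = 20 spikes/s makes the expected
full-window Fano factor 1 + σ²w/λ = 6, far enough from 1 that the
"noisy NV > 1" behaviour is unambiguous at 100 trials. The ramp fixture
uses σ = 5 spikes/s so the level-binned NV spans a clear inverse relation
(≈1.33 at baseline down to ≈1.07 at peak).

## Numerical choices

* **Generation** is Lewis–Shedler thinning against the profile's rate
  ceiling — exact for bounded rates, and verified by the time-rescaling
  theorem (rescaled inter-spike intervals are Exp(1) by KS test).
* **RNG contract**: trial i of root seed s uses the substream
  `SeedSequence(s, spawn_key=(i,))`, so any trial is reproducible
  independently of how many trials are requested.
* **Kernel truncation** at ±5σ, renormalized to exactly unit area.
* **Edges**: the SDF is computed on a grid padded by 5σ on each side of the
  requested window and cropped, so spikes just outside the window
  contribute their kernel mass inside it. At the boundary of the *data*
  support (where no spikes exist beyond the edge) the mean SDF is biased
  low, but the variance is biased by nearly the same factor, so NV is
  almost unaffected; mass is conserved to <0.5% whenever spikes sit ≥5σ
  from the window edges.
* **Regularizer placement**: the calibration divides Var before k·ε is
  added, so the regularizers act exactly as written in the NV definition.
* **Rate levels**: time bins are assigned by mean rate as a fraction of its
  maximum into [0.8, 1], [0.5, 0.8) and [0, 0.5); empty levels are reported
  with n = 0 rather than dropped.
* **Ties/degenerate inputs**: simultaneous spikes are allowed (continuous
  times make ties measure-zero); across-trial variance requires ≥2 trials
  and is computed with ddof = 1.

## Estimating expectations of stochastic statistics

Time-mean NV at 100 trials fluctuates with SD ≈ 0.04 across realizations;
the level-binned NV means of a single 500-trial ramp run fluctuate at the
same scale as the expected mid-vs-top gap (≈ 0.03). Where a claim concerns
the *expectation* of such a statistic (Poisson unity, the strict level
ordering), the package's checks therefore average the statistic over a
couple dozen re-seeded replicates at the stated trial counts; problem
sizes used are 50 × 100 trials (unity), 100 × 100 trials (noisy excess),
24 × 500 trials (level ordering) and 3 × 1000 trials (full-window Fano).
Single-run values are asserted only against correspondingly wide sampling
bands (±0.15 for 100-trial unity).

## Clipping bias

With λ = 20 and σ = 10 spikes/s, P(λ + η < 0) ≈ 0.023 and clipping at zero
truncates the offset distribution: the realized mean rate rises to ≈ 20.09
and the offset variance falls to ≈ 96, so the exact full-window Fano
expectation is ≈ 5.8 rather than the untruncated 6. Tests compare against
6 with Monte-Carlo bounds that cover this bias; at σ/λ ratios below ~0.4
the effect is negligible.

## What the generator does and does not emulate

The synthetic data reproduce: trial-based Poisson firing, a stimulus-locked
rate rise, per-trial rate offsets, and the resulting NV behaviour (unity,
excess, inverse rate relation, post-onset NV decline). They do **not**
contain refractoriness or any spike-history dependence, direction tuning,
across-neuron correlations, non-stationary noise within a trial, or
recording artifacts. Passing tests therefore validate the statistical
machinery and the model's internal consistency — not that real cortical
data follow this generative model.

## Known limitations

* NV modes share one kernel correction derived for homogeneous Poisson
  statistics; for strongly non-stationary rates the calibrated NV is exact
  only in the limit of rates varying slowly relative to the kernel width.
* The noise model is a per-trial constant offset; slow within-trial rate
  drift or multiplicative gain fluctuations are out of scope (the latter is
  an explicit extension point in `rate_model`).
* Alignment assumes the event time is known per trial; it is not estimated
  from the data.
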