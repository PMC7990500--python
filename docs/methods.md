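# Methods

This document describes the generative models, estimators, and numerical
choices in `optodetect`, and why they are the way they are.

## 1. Task model

### Trial structure

A head-fixed observer holds a lever and must release it within a reaction
window after a contrast increment appears on a drifting grating.  An LED
delivers optogenetic silencing light as a periodic pulse train: 200 ms on,
1000 ms off (period 1200 ms).  The phase of the train is drawn uniformly per
trial, so the observer cannot use the light itself as a temporal cue.

Stimulus onsets come in two flavors:

- **ON trials** — the stimulus is locked 55 ms *before* a pulse onset, so the
  visually evoked response in cortex arrives while the light is on.
- **OFF trials** — the stimulus sits 820 ms after the preceding pulse's
  offset, in the middle of the dark interval.

The planned onset is drawn from a geometric (discretized-exponential)
distribution with mean 1400 ms, shifted so no stimulus appears before 400 ms
and capped at 4100 ms.  The approximately flat hazard of an exponential keeps
the observer's temporal expectation constant over the trial.  The actual onset
is the *latest* grid slot (ON or OFF, as above) at or before the planned
onset; if no slot exists the trial is redrawn.  Because the earliest OFF slot
is structurally later than the earliest ON slot (phase + 1020 ms vs
phase − 55 ms), OFF trials are on average longer — an asymmetry the analysis
code must not mistake for an effect of the light.

Worked example (pulse train phased at 300 ms, planned onset 2000 ms): pulses
occupy 300–500, 1500–1700, 2700–2900 ms; the ON slot grid is
{245, 1445, 2645, …}, so the ON onset is 1445 ms; the OFF grid is
{1320, 2520, …}, so the OFF onset is 1320 ms.

### Observer model

The observer is a high-threshold detector with a Weibull psychometric
function for hits,

    p(c) = (1 − λ) · (1 − exp(−(c/α)^β)),

and a constant false-alarm hazard (default 0.1 events/s) throughout the
pre-stimulus period.  A false alarm within 100 ms after stimulus onset still
counts as a false alarm (it cannot be stimulus-driven); a release between
100 ms and the 550 ms reaction deadline is a hit.  Silencing raises the
threshold α on ON trials via a hinge dose-response (section 3); β = 3 and
λ = 0.05 are typical psychophysical values for this task class.

## 2. Psychometric fitting

`fit_weibull` maximizes the joint binomial likelihood of ON and OFF hit
counts with a shared slope β, separate thresholds α_on, α_off, and separate
lapse rates.  Optimization runs in log-parameter space (L-BFGS-B, three
starting points) so positivity is automatic and the Hessian is better
conditioned.  The headline statistic is the threshold increase
100·(α_on − α_off)/α_off.

Confidence intervals for α use the **profile likelihood**: the threshold is
stepped away from its MLE, all other parameters re-optimized, and the bound
placed where the deviance rises by χ²₁(0.95)/2 ≈ 1.92.  Inner optimizations
are warm-started from the previous step and memoized so the root finder sees
a deterministic function.  Profile intervals respect the likelihood's
asymmetry near the edges of the contrast range, where Wald intervals are
unreliable.  Measured coverage on simulated sessions (200 trials) is ≈ 0.93
for a nominal 0.95, the usual small-sample behavior of profile intervals.

`fit_naka_rushton` fits d′(c) = d′_max · c^n / (c^n + c50^n) to
sensitivity-vs-contrast points for comparisons in d′ space.

## 3. Dose-response (hinge) model

Threshold increase vs LED intensity is modeled as a hinge,

    f(I) = max(0, s·(I − i0)),

zero below the silencing threshold i0 and linear above it.  The quantity of
interest is the intensity producing a 100 % threshold increase,
X100 = i0 + 100/s, which localizes where on the cortical map the light is
effective.  Fitting minimizes SSE over a grid of i0 (with the slope
closed-form or fixed), taking the smallest i0 on a flat SSE plateau.  When
several spots are fit, `pool_slope` fixes a common slope (median of free
slopes from well-constrained spots) and refits per-spot i0 — thresholds vary
across the map much more than slopes do.

### Bootstrap interval for X100

Per-spot uncertainty comes from a session-level bootstrap (resampling
(intensity, threshold-increase) points).  Two facts shape the interval
construction:

1. **The kink is non-regular.**  If tested intensities straddle i0, the
   estimator of i0 has a non-normal, boundary-influenced distribution, and
   naive percentile bootstraps undercover (we measured ≈ 0.80–0.88 at
   n = 15 sessions).  The recommended design therefore places all tested
   intensities on the rising limb when the goal is estimating X100; there
   X100 is a smooth function of regression coefficients.
2. **n is small.**  Even on the rising limb, a percentile interval at
   n ≈ 15 is too short.  We use the *expanded basic* (reverse-percentile)
   interval: percentile tails widened from 2.5 % to
   Φ(−t_{n−1,0.975}·√(n/(n−1))) ≈ 1.3 %, then reflected about the point
   estimate.  Measured coverage is 0.96–0.97 at nominal 0.95.

If the fitted X100 exceeds the largest tested intensity, the estimate is
reported as a **lower bound**: the interval's upper end is +∞ and
`x100_is_lower_bound` is set.  Control locations (no retinotopic overlap
with the stimulus) land in this regime by construction.

## 4. False-alarm hazard and signal detection

### Two hazard estimators

- `hazard_estimated`: (fraction of trials ending in a false alarm) ÷ (mean
  trial length in seconds).  This is exactly unbiased when the recorded
  trial length equals the at-risk time — i.e., when every trial ends at the
  false alarm or at the censoring point (stimulus onset + 100 ms).  Then
  the estimator is λ·E[min(T_fa, T_c)] / E[min(T_fa, T_c)] = λ.
- `hazard_mle`: false alarms ÷ total at-risk seconds, the constant-hazard
  maximum-likelihood estimator.  It is unbiased regardless of how trial
  length is bookkept.

On full observer sessions the recorded trial length includes time *after*
the at-risk period ends (the reaction window, and the hold through a hit),
so `hazard_estimated` reads ≈ 20 % low there.  Both estimators are exposed;
`hazard_mle` is the recommended one for session data, and the test suite
pins down the bias of the other as a documented property.

`hazard_binned` gives a life-table hazard over time (events in a bin ÷
trials at risk at the bin start ÷ bin width), either aligned to trial start
or folded on the pulse cycle (exposure-weighted).  For the simulated
constant-hazard observer the folded curve is flat and ON/OFF event counts
split as their exposure shares (exact binomial test).

### Sensitivity and criterion

d′ = z(H) − z(FA) per contrast, with the false-alarm rate taken as
hazard × 0.55 s (the probability of a spontaneous release inside the
reaction window, small-rate approximation) and rates clamped away from 0/1
by the 1/(2N) correction.  The criterion is reported as
c = (z(H) + z(FA))/2 (so c = 0 when FA = 1 − H, i.e. an unbiased observer);
a `conventional` flag flips the sign for the more common
−(z(H)+z(FA))/2 convention.  The relative criterion c′ = c/d′ is undefined
(NaN) at d′ = 0.

## 5. Electrophysiology

Spike rates are measured in three windows: baseline r_base = [−50, −10) ms
before LED onset; the inhibition minimum r_min = [25, 50) ms after LED
onset; and the visual response r_vis = [65, 115) ms after stimulus onset
(shifted +25 ms for higher visual areas, whose latencies are longer).  Units
enter analysis if visually responsive (r_vis ≥ 1.1 · r_base at zero
intensity), well-isolated (SNR ≥ 2.5), and broad-spiking
(trough-to-peak > 0.45 ms) — narrow units are putative inhibitory cells
whose rates *rise* under this silencing strategy.

The normalized response at intensity I is
(r_vis(I) − r_min(I)) / (r_vis(0) − r_min(0)); subtracting r_min removes
the floor the silencing imposes, and the ratio is 1 at zero intensity and 0
at complete silencing by construction.  Suppression is fit as a unit-height
Gaussian, g(x) = exp(−x²/2σ²), in either the intensity domain (yielding
I50 = σ·√(2 ln 2), the intensity at half suppression) or the distance domain
(yielding the spatial FWHM = 2.355·σ of the silencing spot).  Bootstrap CIs
resample units (groups), not points, so within-unit correlation does not
shrink the interval.

Visual latency is the half-max time t50 of a logistic fit to a rising PSTH.
The simulated units place it at 65 ms post-stimulus; the LED leading the
stimulus by 10 ms means the inhibition minimum (25–50 ms post-LED) closes
before visually evoked spikes arrive.

## 6. Widefield imaging

Hemodynamic/global fluctuations are removed by projecting out the first
principal component of the frames × pixels matrix (per-pixel mean restored
afterwards).  Response maps average, over stimuli, the frame-difference
signal (Fdiff − Fdiff0)/F0 with 3-frame baselines — frame differencing
suppresses slow drift, and the Fdiff0 subtraction removes any residual
baseline trend.  ROI responses are (mean of 2 post-stimulus frames − mean of
2 pre-stimulus frames)/pre, and two stimulus conditions are compared with a
two-sided Mann-Whitney test.  Pixels with near-zero baseline are masked NaN
rather than divided.

## 7. Default generative parameters

| Parameter | Default | Rationale |
| --- | --- | --- |
| pulse on/off | 200/1000 ms | duty cycle low enough to probe ON vs OFF states within a trial |
| stim→pulse lead | 55 ms | evoked response arrives during the pulse |
| OFF gap | 820 ms | centers OFF stimuli in the dark interval |
| onset mean / min / cap | 1400 / 400 / 4100 ms | near-flat temporal hazard |
| reaction window | 550 ms | generous for mouse lever release |
| FA cutoff | 100 ms | releases sooner cannot be stimulus-driven |
| α₀, β, λ | 12 %, 3, 0.05 | typical contrast-increment psychophysics |
| FA hazard | 0.1 /s | ≈ 1 false alarm per 10 s of holding |
| hinge slope, i0 | 295.9 %·mm²/mW, 0.112 mW/mm² | X100 ≈ 0.45 mW/mm² at the spot center |
| I50 | 0.2 mW/mm² | half-silencing intensity of simulated units |
| spatial FWHM | 0.73 mm | light-spot silencing width |
| visual latency | 65 ms | typical V1 single-unit latency |

## 8. Limitations

- The observer model has no motor-latency distribution; releases are
  instantaneous at detection time.
- The hinge bootstrap interval assumes all tested intensities lie on the
  rising limb; with points below the kink, intervals on X100 revert to the
  non-regular regime and coverage degrades (documented above).
- The imaging generator uses a separable (spatial × temporal) transient and
  Gaussian noise; it does not model photon shot noise or vascular artifacts.
- `hazard_estimated` is retained for comparability but is biased on data
  where trial length outlives the at-risk window; prefer `hazard_mle`.
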