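# optodetect

Simulation and analysis toolkit for optogenetic silencing experiments in a
visual change-detection task.

## The problem

A head-fixed mouse holds a lever and releases it when a contrast increment
appears on a drifting grating.  An LED over visual cortex delivers
inhibitory-opsin silencing light as a periodic pulse train (200 ms on / 1000 ms
off), and each trial's stimulus is timed either to coincide with a light pulse
(**ON** trials) or to fall in the dark gap (**OFF** trials).  Comparing
psychometric thresholds between ON and OFF trials, across LED intensities and
across cortical locations, measures *where* and *how strongly* that patch of
cortex contributes to detection.

`optodetect` provides:

- **`optodetect.simulate`** — generative models of the task: pulse-train
  timing with the ON/OFF onset grids, a Weibull observer with a constant
  false-alarm hazard, Poisson spiking units under Gaussian
  intensity-and-distance suppression, and widefield movies with global
  fluctuations and calcium-like transients.
- **`optodetect.psychometrics`** — joint ON/OFF Weibull maximum-likelihood
  fits (shared slope), profile-likelihood threshold CIs, threshold-increase
  statistics, Naka-Rushton d′-vs-contrast fits, session QC.
- **`optodetect.sdt`** — false-alarm hazard estimators (scalar, binned
  life-table, pulse-folded), d′ and criterion per contrast.
- **`optodetect.dose_response`** — hinge (threshold-linear) fits of threshold
  increase vs LED intensity, the 100%-increase crossing point X100 with
  small-sample bootstrap CIs and lower-bound semantics, slope pooling across
  spots, silencing-spot geometry from widefield maps.
- **`optodetect.ephys`** — windowed spike-rate measures around LED/stimulus
  onsets, unit selection, normalized suppression curves, Gaussian suppression
  fits (I50, spatial FWHM), visual latency.
- **`optodetect.imaging`** — global-component removal (PCA), stimulus-locked
  frame-difference response maps, ROI responses with condition comparisons.

Model details, estimator derivations and default-parameter rationale are in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate one cortical spot tested at four LED intensities (8 sessions of 300
trials), fit the psychometric functions, and locate the intensity that raises
the detection threshold by 100%:

```python
import numpy as np
from optodetect.simulate import ObserverParams, SessionConfig, simulate_spot_sessions
from optodetect import psychometrics as psy, dose_response as dr, sdt

rng = np.random.default_rng(7)
params = ObserverParams()          # OFF threshold 12% contrast, FA hazard 0.1/s
cfg = SessionConfig(n_trials=300)
sessions = simulate_spot_sessions([0.2, 0.35, 0.55, 0.8], 8, params, rng,
                                  session_config=cfg)

fit0 = psy.fit_weibull(sessions[0])
lo, hi = psy.profile_ci_alpha(fit0, "OFF")
print(f"alpha_off = {fit0.alpha_off:.2f}% (95% CI {lo:.2f}-{hi:.2f}), "
      f"threshold increase = {psy.threshold_increase(fit0):.1f}%")
print(f"OFF false-alarm hazard (MLE): "
      f"{sdt.hazard_mle(sessions[0].to_frame(), 'OFF'):.3f} /s")

points = [(s.intensities[0], psy.threshold_increase(psy.fit_weibull(s)))
          for s in sessions]
hinge = dr.fit_hinge(points, slope=None, n_boot=1000, rng=rng)
print(f"X100 = {hinge.x100:.3f} mW/mm^2 "
      f"(95% CI {hinge.ci95[0]:.3f}-{hinge.ci95[1]:.3f})")
```

Output:

```
alpha_off = 10.57% (95% CI 8.97-12.97), threshold increase = 37.3%
OFF false-alarm hazard (MLE): 0.095 /s
X100 = 0.494 mW/mm^2 (95% CI 0.408-0.568)
```

The first session (0.2 mW/mm²) already shows a threshold increase (fitted ON
threshold 14.51% vs OFF 10.57%); the hinge fit across intensities puts the
100%-increase crossing at 0.494 mW/mm² — the generative truth is 0.45, inside
the bootstrap CI.  At a control location with no effect the fit instead
reports X100 as a lower bound (`x100_is_lower_bound=True`, upper CI = ∞).

The same pipeline is scriptable from the CLI:

```sh
optodetect simulate behavior --seed 1 --out sessions/
optodetect fit-psycho --sessions 'sessions/*.csv' --out fits.json
optodetect dose-response --fits fits.json --out hinge.json
```

(plus `optodetect sdt`, `optodetect ephys`, `optodetect imaging` for the
other data streams).

## Reproduction

The full check — simulation-based recovery of every headline quantity — is
one command:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

(≈3–5 minutes on one CPU).  With seed 1 it reports, among others: median
fitted OFF threshold 12.15% (truth 12, profile-CI coverage 0.94 over 200
sessions), median X100 0.448 mW/mm² (truth 0.45, bootstrap-CI coverage 0.90
over 60 replicates), false-alarm hazard estimates 0.100–0.105 /s on a 0.1 /s
constant-hazard process, median I50 0.204 mW/mm² (truth 0.2), median spatial
FWHM 0.723 mm (truth 0.73), visual latency 64.1 ms (truth 65), and exact
imaging oracles (step-map error 0, PCA residual at the noise floor).

The test suite (timing grids, estimator identities, recovery and coverage
studies, CLI round-trips) runs with:

```sh
python -m pytest -q tests/
```
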