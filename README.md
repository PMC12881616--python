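# floquet-ews

Stability tracking for periodically forced systems — seasonal time series and
spatio-temporal fields — without deseasoning or detrending.

## The problem

Early-warning analysis of tipping points ("critical slowing down", CSD)
conventionally assumes stationary fluctuations around a fixed point, so
seasonal data must first be deseasoned and detrended. That pre-processing is
a known source of bias: different deseasoning choices change the resulting
autocorrelation and variance trends, and changes in measurement noise (e.g.
merged multi-sensor records) masquerade as stability change.

For a system with a known forcing period *T*, linear stability around the
periodic orbit is described by the monodromy matrix — the linear map
advancing perturbations by one full period — whose eigenvalues ρᵢ are the
**Floquet multipliers**: the orbit is stable while every |ρᵢ| < 1 and loses
stability as a multiplier approaches and crosses the unit circle.

This package estimates Floquet multipliers directly from data by
**period-lagged dynamic mode decomposition (DMD)**. Within each sliding
window, delay-embedded snapshot matrices are formed,

    X = [x_t, x_{t+1}, …],   Y = [x_{t+T}, x_{t+T+1}, …],

where each column stacks m delayed copies (delay τ) of the scalar series —
or of all grid cells for spatial input — and the propagator **A** = **Y X⁺**
is fitted via a rank-truncated SVD. Because Y is X lagged by exactly one
period, the eigenvalues of **A** approximate the Floquet multipliers: a
stable seasonal cycle pins one eigenvalue near 1+0j, while destabilisation of
the underlying process appears as a second eigenvalue rising towards 1 from
below. Tracking eigenvalues across windows, filtering out the persistent
seasonal one, and scanning the remaining maximum magnitude for a persistent
threshold crossing yields an early-warning signal that needs no
pre-processing and is robust to step changes in noise level.

The package also ships:

* five seeded synthetic tipping/noise models (seasonal pitchfork and logistic
  bifurcation models, a piecewise-noise stationary process, a seasonal
  reaction–diffusion vegetation model with stress feedback, and a seasonal
  Klausmeier vegetation–water pattern-formation model),
* conventional baseline indicators for comparison (rolling AC1, variance,
  restoring rate; spatial variance/skewness, per-cell temporal AC1, Moran's
  I; STL and climatology-based deseasoning),
* delay-embedding diagnostics (average mutual information, false nearest
  neighbours),
* consensus resampling of irregular measurement records onto even time grids,
* CSV/NetCDF/YAML I/O and a `floquet-ews` command line.

## Worked example

Simulate the seasonally forced pitchfork model (control parameter ramped
through the bifurcation from year 10 on) and run the rolling Floquet
analysis:

```python
from floquet_ews import FloquetDMD, PitchforkParams, simulate_pitchfork

run = simulate_pitchfork(PitchforkParams(seed=3))
print(run.transition_time)        # 23.48… (ground-truth transition, years)

res = FloquetDMD(
    run.output,
    m=7, tau=182, T_steps=365, window_len=1825, stride=228,
    rank=3, max_jump=0.5, seasonal_band=0.3, min_coverage=0.6,
).fit()
print(res.summary())
```

```
Floquet-multiplier stability analysis
=============================================
windows analysed      : 34  (skipped: 0)
window span (samples) : 3282
embedding (m, tau, T) : (7, 182, 365)
mean rank used        : 3.00
track labels          : {'seasonal': 1, 'noise': 11, 'csd_candidate': 1}
filtered max |rho|    : first 0.6965 -> last 0.9967
seasonal track |rho|  : 0.9585 .. 1.0248
threshold crossing    : t = 15.7411
```

The seasonal cycle is captured by a single track pinned near |ρ| = 1
(0.96–1.02); the filtered maximum over the remaining eigenvalues crosses the
stability threshold at year 15.7 — roughly eight years before the
ground-truth transition at year 23.5. `res.plot()` draws the tracks,
`res.candidate_magnitudes()` returns the rising mode, and for spatial input
`res.spatial_mode(w)` / `res.mode_change(early, late)` map which grid cells
drive the instability.

The same pipeline is scriptable from a shell:

```bash
floquet-ews simulate pitchfork --seed 3 --out run/
floquet-ews analyze-1d --input run/pitchfork.csv --config cfg.yaml --out out/
```

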