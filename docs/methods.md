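# Methods

## Stability of periodically forced systems

For a linear system with T-periodic coefficients, perturbations z around the
periodic orbit evolve over one full period by the monodromy matrix **A**;
its eigenvalues ρᵢ (Floquet multipliers) govern stability: |ρᵢ| < 1 for all i
means perturbations decay, any |ρᵢ| ≥ 1 means the orbit is unstable. For a
nonlinear system observed near a periodic attractor, the linear operator that
best maps the observed state to the state one period later is a data-driven
approximation of the monodromy matrix, in the same sense in which DMD
approximates the Koopman operator of the flow over the lag used. The central
estimator of this package is therefore:

1. form delay-embedded snapshot matrices X and Y over a window, with Y lagged
   by exactly the forcing period T (in samples);
2. optionally subtract per-row means of the combined X∪Y columns
   (mean-centering);
3. compute the reduced operator Ã = U_r* Y V_r Σ_r⁻¹ from the rank-r SVD
   X ≈ U_r Σ_r V_r*;
4. take the eigenvalues of Ã as Floquet-multiplier estimates and lift the
   eigenvectors to exact DMD modes Φ = Y V_r Σ_r⁻¹ W (columns normalised).

Delay embedding serves two purposes: it reconstructs unobserved state
dimensions (Takens), and — more important here — it gives the deterministic
seasonal component enough coordinates to occupy its own singular directions,
so that the least-squares fit does not shrink the seasonal eigenvalue toward
the noise multiplier. With a delay of half a period the embedded seasonal
cycle is nearly one-dimensional (alternating signs across embedding levels),
which concentrates it in a single coherent direction while stochastic
fluctuations decorrelate across levels.

A stable seasonal cycle (plus any window offset, when not mean-centering)
maps to itself under the period lag and contributes eigenvalue(s) ≈ 1+0j in
every window. Destabilisation of the noise-driven part appears as an
eigenvalue rising from |ρ| = e^(−λT) toward 1 as the effective restoring rate
λ → 0. Eigenvalues are chained across windows by nearest-neighbour matching
in the complex plane; a chain is labelled *seasonal* when it covers enough of
the record with |ρ| inside 1 ± δ throughout, *noise* when its mean magnitude
is below a floor, and the remaining chain with the largest terminal magnitude
is the *csd_candidate*. The per-window maximum over non-seasonal eigenvalues
("filtered maximum") is scanned for the earliest run of `persistence`
consecutive windows at or above the threshold (default 1.0); that window's
centre time is the detection time.

### Practical behaviour worth knowing

* The seasonal multiplier is *not* exactly 1 in finite noisy windows: the
  least-squares eigenvalue is shrunk by the ratio of noise to seasonal
  variance within the seasonal subspace, and during a forcing-parameter ramp
  the seasonal response amplitude/phase drifts, which can push it slightly
  above 1 (a genuinely "slightly unstable" periodic component). The
  classification band must accommodate this; δ = 0.05 (package default) suits
  quasi-stationary records, while the ramped bifurcation studies here use
  δ = 0.3.
* When the rising candidate approaches the seasonal eigenvalue the two
  collide in the complex plane and matching may swap their identities. Both
  chains then remain near 1, so the filtered maximum and the crossing time
  are robust, but single-chain coverage can drop; the pitchfork study
  therefore uses `min_coverage = 0.6` (package default 0.9). Greedy matching
  outperformed globally optimal assignment here, because the Hungarian
  solver forces crosswise matches at collisions.
* Per-window estimates on noise-dominated directions fluctuate with the
  number of effectively independent samples (window length over the noise
  correlation time). Windows of several years at daily sampling are used for
  annual-period systems.

## Embedding diagnostics

`average_mutual_information` uses a joint histogram with equal-width bins
(default 16) over the finite value range; lag 0 reduces to the entropy of the
binned marginal. `select_tau` returns the first strict local minimum of the
curve, falling back to the first lag below AMI(1)/e, then to 1. Note that for
noise-free deterministic signals the binned MI of a functional relationship
stays high at every lag and the estimated curve is jagged; the quarter-period
minimum of an oscillatory signal is recovered cleanly once measurement noise
makes the relationship statistical. `false_nearest_fraction` implements both
standard Kennel criteria: a neighbour is false when the extension distance
grows by more than `r_tol` (=10) relative to the m-dimensional neighbour
distance, or when the extended distance exceeds `a_tol` (=2) attractor sizes
— the second criterion is what keeps the false fraction high for stochastic
data. Final (m, τ) choices for Floquet runs are deliberately explicit
configuration, not auto-selected: delay-embedding criteria reconstruct the
dominant (seasonal) attractor and are blind to the period-lagged mode
separation the analysis needs.

## Synthetic models

All models integrate with Euler–Maruyama (drift · dt + σ√dt · N(0,1)) under a
counter-based Philox generator, so identical parameters + seed reproduce
outputs bit-for-bit. The 1D bifurcation models use years as the time unit
(annual angular frequency 2π, dt = 1/365, one sample per step → daily
sampling); the spatial and piecewise-noise models use days with a 365-day
year, integrating at sub-daily dt and saving the last substep of each day.
Spatial Laplacians are 5-point stencils with periodic boundaries by default
(no-flux selectable). Defaults were chosen once so that each system is
stable before its ramp, transitions in the final third of the run, and has a
seasonal response comparable in scale to its noise fluctuations.

* **Pitchfork**: dx/dt = p(t)x − x³ − λx + A cos(ωt) + σξ. Defaults: p ramps
  linearly from −3 (held for the first 10 of 30 years) to +3; λ = 0, A = 1,
  σ = 0.05. Pre-ramp the state sits at 0 with restoring rate 3/yr (seasonal
  response amplitude ≈ 0.14, noise SD ≈ 0.02); the bifurcation is crossed at
  year 20 and the state escapes to ±√p some years later (escape from an
  unstable origin at finite noise is slow). A sigmoidal (logistic) ramp is
  available.
* **Logistic**: dx/dt = r(t)x(1 − x/K) + A cos(ωt) + σξ, clipped to x ≥ 0;
  r ramps 3 → −1 over years 10–30, K = 1.
* **Piecewise-noise stationary process**: an AR recursion
  u_k = 0.8 u_{k−1} + ε at 24 substeps/day with additive annual sine
  (amplitude 2), where ε's SD is σ = 1 plus segment-specific extra noise
  (defaults 0 / 2.5 / 1.0 across three 5-year segments, emulating instrument
  changes); output is the daily mean.
* **Reaction–diffusion vegetation**: ∂V/∂t = r_v V[1 − V(h_E^p + E^p)/h_E^p]
  + D∇²V + ση with stress feedback E = E0(t)·h_v/(h_v + V); E0 carries an
  annual sine (amplitude 0.25) and ramps 0.8 → 3.2 over days 2400–7300
  (fold at E0 ≈ 2.05 under h_E = 1, h_v = 0.5, p = 6, r_v0 = 0.05/day).
  Growth-rate seasonality is mildly heterogeneous per cell (amplitude
  0.3·r_v0 ± 50%, phases ±0.5 rad) to avoid phase locking. dt = 0.1 day,
  daily snapshots, spin-up with E pinned at its initial base value. V is
  clipped to ≥ 0 (noise would otherwise drive unphysical negative runaway
  after collapse).
* **Klausmeier**: ∂N/∂t = WN² − mN + D_n∇²N + ση_N (N ≥ 0),
  ∂W/∂t = a(t) − W − WN² + e∇²W, rainfall a = a_base(t) + A sin(2πt/365)
  with a logistic decline; classic nondimensional rates (m = 0.45)
  interpreted per day, dt = 0.01 day. Noise enters the biomass equation
  only. The vegetated equilibrium exists for a ≥ 2m
  (N* = (a + √(a² − 4m²))/2m, W* = m/N*).

The ground-truth `transition_time` marks the first time the trailing 30-step
mean departs from the pre-ramp mean by more than 5 pre-ramp SDs for 30
consecutive saved steps (domain mean for fields). Near a bifurcation at
finite noise this marker can also fire on large excursions just before the
deterministic crossing; it is a marker for validation, not part of the
method.

What the generators deliberately do **not** emulate: irregular sampling
gaps with realistic spatial structure, multiplicative/state-dependent noise,
observation error distinct from process noise, non-sinusoidal seasonal
shapes, or trends unrelated to the ramped parameter. Passing the validation
studies therefore demonstrates correctness of the estimator and its claimed
qualitative advantages under these idealised conditions, not performance on
any particular observational record.

## Baseline indicators

Rolling indicators use trailing windows reported at the window end: lag-1
Pearson autocorrelation, sample variance (n−1), and a restoring-rate proxy
(OLS slope of x_{t+1} − x_t on x_t; ≈ λ·dt, negative when stable — a
deliberately simple regression stand-in, not a spectral estimator).
Deseasoning: STL (statsmodels, with a stiff seasonal smoother of 10 periods
so the removed cycle is climatological rather than noise-tracking) or
subtraction of the per-phase long-term mean followed by a centred rolling
mean (default width 5 periods). Spatial indicators per snapshot: variance,
bias-corrected skewness, and Moran's I with symmetric, row-unnormalised rook
weights on non-periodic boundaries; per-cell rolling AC1 is summarised by
the domain mean. Pixel-wise deseasoning is supported for all of them.

## Analysis configurations of the validation studies

Chosen by scanning (m, τ, window, rank) for clean separation of the seasonal
mode from the candidate mode — the intended tuning procedure for any new
system — and then frozen:

| system | m | τ | T | window | stride | rank | centred | δ | coverage |
|---|---|---|---|---|---|---|---|---|---|
| pitchfork (daily, annual) | 7 | 182 | 365 | 1825 | 228 | 3 | no | 0.3 | 0.6 |
| vegetation field | 2 | 91 | 365 | 730 | 91 | 4 | yes | 0.3 | 0.9 |
| stationary process | 7 | 182 | 365 | 1095 | 137 | 3 | no | 0.3 | 0.9 |

Other defaults: threshold 1.0, persistence 3 windows, greedy matching with
max_jump 0.5 (0.2 package default), automatic rank = smallest r with ≥ 99.5%
squared singular-value energy, pseudo-inverse tolerance 1e−10·σ_max, windows
with > 20% missing columns skipped. For spatial windows at small fixed rank
the SVD is computed by randomised projection (scikit-learn) for speed; the
full SVD is used otherwise.

## Numerical and design notes

* Exact DMD modes (Y V Σ⁻¹ w) are returned rather than projected modes
  (U w): for spatial-mode maps the exact convention keeps the mode in the
  data space of Y.
* Eigenvalues are sorted by descending magnitude, ties by descending real
  part. Real-valued input gives a real reduced operator, so conjugate pairs
  are intact by construction; a guard raises the rank if complex input ever
  orphans a pair member.
* Spatial stacking is level-major: rows [0, d) of a window matrix are the
  un-lagged snapshot of all d cells, so "first spatial component" extraction
  is simply the first d rows of a mode column, taken as magnitudes and
  re-normalised.
* Consensus resampling takes k = the minimum record count over *non-empty*
  bins (a literal minimum over all bins would be 0 whenever any bin is
  empty), samples without replacement, and is made order-invariant by
  sorting records before sampling.
* The seasonal imprint on raw rolling AC1 of a cosine-forced system appears
  at the *first harmonic* (2/yr) of the forcing: the indicator responds to
  the squared seasonal slope/variance within the window, which is invariant
  under half-period shifts of a pure cosine. Asymmetric seasonal shapes
  would move power to the annual line.

## Known limitations

* No uncertainty quantification on eigenvalue tracks: phase/bootstrap
  surrogates are not well defined in the period-lagged embedded setting and
  are intentionally out of scope.
* Track identity through eigenvalue collisions is heuristic; labels, not
  identities, are the robust output (see above).
* Near a fold at finite noise, detection necessarily concentrates in the
  final approach: the candidate multiplier e^(−λT) is numerically
  indistinguishable from the noise floor while λT ≫ 1. Lead times depend on
  ramp speed and T.
* The filtered maximum can exceed 1 transiently *after* a transition (the
  escape dynamics are genuinely unstable); detection times are meaningful
  only up to the first transition.
* Very high noise (fluctuations larger than the seasonal response) degrades
  the seasonal/candidate separation; the method then fails towards "no
  detection" rather than false alarms.
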