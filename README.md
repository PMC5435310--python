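# ctscr — continuous-time spatial capture-recapture

`ctscr` estimates the spatial distribution and abundance of individually
identifiable animals from surveys with **continuous-time recorders**
(motion-activated cameras, microphones).  Unlike discrete-occasion SCR
models, it uses the exact detection *times*, so no information is thrown
away by binning the survey into occasions and no "midnight problem"
arises from the choice of cut-off times.  It is aimed at quantitative
ecologists analyzing camera-trap surveys of naturally marked animals
(tigers, leopards, individually recognizable birdsong, ...).

## Model

A population of `N` animals lives in a planar region `B`.  Each animal has
a latent **activity center** `s_i`, fixed during the survey (spatial
closure).  Two point processes are coupled hierarchically:

* **Spatial**: activity centers follow a Poisson process with log-linear
  intensity

  ```
  log λ(s) = β′v(s),        N(B) ~ Poisson(Λ(B)),   Λ(B) = ∫_B λ(s) ds
  ```

  where `v(s)` are density covariates (intercept-only for constant density).

* **Temporal**: detections of individual `i` at trap `k` (location `x_k`,
  operating over `(0, T_k]`) form an inhomogeneous Poisson process with
  intensity

  ```
  φ(t, s_i, x_k) = ψ_k · γ(t) · exp(−‖s_i − x_k‖² / 2σ²)
  ```

  with baseline encounter rate `log ψ_k = α′w_k`, temporal modulation
  `log γ(t) = ξ′z(t)` (e.g. a binary daytime indicator), and Gaussian
  distance decay with movement scale `σ`.

Only `n ≤ N` animals are ever detected.  The observed-data likelihood
augments them with the latent count `n0 = N − n` through
`π0 = Λ(B)⁻¹ ∫ λ(s) Π_k exp[−Φ(T_k, s, x_k)] ds`, the probability that an
animal living in `B` escapes detection entirely (`Φ = ∫φ dt` is the
expected number of detections for one animal–trap pair).  Fitting is
Bayesian: adaptive random-walk Metropolis-within-Gibbs over `(β, α, ξ,
log σ)` and the centers, with an exact Gibbs draw `n0 ~ Poisson(π0 Λ(B))`.
Posterior prediction places the `n0` never-detected centers by sampling
from `λ(s)·Π_k e^{−Φ}`, yielding gridded abundance maps `N(B_m)` and
density estimates.  A **restricted** (time-homogeneous) variant uses only
the count matrix; its temporal parameters are not identifiable and the
encounter intercept absorbs the time-averaged rate.

## Worked example

Simulate one survey under the built-in study design (spatially varying
density and detection-rate covariates, 10×10 trap grid, 30 time units,
equal day/night split, β = (1.4, 0.8), α = (−0.7, 1.0), ξ = −1, σ = 0.4)
and refit it:

```python
from ctscr import ContinuousTimeSCR, simulate_study, canonical_design

bundle = simulate_study(canonical_design(replicate_seed=42))
print(f"simulated N = {bundle.N}, observed n = {bundle.data.n}, "
      f"detections = {bundle.data.n_events}")

est = ContinuousTimeSCR(model="full", iterations=1200, burn_in=200, seed=7)
est.fit(bundle.data, bundle.domain, bundle.schedule)
print(est.summary_.round(3))
print("abundance:", {k: round(v, 1) for k, v in est.abundance_.items()})
```

which prints

```
simulated N = 156, observed n = 132, detections = 8803
           mean    2.5%   97.5%   mcse
beta_0    1.487   1.285   1.728  0.012
beta_1    0.768   0.556   0.986  0.012
alpha_0  -0.724  -0.761  -0.688  0.003
alpha_1   1.011   0.978   1.044  0.002
xi_0     -1.022  -1.071  -0.977  0.003
sigma     0.397   0.392   0.403  0.000
n0       25.196  14.000  36.025  0.327
abundance: {'mean': 157.2, 'lo': 146.0, 'hi': 168.0}
```

Every generating value lies inside its 95% credible interval: the
day/night effect `xi_0 ≈ −1.02` says the daytime encounter rate is
`exp(−1.02) ≈ 36%` of the nighttime rate; `sigma ≈ 0.40` is the movement
scale, so a 95% home range is `π σ² χ²₂,₀.₉₅ ≈ 3.0` area units
(`est.home_range(0.95)`); the posterior of `n0 ≈ 25` never-detected
animals brings total abundance to ≈157 against a simulated truth of 156.
`est.predict_abundance(map_resolution=0.26)` returns the gridded posterior
abundance map, and `est.predict_density(area_unit=100.0)` the density per
100 squared units.

A `ctscr` command-line tool wraps the same pipeline
(`simulate`, `fit`, `predict`, `summarize`, `recover`) around the CSV
schemas documented in `ctscr.io`.

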