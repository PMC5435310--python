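# Methods

This note records the modelling assumptions, numerical choices and design
decisions behind `ctscr`, in the spirit of a statistical-software methods
appendix.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and likelihood

The hierarchical model couples a spatial Poisson process of latent
activity centers, `log λ(s) = β′v(s)` over a finite region `B`, with
per-trap inhomogeneous temporal Poisson processes of detection times,
`φ(t, s, x_k) = ψ_k γ(t) exp(−‖s−x_k‖²/2σ²)`, `log ψ_k = α′w_k`,
`log γ(t) = ξ′z(t)`.  Assumptions worth making explicit:

* **Spatial closure** — centers are fixed for the survey's duration.
* **Conditional independence** — given its center, an animal's detection
  processes at different traps are independent Poisson processes; there is
  no behavioral response (trap-happiness/shyness) and no interaction
  between animals.
* **Gaussian distance decay** — encounter rate falls as a half-normal
  kernel of center–trap distance; `σ` has length units and also fixes the
  derived home-range area `π σ² χ²₂,q`.
* **Known temporal covariates** — `z(t)` must be available over every
  trap's whole operating window, not just at detection times.

The observed-data log-likelihood augments the `n` observed individuals
with the never-detected count `n0` via
`π0 = Λ(B)⁻¹ ∫_B λ(s) Π_k exp[−Φ(T_k,s,x_k)] ds`:

```
log L = −Λ(B) + n0·log(π0 Λ(B)) − log(n0!) + Σ_i log λ(s_i)
        + Σ_{i,k} [ −Φ_ik − log(y_ik!) + Σ_j log φ(t_ikj) ]
```

The **restricted** (time-homogeneous) model drops `γ(t)` and uses the
counts-only likelihood `y_ik | s_i ~ Poisson(T_k φ(s_i, x_k))`.  Its
temporal parameters are structurally non-identifiable (γ is absorbed by
the intercept `α₀`), and the package refuses a restricted fit with
temporal effects supplied.  With equal day/night durations and a true day
effect ξ, the restricted intercept estimates `α₀ + log((1+e^ξ)/2)` — the
time-averaged encounter rate — which for ξ = −1 is a bias of ≈ −0.38.
With ξ = 0 the two likelihoods differ by the data constant
`Σ_ik y_ik log T_k` (the uniform density of the ignored times); the count
parameterization `(T_k φ)^y` was chosen for the restricted model so that
this identity holds exactly, and it is asserted to 1e-10 in the tests.

## Quadrature

All spatial integrals (`Λ(B)`, `π0`, the unobserved-center weights) use a
midpoint rule over a regular grid of square cells; non-habitat cells are
excluded from integrals, proposals and predictions.  The quadrature
resolution is a configuration parameter.  For a constant intensity the
midpoint rule is exact; for smooth surfaces the tests check that halving
the cell size changes `Λ(B)` by well under 0.5% at the default
resolutions.  Centers `s_i` are continuous parameters: `λ` and `Φ` are
evaluated at exact coordinates for individuals, and at cell centers only
inside integrals.  Density covariates at a continuous point are looked up
from the point's cell (piecewise-constant interpolation), keeping the
likelihood consistent with the quadrature at masked-cell boundaries.

Time integrals `Φ = ∫ φ dt` are closed-form for piecewise-constant
temporal covariates (`Φ = ψ e^{−d²/2σ²} Σ_seg e^{ξ′z} · len`), the case of
any day/night analysis; `expected_count_numeric` provides adaptive
quadrature for arbitrary `γ(t)` and the closed form is cross-checked
against it to 1e-8 relative error.

## MCMC

Posterior sampling is Metropolis-within-Gibbs, each iteration doing:

1. blockwise Gaussian random-walk updates of `β`, `α`, `ξ` and `log σ`
   (Jacobian-corrected; proposals with `σ ≥ σ_max` are rejected);
2. simultaneous per-individual random-walk updates of the centers —
   conditionally independent targets, so the sweep vectorizes; proposals
   in masked or out-of-bounds cells are rejected (a zero-prior region);
3. an exact Gibbs draw `n0 ~ Poisson(π0 Λ(B))`, its full conditional.

**Priors.** Normal(0, 10²) on every coefficient of β, α, ξ; Uniform(0,
σ_max) on σ with σ_max defaulting to half the domain diameter.  These are
weakly informative at the scale of log-rates and are configurable.

**Initialization.**  Centers start at each individual's detection-weighted
trap centroid; σ at the root-mean-square detection distance from those
centroids; the encounter intercept by moment-matching the total detection
count; density intercept at `log(n/|B|)`; all other coefficients at 0.

**Adaptation.**  Proposal scales follow a Robbins–Monro recursion on the
log scale during burn-in only (targets: 0.44 for scalar blocks, 0.25 for
vector blocks, 0.35 for the bivariate center proposals) and are frozen
afterwards, so the retained chain is a valid Markov chain targeting the
posterior.  Initial scales are set from data-size heuristics
(≈ 1/√(total detections) for rate parameters).

**Fast path.**  For piecewise-constant `z(t)` the likelihood depends on
the detection times only through the per-pair counts `y_ik` and the summed
covariate values at event times, so the sampler precomputes the cell–trap
distance matrix and per-trap effective durations and re-evaluates, per
block, only the factors that block changes (e.g. an `α` proposal reuses
the σ-kernel).  The fast path is asserted equal to the reference
likelihood to 1e-10.

**Reproducibility.**  One master seed spawns independent child streams
for the θ-blocks, the center sweep and the n0 draw, so draws at iteration
t are unaffected by the total iteration count, and chains are
bitwise-reproducible.  Batch-means Monte Carlo standard errors (⌊√m⌋
batches) accompany every posterior summary.

The marginal likelihood is deliberately not computed: the latent centers
are the inferential target, not a nuisance.

## Posterior prediction

Centers of the `n0` never-detected individuals are drawn per retained
iteration from the discrete cell distribution with weights
`λ_m exp(−Σ_k Φ_mk)·area`, jittered uniformly within the chosen cell —
exact at the quadrature resolution and consistent with the discretization
used for `π0`.  Abundance maps `N(B_m)` bin observed-chain centers plus a
fresh draw of unobserved centers each iteration (no thinning), so map
summaries average over full posterior uncertainty; per iteration the cell
counts sum exactly to `n + n0`.  Density is `(n + n0)/|B|` per iteration,
scaled to the requested area unit.  The home-range area `π σ² χ²₂,q`
follows from the Gaussian kernel.

## Synthetic-data generator

`simulate.canonical_design()` encodes the canonical validation design:

| quantity | value | why |
| --- | --- | --- |
| β | (1.4, 0.8) | generating density model |
| α | (−0.7, 1.0) | generating encounter model |
| ξ | −1 | daytime rate ≈ 37% of nighttime |
| σ | 0.4 | multi-trap exposure for animals near the array |
| region | 5.2 × 5.2 square | gives E[Λ(B)] ≈ 150 for a standardized covariate surface |
| traps | 10 × 10 grid, spacing 0.31, centered | spacing chosen so the design's expected observed count Λ(B)(1−π0) ≈ 124 |
| T | 30 time units, all traps | continuous operation |
| day/night | alternating half-unit segments, equal split | piecewise-constant z(t) |
| quadrature | 0.13 (40 × 40 cells) | ≈ σ/3; Λ(B) stable under refinement |

Covariate surfaces (one for density, one for baseline detection rate) are
Gaussian-smoothed white noise (length scale 1.0), standardized to mean 0 /
sd 1 over habitat cells, deterministic given a seed, and held fixed across
replicates.  They are a stand-in with the same statistical role as the
surfaces used in the original validation experiment, not a reconstruction of them, so quantities
that depend on the exact surface (e.g. Λ(B) = 150.2 precisely, or the
trap-level ψ range 0.41–0.61) are matched only in design expectation —
here Λ ≈ 146 and E[n] ≈ 123.5.

Detections are simulated exactly for piecewise-constant `z(t)`: a Poisson
count per (individual, trap, segment) with uniform times within the
segment.  A thinning sampler for general `γ(t)` is provided and
cross-validated against the exact one.  What the generator does *not*
emulate about real data: animal movement trajectories (only the
activity-center abstraction), trap outages, double-counting across paired
cameras, identification error, and tied timestamps.  Passing the
recovery tests therefore demonstrates correctness of the inference under
the model's own assumptions, not robustness to those field realities.

## Scaled-down replication protocol

The replicate experiment (`ctscr.recovery`, `scripts/acceptance.py`,
`tests/test_acceptance.py`) fits both models to each replicate with 1200
MCMC iterations and 200 burn-in, summarizing the final 1000 draws — the
protocol of the original validation experiment — using 20 replicates in the script and 10 in
the test suite (the package's choice of problem size; per-replicate Monte
Carlo error enters the test tolerances explicitly as 3 standard errors of
the replicate mean).

## Degenerate inputs and edge cases

* Tied detection times are admitted with a warning (probability zero
  under the model, common in real camera data).
* Times exactly on a segment boundary belong to the earlier segment
  ((start, end] convention), matching the half-open trap window (0, T_k].
* An all-masked domain, a schedule with gaps/overlaps, times outside
  (0, T_k], unknown trap ids, or a restricted fit with temporal effects
  all raise typed, row-addressed errors at the I/O boundary.
* A non-finite log-posterior aborts the chain with a diagnostic rather
  than continuing silently.
* Zero traps make the empty product equal 1, so π0 = 1 and prediction
  reduces to the density surface.

## Known limitations

* The temporal process is Poisson: no self-excitation (a tiger lingering
  in front of a camera produces clustered photos that violate this).
* Each trap station is one detector; paired-camera deduplication is
  assumed done upstream.
* Coordinates are planar; geographic projection is the user's
  responsibility.
* The quadrature grid bounds the spatial resolution of predictions;
  abundance maps cannot be finer than the quadrature and the package
  refuses to pretend otherwise.
* Open-population dynamics (recruitment, mortality between sessions) are
  out of scope.
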