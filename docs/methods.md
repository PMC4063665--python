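# Methods

## Model structure and assumptions

Silicon moves through four pools — medium (S₁, µM), cytoplasm (S₂), soluble
SDV content (S₃) and deposited silica (S₄, all per-cell pools in fmol/cell) —
via three enzymatic steps, each modelled in full mass-action form (reversible
binding to a finite pool of active sites, irreversible catalysis) rather than
as an instantaneous Michaelis–Menten rate law.  Keeping the binding
intermediates Cᵢ explicit costs four extra state variables but buys three
things: enzyme conservation becomes a structural property that the solver can
be tested against; surge uptake by starved cells emerges from the transient
loading of free transporters without any ad-hoc switching; and time-varying
enzyme totals (SIT expression over the cell cycle) enter naturally.

Assumptions worth stating explicitly:

* **Synchronized-majority coupling.**  All cells are represented by one set
  of intracellular ODEs; the non-synchronized minority enters only through
  the measured cell-density curve N(t), whose growth term U·dN/dt withdraws
  medium silicon for newly dividing cells.  N(t) is an input (flat for
  `t_lag`, then exponential), not a fitted quantity, and is analytic so
  dN/dt is exact inside the stiff solver.
* **Amount-based pools.**  Per-cell pools are amounts, not concentrations;
  compartment volumes (notably the small and growing SDV volume) are
  absorbed into the kinetic constants, because they are unmeasured and would
  not be identifiable from these data.
* **Net uptake.**  dU/dt is the net flux through the transporter step
  (binding minus unbinding), so the medium balance is exact by construction;
  U can transiently fall only if unbinding dominates.
* **Validity domain.**  The model describes a culture whose medium is not
  exhausted: once S₁ reaches zero the population term would drive it
  negative.  The default scenario keeps the horizon inside this domain, and
  the uptake-rate assay (below) dilutes the culture for the same reason.
* **Michaelis constant convention.**  The fitted Kᵢ is the Michaelis
  constant of the derived scheme: kf_i = kcat_i(1 + r)/Kᵢ, kr_i = r·kcat_i,
  with the reverse-to-catalytic ratio r fixed at 1 (not fitted; it is not
  identifiable from saturation-type data and only shifts the partitioning
  between kr and kcat at fixed Kᵢ).

## Default scenario (what the synthetic data emulate)

The generator emulates a synchronized batch-culture experiment on
*T. pseudonana* after 24 h silicon starvation: all intracellular pools start
empty, silicic acid is added at t = 0, and the population is observed for
5 h.  Defaults, chosen once as a realistic scenario of this type:

| quantity | default | rationale |
|---|---|---|
| S₁(0) | 100 µM | typical replete pulse after starvation |
| V_c | 1 L, N₀ = 5×10⁸ cells/L | ~5×10⁵ cells/mL culture; keeps total demand inside the medium budget |
| lag / growth | 120 min flat, then 2×10⁻³ min⁻¹ | density flat ~2 h, then ~40 % growth over 3 h (partial synchrony) |
| K₁ | 8 µM | literature-scale half-saturation for SIT uptake |
| kcat₁, E₁₀ | 2 min⁻¹, 0.25 fmol | Vmax₁ = 0.5 fmol cell⁻¹ min⁻¹, surge-scale uptake |
| K₂, kcat₂, E₂₀ | 5 fmol, 5 min⁻¹, 0.10 fmol | cytoplasmic pool peaks ~20 fmol |
| K₃, kcat₃, E₃₀ | 2 fmol, 5 min⁻¹, 0.09 fmol | ~100 fmol silica deposited per cell over the run |
| observations | 10 medium-Si samples over 0–300 min, 5 % relative sd | sparse, noisy population data |
| end point | one S₄ value at 300 min, 5 % relative sd (floor) | per-cell silica content is known only roughly |

With these values the run depletes the medium from 100 to ~8 µM and ends
with ~98 fmol deposited silica, ~18 fmol cytoplasmic pool and ~128 fmol
cumulative uptake per cell — the order of magnitude reported for this
organism (tens of fmol per valve, a ~15 fmol silicon pool, per-cell uptake
below ~100 fmol).

Observation noise is independent Gaussian with truthfully recorded
per-point standard deviations (weighted least squares is then the Gaussian
maximum-likelihood criterion, and the objective at the true parameters has
expectation equal to the number of observations — the calibration the
acceptance script verifies).  `noise_scale=0` produces noise-free data with
the same recorded sds for recovery experiments.  The generator does **not**
emulate measurement drift, autocorrelated errors, partial-synchrony
distributions, or day/night physiology; passing tests therefore demonstrate
correctness of the inference machinery under the stated error model, not
robustness to real-data pathologies.

## SIT expression profile

Time-varying transporter totals enter as Eᵢ + Cᵢ = gᵢ(t)·Eᵢ₀ with gᵢ
piecewise linear, implemented as the additive source Eᵢ₀·gᵢ′(t) on free
enzyme (newly expressed enzyme arrives unoccupied — the simplest scheme
consistent with scaling the conservation law).  The default profile starts
at 1, dips to 0.5 in a 120–180 min S-phase window (deposition pauses there)
and rises to 1.3 during valve formation — within ±50 % of the average, as
immunoblot time courses indicate; only the shape, not the amplitude, is
meant to be quantitative.  The deposition enzyme keeps a constant total.

## Inverse problem

The objective is F(θ) = Σ((dᵢ − fᵢ(θ))/σᵢ)² + P(θ) over the medium-silicon
series and the single end point (cell density is a known input, not fitted).
The penalty encodes that total enzyme must stay below a fraction ε of the
time-averaged substrate+product pool ρᵢ of its step:

P(θ) = w·Σᵢ logistic(α·ln(Eᵢ₀/ρᵢ/ε)),  defaults w = 10, α = 5, ε = 0.01.

The logistic acts on the **log** of the ratio: it is smooth and monotone in
every Eᵢ₀, negligible deep inside the feasible region, w/2 per step at the
boundary and saturating at 3w deep in violation, with a gentle slope (α = 5
keeps the constraint soft, widening the acceptance interval rather than
pinning parameters).  For step 1 the substrate pool is counted per cell
(S₁V_c/N(t)); ρᵢ = 0 is treated as a maximal violation.  A trial θ whose
simulation fails contributes a large finite sentinel (10⁶) instead of an
exception so the metaheuristic can continue.

**Search.**  Scatter search over box bounds spanning the literature-scale
orders of magnitude, all coordinates log-scaled: a Latin-hypercube
diversification sample, a reference set split between a quality half and a
max-min-distance diversity half, trial points on the (extrapolated) segments
between reference pairs, adaptive Nelder–Mead refinement of promising trials
clipped to the box, and a final chain of simplex restarts.  The search runs
in the observable coordinates (Kᵢ, Vmaxᵢ = kcat_i·Eᵢ₀, Eᵢ₀) rather than
(Kᵢ, kcat_i, Eᵢ₀): the data term is governed almost entirely by (K, Vmax)
while the penalty constrains only Eᵢ₀, so these coordinates decouple the two
terms and remove a long compensating kcat·E₀ valley that otherwise traps
derivative-free search.  Candidates are always materialized as the canonical
parameter vector before simulation.

**Acceptance, not optimization to the bottom.**  The stopping tolerance is
set by the data error: n_fitted + 5 for routine fits (the headline fit of
this kind lands around 15 for 10 points), n + 3√(2n) (the ~3σ upper quantile
of a χ²ₙ) for synthetic-ensemble experiments, and a small floor (10⁻³) for
noise-free recovery.  All evaluated vectors with F below the tolerance form
the accepted ensemble (deduplicated at 10⁻⁶ relative distance); refining
further would fit noise.  The fitted-record count is 11 (10 medium-silicon
points + the end point).

## Identifiability diagnostics

Raw sensitivities ∂x/∂θ are integrated as forward sensitivity ODEs with
analytic state and parameter Jacobians (the right-hand side is polynomial,
so the Jacobians are exact closed forms; the Eᵢ₀ initial-condition
dependence enters through S(0)).  Central finite differences with relative
step 10⁻⁶ serve as an independent oracle; the two agree to ≤10⁻³ relative
(per-state scaling) at tight solver tolerances.  Normalized sensitivities
∂x/∂θ·θ/x are reported for the fitted observables by default; entries with
|x| < 10⁻¹² are masked, never zeroed or regularized.  Perturbation analysis
rescales each parameter by (1 ± 10 %), re-simulates and records objective
change, maximum relative trajectory deviation, and whether the sign pattern
of the time derivative survives (evaluated only where the derivative is
decisively nonzero).  Ensemble dispersion is summarized per parameter as the
coefficient of variation and the range over the searched bound range, in the
search coordinates when a search space is supplied.

## Numerical choices

* Solver: LSODA with the analytic Jacobian; defaults rtol 10⁻⁸ / atol 10⁻¹⁰
  for simulation (conservation residuals ≤10⁻⁶ relative, typically ≤10⁻⁸),
  relaxed to 10⁻⁶/10⁻⁸ inside objective evaluations where ~10⁻⁷-level
  objective noise is immaterial against the 10⁻³ recovery floor.
* No negative-value clipping anywhere: non-negativity is asserted by tests
  (within 10× the absolute tolerance), not patched in the dynamics.
* Piecewise-linear gᵢ report right-hand derivatives at knots; constant
  extrapolation outside the knot range.
* The uptake-rate surface is computed as a rate assay on a 20-fold diluted,
  non-growing subsample — mirroring how short-incubation uptake kinetics are
  measured, and keeping long incubations at low concentration inside the
  model's validity domain.
* The diffusion check solves the flux balance vmax·s/(K+s) = 4πDa(s∞ − s)
  for the membrane concentration by bracketed root finding (the root always
  lies in [0, s∞] for positive inputs) with seawater-scale D = 10⁻⁹ m²/s and
  cell radius 1.5 µm; at those values transport limitation stays at the
  percent level even with D reduced tenfold, justifying the compartmental
  (non-spatial) treatment.
* Reproducibility: a single run seed fans out to per-stage child seeds via a
  CRC-keyed SeedSequence, so every stage can be rerun in isolation and whole
  pipelines are bit-reproducible (timestamps aside).

## Problem sizes used in the shipped experiments

The shipped tests and scripts run the estimator at reduced budgets chosen as
sensible desk-scale defaults: diversification 80–90 points, reference set
8–10, ≈2,500 evaluations for noisy penalty-on/off comparisons and ≤12,000
for noise-free recovery; the replicate-calibration experiment uses 1000
synthetic datasets.  Dispersion comparisons subsample ≤60 ensemble members
for trajectory statistics.

## Known limitations

* Structural identifiability is not analyzed symbolically; the package
  quantifies *practical* identifiability via the accepted ensemble (the Eᵢ₀
  remain non-identifiable — only K and Vmax are pinned by these data, which
  is precisely what the penalty comparison demonstrates).
* No per-cell heterogeneity or ensemble-of-cells modelling; the population
  enters through N(t) only.
* No silica polymerization chemistry, SDV geometry or pattern formation.
* Gross vs net uptake cannot be distinguished from these data; the net
  convention is hard-wired into U.
* The scatter search is serial; no gradient-based or Bayesian estimation.
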