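# Methods

## Models

Both models describe a scalar decision variable x(t) absorbed at two
boundaries, with the upper boundary coding the correct response.

**DDM.** dx = ν dt + σ dW on (−B, B). ν (state units/s) is the evidence
quality; B (> 0) the boundary separation half-width.

**nl-DDM.** dx = −k (x + a)(x − z)(x − a) dt + σ dW. The drift is the
negative gradient of the double-well potential
V(x) = k(x⁴/4 − z x³/3 − a² x²/2 + a² z x). The cubic has exactly three
roots: stable attractors at ±a (drift slope −2k a² ± … < 0 there) and an
unstable fixed point at z, constrained to lie strictly inside (−a, a). The
deterministic flow only approaches ±a asymptotically; absorption is carried
by noise, so the absorbing boundaries sit exactly at ±a with no buffer.
Moving z toward −a deepens the +a well (V(−a) − V(z) strictly decreases in
z), larger k scales time (the noise-free path under k at time t equals the
path under k'=k/c at time c·t), and larger a pulls the wells apart.

Setting z = 0 and matching coefficients against the symmetric double-well
potential V(x) = −μx − αx² + x⁴ at μ = 0 gives k = 4 and a² = α/2; no
reduction exists for μ ≠ 0 because the nl-DDM's cubic term has no DWM
counterpart, and the map raises an error in that case.

**Shared machinery.** Starting points are uniform on [x₀ − s_z, x₀ + s_z],
required to lie strictly inside the open domain. The non-decision time
T_nd (s) is a pure translation of the decision-time distribution. The noise
term is interpreted as Wiener increments: a discrete step adds
drift·dt + σ√dt·N(0,1). σ defaults to 0.3 and is held fixed during fitting
(drift/boundary/noise are jointly non-identifiable; fixing the noise scale
is the standard normalization).

## Simulation

Euler–Maruyama with default dt = 0.5 ms and t_max = 5 s (task response
windows are 2–3 s; the margin accommodates slow parameter regimes).
Boundary crossing is detected by sign change at grid points without a
Brownian-bridge correction — a first-order scheme whose bias shrinks with
dt; a coupled coarse/fine refinement test (coarse noise equal to summed
fine noise) bounds the choice-probability bias below one binomial standard
error at n = 10,000. Undecided trials at t_max are excluded from the trial
table but counted in metadata, because the likelihood operates on observed
RTs only. One seed drives two independent streams (starting points; within-
trial noise) through `numpy.random.SeedSequence`, making datasets exactly
reproducible.

## First-passage solver

The forward Fokker–Planck equation ∂p/∂t = −∂(μ(x)p)/∂x + (σ²/2)∂²p/∂x² is
discretized in conservative flux form on a uniform grid (default
dx = domain/200) with Scharfetter–Gummel exponential fitting at cell faces
(weight B(w) = w/(eʷ−1), computed from the positive branch and the identity
B(−w) = w + B(w) so large drift-to-diffusion ratios cannot overflow). This
reduces to central differences for small cell Péclet numbers and to upwind
for large ones, keeping densities non-negative for any k, ν. Time stepping
is Crank–Nicolson with default dt = 2 ms; the constant tridiagonal system
is Thomas-factorized once and reused each step (compiled with numba). The
uniform starting distribution is deposited with cell-proportional weights
(point starts split linearly between neighbors); a support within half a
cell of a boundary is rejected as touching it. Boundary fluxes are read at
the time-midpoint state, which makes the discrete balance exact: absorbed
correct + error mass + remaining (undecided) mass = 1 to round-off; the
undecided mass is reported, never renormalized. Defective densities are
sampled at step midpoints (n + ½)dt, and T_nd shifts the grid exactly.

Validation is dual-route: the DDM solution is compared against the
closed-form Wiener first-passage image series (method of reflections with
per-term combined exponents, 12 image pairs; `nlddm.analytic`, sharing no
code with the solver) at total-variation distance < 1%, and the nl-DDM
solution against 50,000-trial Monte-Carlo runs at Kolmogorov–Smirnov
distance < 0.02. Halving dx and dt moves the absorbed correct mass by
less than 10⁻³.

## Likelihood, configurations, fitting

NLL = −Σ ln f(rtᵢ), where f is the correct-boundary defective density for
correct trials and the error-boundary density for error trials, evaluated
by linear interpolation of the solver grid at the observed RT and floored
at 10⁻¹⁰ before the log (an RT where the model has no mass, e.g. below
T_nd, contributes −ln 10⁻¹⁰ instead of infinity). RTs beyond the solved
horizon are an error, not a silent zero. BIC = ln(n)·#params + 2·NLL with
the natural logarithm.

A `ModelConfig` maps parameters to condition factors. The two bundled
designs: a two-stimulus task (DDM: B, ν per stimulus ×2, x₀, s_z, T_nd — 6
free; nl-DDM: k, a, z per stimulus ×2, x₀, s_z, T_nd — 7 free) and a
four-word-type × instruction × phase design (DDM: ν per word ×4, B per
instruction×phase ×4, x₀, s_z, T_nd — 11 free; nl-DDM: z per word ×4, a per
instruction ×2, k per phase ×2, x₀, s_z, T_nd — 11 free). σ is fixed at 0.3
throughout, and the non-decision time is shared across conditions.

Constraints are kept feasible by searching z, x₀ as fractions of the
smallest boundary parameter in play and s_z as a fraction of the remaining
gap (reported back on the absolute scale), so plain box bounds suffice.
The global stage is seeded `scipy` differential evolution (population
15·dim, Sobol initialization, tol 10⁻⁶, generation cap 25); a Nelder–Mead
polish follows, clipped back into bounds. During fitting the solver runs
at a coarser resolution (nx = 120, dt = 4 ms, horizon = max observed RT)
than stand-alone solves; the refinement bound above covers the
discretization gap. Non-convergence is reported through a flag.
Undecided-trial probability mass does not enter the likelihood — a
deliberate divergence from toolkits that model censoring, consistent with
datasets that contain decided trials only.

Parameter-recovery protocol: nuisance quantities that are known by design
(σ, T_nd — and for point-start DDM data, x₀ = s_z = 0) are fixed at their
generating values, mirroring how the sweep study fits are configured; with
T_nd free the likelihood has a ridge trading T_nd against k that inflates
individual errors without worsening fit quality.

## Studies

**Parameter sweep.** Defaults B = 1, ν = 0.2, x₀ = 0, s_z = 0, σ = 0.3,
T_nd = 0.3; ranges B ∈ [0.2, 5], ν ∈ [0, 10], x₀ ∈ [−1, 1], s_z ∈ [0, 1];
uniform inclusive grids, one parameter varied at a time (100 points each →
400 datasets at full scale; the validation battery runs 10 points each →
40 datasets), 500 trials per dataset. Grid values whose start support would
touch the boundary (x₀ = ±1 at B = 1; s_z = 1) are recorded as requested
but simulated with the support clipped to 98% of the half-domain, since an
absorbing start decides instantly and is outside the solver's premises.
The nl-DDM refit fixes σ = T_nd = 0.3 (the generating values) and frees
k, a, z, x₀, s_z. Weak-drift/wide-boundary grid points can leave most of
the 500 trials undecided within t_max = 5 s; fits then use few trials and
are noisy, and grid points with no decided trials are recorded as failures.
Correlations are Pearson ρ over complete rows with two-sided p from the
t reference (n − 2 df); within-DDM pairs are masked as design artifacts.

**Model comparison.** Paired BIC differences are tested for normality
(Shapiro–Wilk at the family α); a one-sided paired t-test runs if normality
is not rejected, otherwise a one-sided Wilcoxon signed-rank test. Constant
nonzero differences go to the signed-rank branch (normality is undefined,
the exact rank null still applies); all-zero differences short-circuit to
p = 1. Effect sizes: Cohen's d (t branch) or matched-pairs rank-biserial
correlation (signed-rank branch). Parameter discriminability across
condition levels uses all pairwise paired t-tests at Bonferroni-corrected
α = family α / #pairs (0.05/6 ≈ 0.008 for four levels).

## Synthetic data and what the tests show

The generator produces exactly the data the models assume: uniform starts,
Wiener noise, stationary parameters within a condition, independent trials,
and a hard simulation horizon standing in for a response deadline. Real RT
data additionally contain contaminant responses, drifting attention and
sequential effects, and non-decision-time variability — none of which are
emulated, so passing recovery and agreement tests demonstrate correctness
of the machinery, not adequacy of the model for any particular dataset.
The 180 ms anticipatory filter treats "below" strictly (a trial at exactly
0.180 s is retained); phase labelling splits the ordered block sequence at
its midpoint and excludes participants missing any block, since they lack
a complete half of the design.

## Numerical choices and limitations

- Validation thresholds: mass conservation 1 ± 10⁻³; TV < 1% vs the
  analytic series; KS < 0.02 vs 50k-trial Monte-Carlo; recovery medians
  < 20% (k, a) and < 0.15·a (z) at n = 2000.
- Scales used in the validation battery (chosen to exercise each property
  at desk scale): 20 solver draws, 5 simulator draws × 50,000 trials,
  10 recovery datasets × 2000 trials, 10-point sweep grids × 500 trials.
- Degenerate inputs fail loudly: invalid geometry raises at construction;
  a start support touching the boundary, non-positive steps, RTs beyond
  the horizon, empty datasets and zero-mass conditional means all raise.
- The solver covers only time-homogeneous drifts; within-trial stimulus
  dynamics (e.g. z varying in time) and multi-alternative extensions are
  out of scope, as are drift-rate and non-decision-time variability.
- Differential evolution with a capped generation budget is stochastic-
  search: the convergence flag reports termination quality, and repeated
  seeds give the spread. Likelihood ridges (k vs T_nd; k vs a) are
  intrinsic to the model class, not solver artifacts.
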