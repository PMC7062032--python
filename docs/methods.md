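# Methods

This note documents the models, the synthetic-data generating process, the
numerical choices, and the limits of what the test suite demonstrates.

## Assemblage construction

Geographic units are either botanical-country-like polygons with an `area`
covariate or equal-area grid cells with `row`/`col` coordinates. Primate
colour vision is coded in three exhaustive, exclusive classes: routine
trichromatic (both sexes trichromatic), polymorphic (population mixture of
di- and trichromats), and dichromatic-or-monochromatic. A frugivore is any
species with fruit rank 1–3; the day-active-frugivore subset keeps diurnal
frugivores only. Cathemeral/crepuscular species do **not** count as
day-active by default (conservative reading; `cathemeral_is_diurnal=True`
flips this).

Palm fruit colours come from a 14-token vocabulary. Classification is a
two-step rule: (1) palatability — a species none of whose listed colours is
a primate-diet colour (brown, green, orange, yellow, red, purple) is
excluded from all proportions; (2) conspicuousness — among palatable
species, *any* of orange/red/yellow/pink makes the species conspicuous,
otherwise it is non-conspicuous. For multi-colour species this is the
permissive reading: a fruit displaying any reddish colour is detectable by
a trichromat. A side effect worth noting: a pink-only species is excluded
(pink is conspicuous but not a diet colour); the classification is
deliberately deterministic so this edge case is visible rather than silently
resolved.

Unit filtering keeps units with at least one focal-class primate and at
least three palatable palm species, so the conspicuousness proportion is
never computed from one or two species. The "more than two palms" rule is
applied to palatable (non-excluded) species only, since excluded species
never enter the proportion. Model variables are transformed in a fixed
order: square root for richness (to normalize counts), natural log for
area, then min–max scaling of every variable to [0, 1]. Transforming before
scaling keeps the variance-stabilizing step on the modelled scale; the
scaling constants are recorded for inversion. Min–max scaling is linear, so
standardized coefficients are unaffected by it; it only standardizes the
raw-coefficient scale across variables.

## Path analysis

The structural model is a recursive (acyclic) system of linear equations
among observed variables with independent Gaussian errors and a fully free
covariance block among exogenous variables. Free parameters: one
coefficient per path, one residual variance per endogenous variable, and
the exogenous variances/covariances. The implied covariance is
`Σ(θ) = (I−B)⁻¹ Ψ (I−B)⁻ᵀ`; fitting minimizes the Wishart ML discrepancy
with the (n−1) convention (`χ² = (n−1)·F`, stated explicitly because
software differs on n vs n−1). For recursive models the likelihood
factorizes along the DAG, so per-equation regression computed from the
sample covariance is the exact optimum; a BFGS refinement is still run from
that start (gradient tolerance 1e-8) and the converged flag reports its
outcome. Standard errors come from the inverse observed information
(numerical Hessian of F times (n−1)/2).

Fit indices: CFI against the independence baseline;
`RMSEA = sqrt(max(χ²−df,0)/(df(n−1)))` with its confidence interval from
numerically inverting the noncentral χ² distribution (Brent root-finding,
tolerance 1e-12 on the noncentrality). The RMSEA CI coverage defaults to
90% (conventional); the adequacy gate "RMSEA CI < 0.05" is evaluated on the
lower bound by default with the upper bound always reported, because the
gate's strictness depends on which bound one reads and both readings should
be auditable. With df = 0 the RMSEA is reported as 0 with an explicit
`rmsea_undefined` flag.

Backward elimination removes, at each step, the path with the largest
p ≥ α (ties: smallest |z|, then lexical (cause, effect) order), refits, and
stops when all paths are significant; the elimination log records every
removal and the final fit-gate status (χ² p > 0.05, CFI > 0.90, RMSEA
gate). Modification indices are computed by exact refit with the candidate
edge freed (the realized Δχ², not the Lagrange-multiplier approximation) —
slower but unambiguous at these model sizes.

## Permutation null and gradient delimitation

The permutation test reshuffles primate species across units: for a unit
with observed total richness k, k distinct species are drawn uniformly
without replacement from the global pool, independently across units (a
species may occupy many units, as with range data). This is the minimal
scheme that preserves per-unit total richness exactly. Each replicate runs
the full pipeline — reshuffle, rebuild the assemblage, filter, transform,
refit the SEM by ML, extract the focal standardized coefficient — and the
one-sided test calls the observed effect significant when it exceeds the
95th percentile of the null coefficients. The inner loop uses an
array-based implementation of the same closed-form ML estimator the
`PathModel` uses (their equality is asserted in the tests to 1e-10).

Two properties matter for interpretation. First, the test is *conditional*
on the observed per-unit richness vector: in any single dataset the null
distribution can be visibly off-centre when total richness happens to
correlate with the predictor by chance (amplified when predictors are
collinear), but the observed statistic under a true null is drawn from the
same conditional law, so type-I error is calibrated — the test suite
verifies ~5% rejection over 200 independent null datasets. Second,
centring "near zero" therefore holds relative to the null spread, not to
Monte-Carlo precision.

The progressive delimitation refits the SEM on nested subsets defined by
minimum palatable palm richness thresholds (2..16 by default, i.e. 15
fits; re-transforming variables on each retained subset), recording the
focal standardized coefficient with a delta-method standard error
(`se_std = |std/b|·se(b)`, ignoring the sampling variability of the
standard deviations) and the fit-gate status. Thresholds leaving fewer
than 30 units (configurable) are recorded as skipped rather than fitted.

## Spatial models

Grid weights use rook adjacency, row-standardized, by default; queen and
binary styles are available. These defaults are assumptions, not derived
facts, and are stamped on the weights object. The SAR *error* specification
(not the lag model) matches the purpose of absorbing residual spatial
autocorrelation: `y = Xβ + u, u = λWu + ε`. λ is profiled over its
eigenvalue-bounded feasible interval with β and σ² concentrated out;
`ln|I−λW|` uses the precomputed eigenvalues of W, and a boundary flag marks
estimates within 0.01% of the feasible interval ends. At λ = 0 the model,
its coefficients and its log-likelihood reduce exactly to OLS. Moran's I
uses the analytic randomization-assumption moments. SAR is applied to
single-equation response models (as in the OLS/SAR robustness comparison),
not to the full path system.

## Mk models, mapping, diversity curves

The Mk likelihood uses Felsenstein pruning with per-branch transition
matrices; P(t) is computed from one eigendecomposition of Q vectorized over
all branch lengths, with an expm-per-branch fallback when the
eigendecomposition is ill-conditioned (condition number > 1e8). Partial
likelihoods are max-scaled per node. The root prior defaults to the
stationary distribution of the fitted Q, with a flat prior selectable —
reported results always carry the choice. Rate fitting is L-BFGS-B on log
rates with two multiplicative starts; ER/SYM/ARD constraints are supported,
and single-observed-state data is fitted but flagged (the rate runs to the
lower boundary and is weakly identified).

Marginal ancestral reconstruction uses message passing (equivalent to the
re-rooting method): downward partials and upward messages combine to exact
per-node conditionals. Stochastic maps sample node states jointly
(root-to-tips from the conditional distributions) and then branch
histories by uniformization — endpoint-conditioned jump counts from the
truncated Poisson–R-power series, jump times as uniform order statistics,
virtual jumps collapsed — which is exact and has no rejection blow-up on
long branches.

Diversity-through-time curves evaluate, at each internal-node age, the
expected number of contemporaneous lineages in a focal state, "just after"
the speciation event. A branch counts as contemporaneous if it strictly
spans the age, hangs from a node at that age (including zero-length
terminal branches), or ends in a tip at that age. Method `simulation`
averages indicator counts over stochastic maps (default, matching the
mapping-based estimator); method `asr` sums exact per-branch conditional
state probabilities at the evaluation point and is deterministic. Both
satisfy the conservation law (sum over states = lineages alive) — exactly
for `asr`, and exactly as well for `simulation` since each branch
contributes one state per map.

## State-dependent diversification

The MuSSE likelihood integrates the standard per-branch D/E equations
tip-to-root with an embedded Cash–Karp Runge–Kutta (adaptive steps,
rtol 1e-9, atol 1e-12, compiled with numba); D is renormalized at every
node with the log-scale accumulated. Small negative undershoots of the
integrator are clipped at zero. Internal nodes multiply daughter D vectors
by λ of the node state, including at the root; root treatments are flat,
equilibrium (stationary of q) or likelihood-weighted (default). A pure
numpy fixed-step RK4 implementation is kept as a cross-check oracle.

The strongest correctness anchor is the factorization identity: with
state-independent rates the MuSSE likelihood equals the analytic
constant-rate birth–death likelihood (closed-form D(t) ratios times
λ^(n−1); the root edge, when present, is ignored as in the pruning pass)
plus the Mk pruning likelihood, with matching root treatments — verified
to 1e-6 on random trees. Fitting is L-BFGS-B on log rates; because
free-rate models can stall on the tied-rate ridge, fits are multi-started
(asymmetric λ perturbations) and the constraint family is fitted
most-constrained first, seeding the freer models with the previous optimum.
Constraint variants: `full` (per-state λ and μ), `equal_lambda`,
`equal_lambda_mu`; q is ER by default. Trees must be ultrametric and
binary; a tip sampling fraction is available.

## Synthetic data: what it emulates and what it does not

The generators encode the study conditions used throughout the tests:

* **Landscape** — five covariates (temperature °C×10, precipitation mm,
  temperature seasonality, precipitation seasonality CV, canopy height m)
  drawn multivariate normal with a mild realistic correlation structure
  (warm–wet +0.3, warm–seasonal −0.4, wet–tall-canopy +0.5), log-normal
  areas. Defaults are humid-tropical (24 ± 6 °C, 1400 ± 700 mm).
* **Palm flora** — 60 species by default: equal numbers of conspicuous and
  non-conspicuous palatable species plus 10% excluded colours. Occupancy
  0.3 with logistic tilting `occupancy·σ(±s·z)` so the expected per-unit
  proportion conspicuous is exactly `σ(s·z)` along the standardized
  gradient covariate (slope in logits per SD); mean palatable richness per
  unit ≈ 8, spanning the 2..16 delimitation range.
* **Primates** — a 60-species pool (25 routine trichromats, 15 polymorphs —
  all diurnal frugivores — and 20 nocturnal/cathemeral others with mixed
  diets). With a non-null scenario, focal richness is generated on the
  square-root scale (`2.2 + 0.7·y_std`, back-transformed and rounded) from
  the *realized* standardized predictors, with residual SD auto-set to make
  the standardized response variance ≈ 1, so the specified path
  coefficients are the recoverable standardized effects; the sqrt-scale
  mean 2.2 keeps zero-richness units rare (<2%), so the inclusion filter
  barely truncates. Species identities are uniform draws within vision
  classes. With an all-zero scenario the generator switches to uniform
  draws from the whole pool given a Poisson total richness — exactly the
  exchangeable regime the permutation null assumes. The remaining ~0.02
  attenuation of a 0.5 effect (rounding + filter truncation) is inherent
  to the emulated protocol, not a bug, and stays well inside the tested
  recovery band.
* **Trees** — birth–death trees conditioned on a tip count (dendropy's
  simulator) with my own CTMC trait evolution; and a forward Gillespie
  state-dependent simulator (per-lineage λ/μ/q by state, extinct lineages
  pruned, bounded retries on total extinction) for BiSSE/MuSSE fixtures.

Not emulated: real geography (no range cohesion or climate envelopes),
phylogenetic signal in species ranges, multi-colour fruit descriptions
(each synthetic palm gets one colour; multi-colour handling lives in the
assemblage classifier and is tested directly), detection/sampling error in
trait data, and non-ultrametric trees. Passing tests therefore demonstrate
the *statistical machinery* — estimator correctness, calibration, power
under known effects — not that any particular empirical dataset satisfies
the models' assumptions.

## Problem sizes and numerical defaults

Test and acceptance runs use deliberately moderate sizes chosen to give
stable Monte-Carlo verdicts: 200–400 units for SEM recovery (50 reps),
200 outer × 200 inner replicates for permutation calibration, 1500 cells
for the gradient hump, 150-tip trees × 12–20 replicates for BiSSE model
selection, 20×20 grids for SAR recovery. Tolerances in tests follow the
oracle class: 1e-10 against exhaustive enumeration, 1e-6 across independent
integrators, analytic-CI-derived bands for Monte-Carlo recoveries.

## Known limitations

* No latent variables, means structure, multi-group SEM, or
  robust (sandwich) standard errors in the path models.
* Modification indices require a refit per candidate (fine at these sizes).
* SAR uses dense eigendecomposition: practical to a few thousand units.
* MuSSE has no hidden states (no HiSSE) and assumes complete, ultrametric,
  binary trees; sampling fraction is a single global ρ.
* The permutation test's exchangeability assumption concerns species
  labels only; spatially constrained nulls (e.g. range-cohesion) are out
  of scope.
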