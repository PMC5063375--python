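# Methods

## Kinetic engine

Networks are generalized mass action (GMA) models: rates
`v_k = alpha_k * prod_l x_l**g_kl`, species dynamics
`dx/dt = N v + B u`.  Concentrations and activities are in relative units
throughout; no unit conversion layer exists.  `0**0` is taken as 1 (the
standard convention of biochemical systems theory), so constant-flux
reactions are well defined, and zero activities are legal (complete
knockouts) while zero kinetic orders on zero concentrations are not an
error.

**Steady states** are found by damped Newton iteration on log-concentrations
`y = log x`, where the power law is linear (`w = alpha_hat + G y`) and the
constraint set is convex.  Rates are evaluated as `alpha * exp(G y)` rather
than `exp(alpha_hat + G y)`, so knocked-out reactions (alpha = 0) need no
special casing.  The Newton step is capped at 5 log-units and backtracked
(halving, 30 tries); the Jacobian `N diag(v) G` falls back to least squares
when singular.  Convergence is declared when the residual max-norm is below
`tol * max(basal flux scale, 1)` with `tol = 1e-10` by default.  If Newton
fails — typically when a knockout drives a pool to the zero boundary, which
log coordinates cannot represent — the engine integrates the ODE with BDF
from the basal state over a long horizon and polishes with Newton where
possible.  Concentrations below a floor of 1e-9 relative units are flagged
"effectively zero" rather than reported as exact zeros; fold changes against
an (effectively) zero reference are NaN, never infinity.  Non-convergence is
an explicit flag (or exception on request), never silent NaNs.

## Fuzzy objectives

Each objective carries a membership function with breakpoints
`x_LB <= x_basal_LB <= x_basal_UB <= x_UB`:

* **fuzzy-equal** (therapeutic, variation): 0 outside `[x_LB, x_UB]`, 1 on
  the basal plateau, strictly monotone on each side;
* **fuzzy-minimize** (adverse): 1 at or below basal, monotone down to 0 at
  `x_UB`.

Five monotone shape families are available (linear, exponential, hyperbolic,
inverse, piecewise-linear) as normalised maps of the linear branch
coordinate; **linear is the default and the only calibrated shape**.

**Calibration of the default breakpoints.**  The published VM50 treatment
table reports (fold change, grade) pairs for one therapeutic and twelve
adverse species under five conditions.  Inverting those pairs under a linear
rule gives a unique consistent breakpoint pattern: adverse memberships with
the plateau at basal and zero at 10x basal (`grade = (10 - fold)/9`), and a
therapeutic membership rising linearly from 0.1x basal to a degenerate
plateau at basal (`grade = (fold - 0.1)/0.9`), mirrored to 10x above.  63 of
65 cells are reproduced to within ±0.01; the two exceptions (the therapeutic
and dopaquinone cells of the COMT-inhibitor column) disagree with the rule
that fits every other cell and are treated as likely typographical errors —
they are excluded from the calibration check rather than force-fit.  These
breakpoints are defaults, not claims: every spec is overridable per
objective.  The variation-effect memberships (fuzzy-equal on activity fold,
plateau at basal, zero at folds 0.1 and 10) are **pure design choices** —
no published values constrain them — and are flagged as such here because
the absolute satisfaction grades of multi-objective optima depend on them.

The overall objective of a design selecting `k` targets is
`(Z_UB - k)/(Z_UB - 1) * lambda` with `lambda` the minimum grade.  `Z_UB`
defaults to 10 (configurable; no published value exists).

## Inner continuous solve

For a fixed target subset the solver maximizes `lambda` subject to
`grade_i >= lambda` over the selected activities (log-space, default fold
bounds [0.1, 10]) and controls (linear space, default [0, 10x basal]).  A
reduced-space formulation is used: the steady state is solved as an inner
equation at every trial point (warm-started from the previous solution), so
the kinetic equalities hold exactly and only the grade inequalities enter
the NLP.  The search combines (i) a coarse 9-point scan along each axis,
(ii) multistart SLSQP (basal point plus uniform draws, 8 starts by default)
on the explicit-lambda formulation, and (iii) a derivative-free Powell
polish of the max-min composite.  Ties between equal-lambda optima are
broken toward basal coordinate-wise (smallest total perturbation, matching
the variation-effect intent).  All randomness is seed-controlled; repeated
trial points are cached within a solve.  An infeasible subset (no converged
steady state, or a zero grade everywhere) is reported with `lambda = 0` and
a flag.

No global-optimality certificate is claimed; the accuracy contract, enforced
by tests, is agreement with dense grid scans (200 points per axis in 1-D,
60x60 in 2-D) to within 0.01 in lambda on synthetic problems.

## Outer evolutionary search

Target subsets are searched by a nested hybrid differential evolution:

* **coding** — a fixed-length integer vector of target indices; length K in
  fixed-cardinality mode, Z_UB slots with an explicit empty sentinel in free
  mode; duplicates are repaired by redraw.
* **operators** — rounded difference mutation (F = 0.5) with reflection into
  range, binomial crossover (CR = 0.8) with one guaranteed mutant slot.
* **selection** — two steps: one-to-one parent/trial competition, then a
  global best update; ties break toward fewer targets, then lexicographic.
* **migration** — when the fraction of distinct codes drops below 0.1, all
  but the incumbent are re-seeded.
* **acceleration** — a 1-swap hill climb on the incumbent each generation.
* **memoization / parallel contract** — subset evaluations are cached by
  sorted index set, and the inner seed of each subset is derived from the
  run seed and the subset itself, so results are independent of evaluation
  order and bitwise reproducible for a fixed seed.

Population 20 and 200 generations by default; the operator hyperparameters
are artifact choices (no published values exist) and are all configurable.
Combination mode forces a treatment preset into every candidate and searches
only complementary targets, with the preset levels co-optimized by the inner
solve; the preset alone is seeded into the initial population.

## Synthetic data

Two generators make every stage testable without any transcribed pathway:

* a **toy chain** (2 species, 3 reactions) with the closed-form steady state
  `x = ((a1/a2)^2, (a1/a3)^2)`, used as the solver oracle;
* **random consistent networks**: a main chain with influx, per-species
  balancing, extra random effluxes/transfers with fractional or negative
  modulating orders (magnitudes 0.05–1, the typical BST range), controls
  feeding random species.  A target steady state is drawn and rate constants
  are back-solved from assigned steady fluxes, so consistency holds to
  1e-10 by construction.  The terminal chain species doubles as a toxic
  byproduct so therapeutic and adverse objectives are both exercisable.
  Test problems apply a 60% deficiency to the head influx — a transfer-
  reaction deficiency is invisible downstream at steady state (the flux is
  pinned by the influx), so diseases are placed where they genuinely
  displace the objective species.

These networks share the GMA form and scale of real pathway models but not
their topology, conservation structure, or parameter correlations; passing
tests demonstrate the correctness of the machinery, not predictive validity
on any real pathway.

## The dopamine case and its stand-in network

The case-study module encodes the published *structure* of the presynaptic
dopamine problem: scenario names and deficiency percentages (VM50–VM95 on
VMAT2, TH50–TH100 on tyrosine hydroxylase), treatment presets (diet = u_t,
L-DOPA = u_l, dopamine agonists = u_d, COMT inhibitors = alpha_22/alpha_26,
MAO inhibitors = alpha_15/alpha_23/alpha_24), the objective sets (DA-e
therapeutic; six toxic species, four ROS, two RNS adverse), and the
reported-value reference table used for membership calibration.

The packaged network (`data/dopamine_synthetic.json`) is a **synthetic
stand-in**, because the source model's full kinetic parameterisation is
published only in supplementary material not redistributed here.  Anchored
to published facts: 34 species / 68 reactions / 3 controls; the tabulated
species at their published one-based indices (x5 dopaquinone … x32 NO2) and
healthy-state concentrations (DA-e = 400); the named enzyme roles (alpha_13
dopamine transporter, alpha_14 VMAT2, alpha_15/23/24 MAO, alpha_22/26 COMT,
alpha_3 TH as a deliberate assignment).  Filled in by design: the remaining
species identities and basal levels, the reaction topology (a curated
pathway core — synthesis, vesicular cycling, reuptake, oxidative
metabolism, glutathione and ROS/RNS chains — plus per-species degradation
effluxes), kinetic orders (0.2–0.9, one negative feedback of DA-i on TH),
and steady fluxes chosen so every species balances with strictly positive
rate constants.  The healthy state is therefore exact by construction, and
the stand-in reproduces the reported *qualitative* behaviour: DA-e falls
monotonically with VMAT2 severity, survives a complete TH knockout through
the L-DOPA route, is fully restored by downregulating the dopamine
transporter or by MAO inhibition under VM50.  Reported *quantitative* fold
changes and multi-objective optima (e.g. the untreated VM50 fold column,
DA-e = 245.7 under TH100, the 3.36 → 1.57 transporter optimum, and the
reported ranking of MAO over the transporter under all three objectives)
depend on the unpublished kinetic orders and are **not** reproduced; the
corresponding suite checks are kept and fail against the stand-in by
design, documenting the gap.  Loading refuses a model file with the wrong
dimensions or an inconsistent basal state.

## Numerical choices and limitations

* Newton tolerance 1e-10 relative (configurable); overflow in log-space
  rate evaluation clipped at exponent ±500.
* Membership evaluation is exact arithmetic on breakpoints; grades are
  reported to 3 decimals in tables, matching the published precision.
* The inner NLP is non-smooth at membership kinks and plateau edges; the
  Powell polish and axis scans exist precisely because SLSQP can stall
  there.
* Problem sizes in the shipped tests are deliberately small (5–8 species
  synthetic networks, single/pair targets, populations of 8, ≤ 12
  generations) so the full suite runs in minutes on one CPU; the defaults
  (population 20, 200 generations, 8 starts) are sized for real screening
  runs.
* No Michaelis–Menten or convenience kinetics, no parameter estimation, no
  stochastic simulation, no Pareto-front generation, no global MINLP
  certificates; "dose" means activity/control variation in relative units,
  with no pharmacokinetics and no clinical claims.
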