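# Methods

## Scope and model

`sustainflux` performs constraint-based analysis of stoichiometric
metabolic networks in which the objective function — and the statistic used
to rank strain designs — incorporates sustainability coefficients attached
to exchange fluxes and to produced biomass. The flux space is the standard
one: steady state `S v = 0` with per-reaction bounds, fluxes in
mmol · gDW⁻¹ · h⁻¹. Thermodynamic, kinetic, resource-allocation and
gene–protein–reaction constraints are out of scope; knockouts act at
reaction level by forcing bounds to zero (ids are retained so reports can
reference deleted reactions).

Two serializations round-trip to structurally equal models: SBML L3/FBC v2
(through libsbml) and a plain TSV dialect whose comment header carries the
metadata the column set cannot (model id, objective, metabolite
compartments and formulas). Exchange reactions are auto-detected as
single-metabolite reactions with coefficient −1 (secretion positive, uptake
negative). That shape test cannot distinguish an exchange from a biomass
drain, so SBML files persist the distinction explicitly: SBO:0000627 for
exchanges, SBO:0000629 for biomass, SBO:0000632 for non-boundary sinks,
plus an inactive FBC objective naming the biomass reaction.

## The sustainability indicator score

Every table row (one per exchange reaction, plus a reserved biomass key)
holds an economic coefficient (currency per unit flux; substrate prices act
on negative uptake fluxes, product prices on positive secretion fluxes,
waste-management costs are entered as negative prices) and one coefficient
per environmental or societal category. Categories live in a
user-extensible registry that fixes their pillar and whether they are a
*harm* (impact potentials, toxicity, land occupation) or a *benefit*
(market value, jobs created, social acceptance). The sign convention makes
larger scores more sustainable: benefits positive, harms negative; loaders
warn when a known harm category carries a positive coefficient.

The score of a flux state is

* per-(exchange, category) contribution `s_{j,c} · g_j(v_j) · u_c / r_c`,
* pillar subtotals E, V, C as sums of their contributions,
* total `S = w̄_econ E + w̄_env V + w̄_soc C` with pillar weights
  renormalized to sum to one.

Normalization references `r_c` (category-unit per common-scale unit,
strictly positive, default 1.0) are user-supplied rather than data-driven
so scores are reproducible and dataset-independent. Sub-weights `u_c`
default to 1.0. A category configured in neither the weight scheme nor the
registry is rejected by name — that is almost always a typo in the table.

`g_j` is the per-row flux transfer: identity by default, a slope for linear
rescaling, or a continuous piecewise-linear function (strictly increasing
breakpoint abscissae, linear extrapolation beyond the ends) for saturating
or threshold-like responses. Piecewise rows are *evaluation-only*: they are
rejected from `linearize_objective` because a piecewise objective is not
generally concave and would silently turn the LP into a non-convex problem.
Post-hoc scoring and ranking support them fully.

Small fluxes are lumped: exchanges with |v| below the threshold ε
(default 10⁻⁶ flux units) contribute nothing and are reported with the
contribution that was neglected. The total neglected mass is bounded by
ε · Σ_j |composite coefficient_j|, so the default ε is far below any
quantity of interest on desk-scale fixtures and typical GSMM fluxes alike.

## Optimization

With all-linear rows the score is a dot product, so maximizing it is an
LP over the flux polytope; growth enters as `v_biomass ≥ f · μ_max` with
μ_max freshly recomputed per call (a fraction travels across chassis,
an absolute rate does not). The default fraction is 0.1 when maximizing
the score and 1.0 when assessing score ranges at the metabolic optimum.

The LP backend sits behind a small contract (any solver returning optimal
basic solutions at tight primal tolerance; selected by the `solver` config
key) and is HiGHS via `scipy.optimize.linprog`, which is deterministic for
a fixed model. Returned optima are polished by a least-squares projection
onto `{S v = 0}`; the projection moves the solution by at most the solver's
feasibility residual and brings `max |S v|` to machine precision (the test
corpus observes ≤ 10⁻¹³). Bounds may consequently be violated by amounts of
the same order, far inside every stated tolerance.

Alternative optima are embraced, not hidden: `fba` returns *one* optimal
vertex and no scientific claim is attached to which one. Claims about
individual fluxes go through `fva` (min/max flux subject to the objective
held at a fraction of its fresh optimum; at fraction 0 the objective
constraint is dropped entirely), and claims about the score go through
`sustainability_range` — an FVA on the score itself. Ranges only widen as
the growth fraction decreases, and any growth-optimal state scores inside
them. `score_tradeoff_curve` sweeps ascending growth fractions; feasible
scores are non-increasing along the curve because the feasible region only
shrinks. Infeasible points are recorded and the sweep continues.

`reduce_variability` narrows the score range below a tolerance by a greedy
single-move loop over candidate deletions and media tightenings: each round
applies the move that most reduces the width while keeping μ_max at or
above the configured fraction of the *original* μ_max. Strict improvement
is required, so termination is guaranteed; exhausted or useless candidate
sets return the best-effort design with a `stalled` flag. Ties prefer
deletions over media edits, then the lexicographically first move — runs
are deterministic. Greedy search is transparent and is validated against
exhaustive evaluation on the small fixtures; it is not guaranteed optimal
on larger candidate sets.

## Design enumeration and ranking

Designs (deletion subsets × insertion subsets up to the size caps) are
enumerated exhaustively in deterministic order, wild type first; spaces
larger than the cap (default 10 000) are refused outright rather than
sampled. Each design is evaluated in isolation: apply, recompute μ_max,
declare infeasible when the model does not solve or does not grow, else
compute the score interval at the required growth fraction. Failures are
recorded in the result, never raised mid-batch.

Ranking collapses the interval to a statistic — by default the pessimistic
lower bound S_min, because under alternative optima the realized flux
distribution is unknown and the worst case is the defensible guarantee;
optimistic and midpoint statistics are available. Ties break by fewer total
interventions, then narrower interval, then design string; infeasible
designs sort last. Results evaluated under different tables or weight
schemes carry different config hashes and refuse to be ranked together.
Cross-chassis ranking therefore requires a shared table and weights;
chassis differences enter only through their networks.

## Synthetic data and the oracle

The toy fixtures are constructed exactly (no randomness) and sized for
hand-derivation: a 10-unit substrate uptake, a clean product route, a
branch that is either product-lossy (TOY-A) or yield-equivalent but
waste-producing (TOY-A2), and, in TOY-B, a biomass drain competing with the
product for the common precursor. The canonical economic table (substrate
0.2, product 1.0, waste −0.1) makes every headline number a two-line
calculation: product optimum 10, score optimum 8.0, score range (7.0, 8.0)
collapsing to 8.0 when the branch is deleted, trade-off curve 8 − 10·f on
TOY-B. Secretions use a finite bound of 1000 rather than literal infinity
so the enumeration oracle below applies; the optima bind at the uptake cap
and are unaffected.

Random models are built by planting a feasible uptake → conversion chain →
secretion path and adding random side reactions (small integer or half
coefficients, finite bounds, occasional extra secretions, occasional
reversibility). Feasibility and a strictly positive planted-secretion
optimum hold by construction, so no rejection sampling is needed and every
seed is usable; a single integer seed drives each generator with no global
state. Random tables draw economics uniformly and harm categories
non-positive. What the generator does *not* emulate about real GSMMs:
cofactor and energy metabolism, compartments, realistic degeneracy
structure, blocked reactions, and network scale — passing tests demonstrate
correctness of the algorithms on well-posed networks, not predictive
accuracy on any organism.

The independent oracle enumerates basic solutions of
`{S v = 0, lb ≤ v ≤ ub}`: every choice of rank(S) linearly independent
basic columns with the non-basic fluxes pinned at either bound, feasibility
checked at a scaled tolerance of 10⁻⁷. For bounded polytopes this decides
feasibility and optimality exactly, independent of any LP library; it is
capped at 10 reactions and is the reference for the solver-agreement tests
(100 seeded models, agreement within 10⁻⁶). A second, fully external
cross-check reads the package's SBML output with cobrapy and reproduces the
optima with its own solver stack.

## Numerical choices and limitations

* LP tolerances: primal 10⁻¹⁰, dual 10⁻⁹; steady-state projection after
  every solve; FVA/score-range assertions use 10⁻⁶–10⁻⁷ slack.
* Growth is declared absent below 10⁻⁹ flux units when deciding design
  feasibility.
* Degenerate inputs: empty models are valid and report infeasibility at
  solve time; a zero-bound model solves to the zero flux vector; fraction 0
  drops the objective constraint in FVA.
* Weighted-sum scalarization only — no Pareto-front enumeration over the
  three pillars, and no mechanism for non-linear interactions *between*
  sustainability goals (per-flux nonlinearity is supported, cross-goal
  nonlinearity is not).
* No MILP: design search is explicit enumeration with a cap; no
  genetic/ML-guided search. No computation of the LCA coefficients
  themselves — they are inputs, obtained elsewhere.
* Societal coefficients in particular are scarce for emerging bioprocesses;
  the toolkit treats them as given numbers and offers no imputation.
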