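# sustainflux

Sustainability-weighted constraint-based analysis of metabolic models.

Strain designs in industrial biotechnology are usually screened by growth
rate, product flux or yield. Economic, environmental and societal
consequences of the process — substrate costs, waste-management burdens,
global-warming or toxicity potentials, jobs created, social acceptance —
enter the picture only much later, at techno-economic or life-cycle
assessment stage, when the organism and pathway are already fixed.
`sustainflux` moves that assessment to the front of the design loop: it
attaches per-unit sustainability coefficients to every exchange flux (and
to produced biomass) of a stoichiometric model, turns them into an
objective for flux balance analysis, and ranks candidate knockout/insertion
designs by the resulting score. It is aimed at metabolic engineers and
modellers working with genome-scale metabolic models in the usual
COBRA-style conventions.

## The model

A metabolic network with stoichiometric matrix **S** admits the steady-state
flux space

```
F = { v : S v = 0,  lb ≤ v ≤ ub }        (fluxes in mmol · gDW⁻¹ · h⁻¹)
```

Exchange reactions carry one metabolite with coefficient −1, so negative
flux is uptake and positive flux is secretion. Each exchange *j* (and
biomass) has a row of coefficients *s*<sub>j,c</sub> over categories *c*
grouped into three pillars — economic (prices, costs), environmental
(LCA-style impact potentials: global warming, eutrophication, …) and
societal (human toxicity, jobs created, …). The sustainability indicator
score of a flux state *v* is the weighted sum

```
Score(v) = w̄_econ · E + w̄_env · V + w̄_soc · C ,
E|V|C    = Σ_{j,c in pillar}  s_{j,c} · g_j(v_j) · u_c / r_c
```

with renormalized pillar weights w̄, per-category sub-weights *u*,
normalization references *r* that bring the categories onto one scale, and
a per-row flux transfer *g* (identity unless a nonlinear response is
declared). Harm categories carry negative coefficients, benefits positive
ones, so a larger score is always more sustainable. With all-linear rows
the score is a plain dot product with the flux vector and can itself be the
LP objective; growth enters as a constraint `v_biomass ≥ f · μ_max`.

Because flux optima are degenerate, the toolkit reports score *ranges*
(flux variability analysis applied to the score), ranks designs by the
pessimistic lower bound by default, and can greedily delete reactions or
tighten media bounds until the score range is acceptably narrow.

## Worked example

`sustainflux fixtures out/` writes the built-in toy fixtures. TOY-A2 takes
up to 10 units of substrate A (price 0.2), converts it via B either cleanly
to product P (price 1.0) or through a branch that co-secretes waste W
(management cost 0.1). Both routes give the same product yield, so classic
FBA cannot tell them apart — the economics can:

```
$ sustainflux sme-range out/TOY-A2.xml out/economic_table.csv \
      --weights out/economic_weights.json --growth-fraction 1 --no-timestamp
{
  "growth_fraction": 1.0,
  "s_max": 8.0,
  "s_min": 7.0,
  "width": 1.0
}
```

At the product optimum (10 units of P, −2 of substrate cost) the realized
score can be anywhere between 7.0 (all flux through the wasteful branch,
10 × 0.1 disposal cost) and 8.0 (clean route only). Screening single
deletions shows how to close that gap:

```
$ sustainflux rank out/economic_table.csv out/TOY-A2.xml \
      --candidates R2,R3 --max-deletions 1 --weights out/economic_weights.json
rank,chassis,design,deletions,insertions,mu_max,s_min,s_max,statistic,feasible
1,TOY_A2,del:R3,1,0,10,8,8,8,true
2,TOY_A2,wild-type,0,0,10,7,8,7,true
3,TOY_A2,del:R2,1,0,10,7,7,7,true
```

Deleting the waste branch R3 pins the score at 8.0 and tops the
leaderboard; deleting the clean route R2 instead locks in the worst case
7.0. The same operations are available as library calls
(`optimize_sustainability`, `sustainability_range`, `rank_designs`, …).

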