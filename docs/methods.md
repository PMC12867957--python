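# Methods

## Scope and system boundary

The package estimates human-health burdens (DALYs) associated with annual
mass flows of municipal plastics through their lifecycle — primary
production, collection and sorting, mechanical (closed/open loop) and
chemical recycling, incineration, engineered landfill, dumpsites, open
burning, littering and aquatic/terrestrial pollution — across eight
geographical archetypes (World Bank income level x urban/rural), three
plastics categories (rigid monomaterials, flexible monomaterials,
multilayer/multimaterials) and six policy scenarios over 2016–2040.
Product manufacturing and consumer use sit outside the flow model and
therefore outside the system boundary. Littering, informal collection
and organized beach clean-ups are modelled as explicit zero-effect
processes (human energy only, empty inventories): mass still routes
through them, so mass balance and downstream transfers are preserved,
but they contribute no emissions. Microplastic/nanoplastic exposure and
use-phase chemical migration are not modelled; the burden pathways are
greenhouse gases, air pollutants and chemical emissions.

## Inventory model

Unit processes exchange flows linearly; the inventory for a demand `f` is
`g = B (I − A)^-1 f`, solved by dense LU factorization (the modelled
systems stay below a few hundred processes, so sparse solvers are
unnecessary). Solvability is guarded by a power-iteration estimate of the
spectral radius of |A| (200 iterations; reject at >= 0.999). Allocation
follows the cut-off convention: inputs flagged as cut-off get an empty
technosphere column and thus zero upstream burden — asserted by tests
that vary a cut-off input's amount and require identical solutions.

Every emission row carries a short/long term label from compilation
through the ledger; the split is only merged at reporting, because the
long-term share (landfill methane, leachate metals, degradation in the
environment) drives interpretation even when totals are identical.
Annual attribution books all current *and future* emissions of one
year's flows to that year: an annual burden is everything a single year
of the system commits the future to, over a 100-year horizon.

Electricity regionalization replaces a process's aggregate grid input by
technology-specific inputs weighted by the archetype's generation mix;
total kWh is conserved exactly (any floating residue is assigned to the
largest-share technology). Units are declared per process and never
converted silently; mismatches are hard errors.

## Impact assessment

Characterization is a linear map from (substance, compartment) emissions
to eight health midpoints, then to DALYs via non-negative
midpoint-to-endpoint factors (hierarchic perspective, 100-year horizon).
Negative *characterized values* are legitimate — avoided-burden credits
flow through as negative emissions — whereas a negative *endpoint
factor* is rejected as a data error. Substances without factors are
never dropped silently: they are logged with their emitted mass, because
a silent zero would be indistinguishable from a genuine zero-effect
process. The shipped factor table is illustrative: endpoint conversions
use published hierarchic-perspective magnitudes (e.g. 9.28e-7 DALY per
kg CO2-eq; 6.29e-4 DALY per kg PM2.5-eq) and GWP100 of 29.8 for fossil
methane, but midpoint factors for the toxicity pathways are simplified
single-substance proxies. Exact-reproduction runs supply a full table
through the CSV loader.

## Building blocks

A unit impact factor is the DALY burden of 1 Mt of a plastics category
through one stage in one archetype (or one packaging service-year of a
reuse system), computed by chaining regionalization, the inventory
solve and characterization. Category inventories are polymer-share
weighted combinations of per-polymer stage inventories; polymer weights
come from product compositions (each product a mix of PET, HDPE, LDPE,
PP, PS, PVC), static across years and stages. The multilayer category
routes proportionally more PVC than the others, which concentrates
chlorinated/toxic emissions there.

Reusable-glass systems provide one packaging service-year: container
production and end-of-life are amortized over the container lifespan,
washing scales with annual uses split between hand and machine washing
per archetype, and the door-to-door refill system adds distribution
transport and uses industrial washing. Defaults (0.35 kg container, 200
uses lifespan, 300 fills/year for household reuse; 0.5 kg, 300 uses,
industrial washing and 3 tkm/year for refill) are literature-plausible
illustrative values chosen once; with them, household washing carries
94–98% of the consumer system's burden depending on archetype washing
practices. Substitute end-of-life defaults take the lower-impact
variants (75% paper recycling, 100% polylactide incineration) and are
config-overridable.

## Coupling, credits, substitution

Each flow record is multiplied by its unit factor; a missing factor key
is a hard error (a silent zero would corrupt totals unnoticed). Credits
are stored as records with *negative effective mass* against the
avoided material's production factor: closed-loop recycling averts the
same category's primary production (yield 0.8), open-loop averts a
lower-grade polymer (0.7) — not the donor polymer, since open-loop
recyclate displaces production in other sectors — and pyrolysis averts
fuel production (0.6). Because every ledger row then satisfies
`dalys = mass x factor`, all breakdowns (midpoint, stage, archetype,
material, substance, direction) are exact linear re-aggregations, and
the credit magnitude can never exceed the avoided production burden at
equal mass (yield <= 1). Reports show induced and avoided effects
separately plus the net, so per-process charts appear larger than net
midpoint totals by construction.

Substitution converts displaced plastic mass into substitute flows:
1:1 by mass for paper, coated paper and polylactide (sensitivity ranges
0.4–9.0 for paper-based, 0.8–1.4 for compostables), and via a packaging
intensity of 2.5e7 service-years per Mt for the reuse systems. The
displaced plastics' own lifecycle records are absent from the flow
dataset by construction, so no double counting arises.

Printed values are rounded to two significant figures; all arithmetic
is unrounded, so printed row totals can disagree with printed sums —
tests always compare unrounded values.

## Uncertainty and sensitivity

Flow uncertainty is propagated by running the full pipeline per Monte
Carlo replicate and summarizing totals as the arithmetic mean with
empirical percentile intervals (2.5/97.5 at the default 95% level); the
method is recorded in output metadata. Percentile intervals were chosen
over normal approximations because replicate distributions are
lognormal-skewed; they are invariant to replicate ordering. Because the
whole pipeline (credits included) is linear in flows, the replicate
mean equals the pipeline applied to mean flows — asserted in tests.
Replicates supplied with real data are consumed as given; synthetic
replicates are seeded lognormal perturbations. The substitution sweep
evaluates the pipeline at the ratio-range endpoints (optionally a
grid); with positive substitute factors totals are monotone in the
ratio, so the endpoints bound the envelope. Characterization-factor and
inventory uncertainty are not propagated (no defensible joint
distribution exists for them here).

## Synthetic world

The generator emulates the statistical structure of the real inputs
with known ground truth:

- **Process networks** are acyclic, depth <= 3 (stage process ->
  electricity technologies / diesel combustion -> fuel supplies), so an
  independent expansion oracle computes exact unit factors; pipeline
  factors must recover them to 1e-9. Per-polymer emission intensities
  vary by a seeded +-15% around stage templates whose magnitudes are
  realistic orders (e.g. ~2.3 t CO2 direct + ~1 MWh electricity per t
  at production; heavily particulate- and dioxin-laden open burning).
- **Electricity mixes** have fossil shares falling with income rank
  (0.80 low-income rural down to 0.42 high-income urban), making the
  same process strictly worse per Mt in fossil-heavier archetypes.
- **Flows** start from 220 Mt global demand in 2016 split across
  archetypes and categories, grow at 3.2%/yr under business as usual,
  and route through collection/sorting/disposal with archetype-specific
  shares. Scenario levers (production cuts, substitution shares,
  collection/recycling/incineration boosts) ramp linearly from 2020 to
  2040 — an explicit approximation of market-penetration lags; the
  system-change scenario's collection expansion ramps 2030–2040 to
  reflect infrastructure build-out time. Mass balance holds at every
  node, year, scenario and replicate by construction and is verified by
  an independent accounting oracle.
- **Replicates** (default 300; the full-world
  test and acceptance summaries use 50 to keep runtimes in seconds)
  apply independent lognormal multipliers (sigma = 0.04) at each
  production source node and propagate them through fixed routing
  shares, so conservation survives perturbation.
- The **shipped configuration** is calibrated to the documented
  qualitative structure only: production rank-1 and open burning rank-2
  in BAU; cumulative burdens ordered BAU > current commitments >
  collect-and-dispose > recycling > reduce-and-substitute > system
  change; demand-reduction scenarios peaking 2030–2032 then declining.
  Absolute magnitudes are synthetic and deliberately not fitted to any
  external dataset — passing tests demonstrate pipeline correctness and
  structural fidelity, not real-world burden estimates. What the
  generator does **not** emulate: correlated replicate noise across
  nodes, climatic adjustment of inventories, time-varying polymer
  composition, and appendix-level product-to-polymer mappings.

## Numerical choices and degenerate inputs

- Spectral-radius guard: power iteration, 200 iterations, reject >= 0.999.
- Share-type invariants (mixes, compositions, washing, end-of-life)
  tolerate 1e-9 absolute deviation from 1.
- Closure checks on aggregation use 1e-9 relative tolerance on the net
  total; factor-table midpoint closure likewise.
- Zero demand yields zero emissions; zero flows yield an all-zero
  result bundle with undefined (NaN) percent reductions rather than an
  error.
- Ties in contribution ranking follow pandas stable sort; sub-threshold
  entries pool into an explicit `other` row so shares always sum to 100.

## Known limitations

Unit factors are static 2016-era snapshots: background electricity and
technology do not decarbonize over the projection, which overstates
late-period burdens for electricity-intensive stages. Substitution uses
mass/service ratios, not full product redesign. The toxicity midpoints
ride on proxy substances rather than a full chemical inventory — real
plastics chemistry is far broader than any inventory discloses. Flow
trajectories are inputs: the package does not re-derive policy lever
dynamics, only applies their mass consequences.
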