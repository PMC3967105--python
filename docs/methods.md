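# Methods

## Model and scoring LP

All computations use standard flux balance analysis on a
constraint-based model: steady state `S·v = 0`, per-reaction bounds,
and maximization of the biomass reaction.  The environment fixes the
substrate (glucose) uptake at GUR = 10 mmol/gDW/h, oxygen at
OUR = 5 mmol/gDW/h (microaerobic — deliberately too little oxygen to
respire all glycolytic NADH, which is the regime in which by-product
coupling is strongest), a non-growth ATP maintenance equality of
8.39 mmol/gDW/h, and free bidirectional exchange for small diffusible
metabolites (CO₂, NH₄⁺, H₂O, …).  All other nutrient uptakes are
closed; secretion stays open.  Infinite bounds are encoded as
±1000 mmol/gDW/h so that the big-M reformulation of the bilevel stage
is well posed.

The screening score of a knockout set is the **shadow price of a
forced production flux**: add the equality `v_target = b_target` with
`b_target = 1e-5` mmol/gDW/h and a growth floor `v_growth ≥ 0.05` /h to
the biomass-maximizing LP, knock out the set's reactions, and read the
dual value of the production constraint.  Interpretation: the slope of
the optimal-growth value function Φ(b) at the origin.  The tiny
`b_target` keeps the solution on the first linear segment of Φ while
breaking the degeneracy of alternative optima at b = 0 exactly; Φ is
assumed linear on [0, b_target] (a breakpoint below 1e-5 would bias the
score; `finite_difference_score` at b_target/2 and 2·b_target serves as
a diagnostic).  Classification uses a zero tolerance of 1e-9 on the
dual: below −1e-9 negative, above +1e-9 positive, otherwise zero.  An
infeasible LP — the strain cannot hold the growth floor while producing
— is its own class and removes the set from further search, on the
rationale that strains growing slower than 0.05 /h are impractical to
construct.

LP duals are non-unique under degeneracy.  The package uses the
solver's returned dual as-is; the independent arbiter in all tests is
the finite-difference slope (Φ(δ) − Φ(0))/δ, and dual-vs-slope
comparisons are restricted to cases certified non-degenerate by local
linearity of Φ (equal chord slopes over [0, δ] and [0, 2δ]; since Φ is
concave this implies a unique dual on the segment).  This caveat is the
main reproducibility risk for genome-scale candidate *counts*: two
LP solvers may classify a handful of borderline sets differently.

A solver note: optlang's GLPK interface retries non-optimal solves
through the GLPK presolver (`presolve="auto"`), whose failure path can
report an infeasible LP as optimal with an all-zero solution.  Because
infeasible scoring LPs carry meaning here, the package pins
`presolve=False` on every model it solves.

## Lexicographic production and yields

Reported production fluxes are **inner-optimistic**: first maximize
growth, then fix growth at its optimum and maximize target export
(avoiding arbitrary alternative optima).  Growth is refixed with a
1e-12 relative slack — GLPK restarts from the optimal basis, so this
never causes spurious infeasibility, and the slack leaks less than
1e-10 into the secondary objective, keeping the toy-model assertions at
1e-9 honest.  The theoretical maximum yield (TMY) is the LP maximum of
target export with no growth-optimality requirement, divided by the
substrate uptake at that optimum; yields are reported as fractions of
TMY (and g/g where formula weights are annotated).

## Reduction

Three structural steps shrink the knockout search space while
provably preserving every optimum:

1. **Blocked-reaction removal** — reactions whose flux-variability
   range is within 1e-9 of zero are deleted.  FVA is run *without*
   constraining growth to its optimum and without the growth floor:
   reactions that only carry flux away from the wild-type optimum must
   survive, or knockout phenotypes would change.  (Both switches are
   exposed.)
2. **Pathway lumping** — a metabolite appearing in exactly two
   non-boundary reactions pins their flux ratio; the pair is merged
   with rescaled stoichiometry and intersected bounds, iterated to a
   fixpoint so longer chains collapse.  Scale factors are recorded so
   lumped fluxes map back to member fluxes.  Adjacencies through common
   cofactors (ATP, NAD(H), H₂O, … — configurable list) are skipped, as
   are merges that would join a gene-encoded reaction with a
   spontaneous one or touch biomass/maintenance/exporter plumbing:
   lumping must never blur what a knockout means.
3. **Gene-set grouping** — reactions whose gene rules have exactly the
   same disjunctive normal form (set of alternative gene sets) cannot
   be disrupted independently and form one knockout unit.  Partial
   overlap does not group.  Units containing a protected gene
   (default *gapA*, *pgk*, *eno*, *gpmA*, glycolytic genes essential in
   vivo) are kept but never offered as knockouts, as are exchanges, the
   biomass reaction, ATP maintenance, target exporters and spontaneous
   reactions.

Equivalence — identical biomass and lexicographic production optima
before and after reduction, per knockout unit mapped back to original
reactions — is asserted to 1e-6 in the test suite on every fixture.

## Beam search

Screening is a deterministic beam search over knockout units.  The
seed generation scores all sets of size `start_depth` (default 1;
2 reproduces the all-pairs variant).  Each generation unions every
parent with every absent unit (≤ P×N children), discards children that
are infeasible or did not *strictly* improve on their parent
(ε = 1e-9; plateaus would otherwise cycle), pools survivors globally,
deduplicates them as unordered sets, moves children whose score reached
≥ 0 into the candidate store (leaving the beam), and keeps the top
P = N children by score, ties broken by the lexicographic order of
sorted unit ids.  Iteration stops when the beam empties or sets reach
`max_knockouts` = 25.  Scores are cached by canonical set, so shared
children across parents cost one LP.  Two runs on identical input are
bit-identical.

The strict-increase rule has a knowable blind spot: a minimal
producing set whose every one-knockout path contains a score plateau
(e.g. two redundant by-product vents that must *both* fall before the
score moves) can never be assembled.  This is a property of the method,
not of the implementation.

## Candidate-restricted OptKnock

The refinement stage solves the bilevel program — outer: choose ≤ K
units to delete, maximizing target export; inner: the cell maximizes
growth subject to those deletions and the growth floor — as a single
MILP.  Inner optimality is imposed by strong duality: primal
feasibility, dual feasibility, and `dual objective ≤ primal growth`
(weak duality supplies the reverse), with binary deletion variables
switching off both primal bounds and the corresponding dual terms
through big-M linearizations (M = 1000, matching the bound encoding;
dual variables of knockable bounds are capped at the same M).  The
outer objective then automatically picks, among inner-optimal flux
distributions, the one maximizing production — the same
inner-optimistic convention as the lexicographic LP.  The returned set
is audited by an ordinary lexicographic FBA solve, which provides the
reported growth and flux.

A pure-enumeration backend (lexicographic FBA over every subset of
size ≤ K) is selected automatically whenever the subset count is at
most 10,000; it doubles as the exactness oracle for the MILP in the
test suite.  Candidate units entering the MILP are the `top_n = 30`
units ranked by the best lexicographic production flux among the
screened candidate sets containing them (ties by unit id) — one
consistent reading of "the units contributing to the highest yields",
isolated in `select_candidate_reactions`.

## Strategy similarity

Knockout strategies of different targets are compared by the
membership Jaccard coefficient J = |A∩B|/|A∪B| of their knockout
sets (by default the OptKnock-refined best set; configurable to the
minimal screened candidate).  1 − J is a metric, and agglomerative
clustering (UPGMA by default; single/complete available — the choice
is not dictated by anything in the problem) produces a dendrogram
serialized as Newick with branch lengths equal to merge-height
differences.  A per-cluster report flags units present in > 90% of a
cluster's sets as that cluster's shared strategy.  The cut height for
flat clusters is a free parameter.

## Toy fixtures and oracles

`make_toy1` is the canonical hand-checkable network: substrate A
(uptake ≤ 10) feeds biomass through B via `R1` (emitting 2 NADH per A);
NADH drains through a fermentative vent `R2` or oxygen-limited
respiration `R3` (O₂ ≤ 5); the target route `R5` consumes A + NADH.
All optima are small rationals, so tests assert to 1e-9: wild-type
growth 10, scores −1 (wild type) and +1/2 (ΔR2), coupled optimum
(20/3, 10/3), TMY 20/3.

`make_random_toy` draws seeded variants of the same architecture:
1–4 parallel substrate→biomass branches with NADH stoichiometry in
{1, 2}, one or two vents, respiration, a target route with randomized
NADH demand, optionally a two-step linear chain (exercising lumping)
and a dead-end reaction (exercising blocked removal).  Integer
coefficients in {1, 2} keep optima rational and LP degeneracy rare.
Each draw is certified at generation time, with the enumeration and
finite-difference oracles only (never with the beam search itself):
the model is feasible with positive growth; some knockout set of ≤ 3
units couples production; and every oracle-minimal producing set has a
knockout ordering along which the score strictly increases.  The last
certificate encodes the reachability assumption of iterative screening
described above — fixtures violating it would make the screen's
completeness test fail for reasons inherent to the method.  Draws
failing certification are resampled from sub-seeds (seed, attempt), so
a spec seed still yields a deterministic model.

What the fixtures do *not* emulate: genome-scale redundancy
(isozymes, parallel cofactor pools, hundreds of exchange reactions),
reversible internal reactions, compartments beyond cytosol, and
realistic biomass composition.  Passing the fixture suite therefore
demonstrates correctness of the algorithms and their implementations,
not the biological counts a genome-scale run would produce; those
additionally inherit the dual-degeneracy caveat above.

## Problem sizes in tests and the acceptance script

The bundled suites run entirely on fixtures: 20 certified random toys
(≤ 12 knockable units) for the screening, MILP and reduction checks,
and 50 toys × all single knockouts for the dual-vs-slope comparison
(~360 certified cases).  `scripts/acceptance.py --seed S` regenerates
both batches from sub-seeds of S and recomputes every headline
quantity from scratch in well under a minute on one CPU.  Genome-scale
runs use the same code paths (`read_model` on SBML/FBC or BiGG JSON,
then the identical pipeline); with P = N beam width they are
compute-days per target list, which is why no genome-scale assertion is
part of the test suite.

## Known limitations

- Plateau-shielded knockout sets are invisible to the strict-increase
  beam (inherent to the method; documented above).
- Duals under degeneracy are solver-dependent; candidate counts on
  large models may vary across solvers at the margin.
- Lumping handles reversible members by bound intersection but does
  not attempt global re-orientation of reversible subnetworks; on
  genome-scale models some lumpable chains through reversible
  reactions are left unlumped (conservative, never incorrect).
- The MILP's dual big-M (1000) is heuristic, as in all practical
  OptKnock implementations; the enumeration backend and the post-solve
  FBA audit guard against big-M artifacts at fixture scale.
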