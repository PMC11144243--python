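# Methods

## Community model construction

A strain model is a stoichiometric matrix S^k with flux bounds and a single
biomass objective; exchange reactions are written `M_e →` with one
extracellular reactant, so positive flux is secretion and negative flux is
uptake.  "Unbounded" is represented by the conventional numeric cap of
±1000 mmol·gDW⁻¹·h⁻¹, which keeps every linear program bounded.

`build_community` copies each member verbatim under a `<strain>__`
namespace, so no reaction of one member can reference another member's
metabolites except through the shared pool.  Extracellular metabolites are
matched across strains by base id after stripping the compartment suffix
(`glc_e`, `glc_com` → `glc`); this is a convention of this package — curated
model collections reconciled across databases may need an explicit id map
first.  Every shared metabolite receives one community import reaction IP
(`→ M_com`, bounded above by the active medium) and one export reaction OP
(`M_com →`, bounded [0, cap]).  The steady-state row of each pool metabolite
is then literally the community balance Σ_k v[ex]_a^k + IP_a − OP_a = 0, so
pool conservation is enforced by the LP itself rather than checked after the
fact.

Media are availability tables mapping base metabolite ids to maximal import
rates.  Mineral ions, water, protons and oxygen default to unconstrained
import unless a medium overrides them; carbon and nitrogen sources must be
granted explicitly, mirroring minimal-mineral-medium practice.  In substrate
scans the availability value is used directly as the import bound — the
minimal assumption in the absence of an uptake-kinetics law.

## Abundance scenarios and the community objective

The community objective is max Σ_k c^k·v_biomass^k with uniform weights
c^k = 1 by default.  Because the framework is steady-state, "abundance" is
interpreted on the biomass fluxes (h⁻¹), the only flux-level reading
available.  The four scenarios are encoded as the simplest linear
constraints consistent with their descriptions:

* **equal** — chained equalities v_biomass^j = v_biomass^k;
* **free** — no coupling; any member may sit at zero;
* **target** — objective weights are the indicator of the target member;
* **fixed (w)** — growth rates locked to proportions via pairwise rows
  w_j·v^k = w_k·v^j (zero-weight members pinned to zero), with the common
  growth rate μ = v^k/w_k as the objective.  This avoids an auxiliary LP
  variable while being algebraically identical to v^k = w_k·μ.

Useful algebraic consequences, asserted by the test suite: a one-member
community is equivalent to single-strain FBA; *free* is a relaxation of
*equal*; and under *free*, adding a strain can never decrease the optimum
(the old solution extends with the newcomer at zero flux).

## Solving

LPs are assembled sparsely and solved with HiGHS via scipy, single-threaded
with presolve and a primal feasibility tolerance of 1e-10, so repeated runs
reproduce fluxes bit-for-bit and steady-state residuals stay far below the
1e-9 contract.  Solver statuses are reported faithfully; screens record
per-row failures as data instead of raising.

pFBA is the standard two-stage formulation: stage 1 fixes the objective at
γ×optimum (as an inequality with 1e-7 slack, for numerical robustness;
γ = 1 by default), stage 2 minimizes Σ|v| by non-negative flux splitting.
Descriptions of the method sometimes speak of minimizing nutrient-exchange
fluxes only; total-flux minimization subsumes that (uptakes are part of the
sum) and is the established definition, so it is the default, with
`minimize="exchange"` available to restrict the stage-2 objective to
boundary fluxes, and the summed community import flux reported on every
solution either way.  FVA minimizes and maximizes each requested flux
subject to objective ≥ γ×optimum.  Reported flux vectors are pFBA
solutions; uniqueness is never claimed — LP degeneracy is intrinsic, which
is exactly why edge robustness tagging exists (below).

## Cross-feeding inference

From an optimal community solution, the exchange profile keeps link fluxes
with |v| above the reporting threshold ε = 1e-6 mmol·gDW⁻¹·h⁻¹ (the solver
noise floor).  A directed edge producer→metabolite→consumer is emitted when
one member secretes and another consumes the same pool metabolite in the
same solution; with several producers/consumers the transferred rate is
apportioned proportionally to each party's flux magnitude, a declared
convention since flux balance cannot identify pairings.  Medium→consumer
supply edges are kept in a separate list so interspecies claims are never
conflated with imports.  Each edge is tagged **stable** if FVA at objective
fraction γ keeps the producer's secretion strictly positive and the
consumer's uptake strictly negative, otherwise **variable** — alternate
optima can then be recognized instead of silently reported as facts.

## Essential and helpful reactions; synthetic cells

A target function is made explicit — community biomass, one member's
biomass, or a designated reaction flux (e.g. pollutant import at the pool) —
because "essential for degradation" is ambiguous between these readings.
A reaction is **essential** iff its single knockout drives the function
optimum below max(1e-6 × intact optimum, 1e-9).  The default candidate set
is the FVA pre-filter at γ (only reactions that no γ-optimal solution can
idle), and every candidate is still confirmed by knockout, so the result
equals exhaustive enumeration; the tests assert this equality on every
fixture.  Essentiality is single-knockout by design — set-wise minimal cuts
are out of scope.

**Helpful** reactions are found greedily, one at a time, against the current
chassis state: each donor reaction absent from the chassis is transplanted
together with its transport prerequisites (the fixpoint closure of donor
transports/exchanges over the reaction's metabolites), and is reported when
the relative gain (F_new − F_base)/max(F_base, ε) exceeds δ = 1% — taking
the chassis state as an argument keeps the greedy sequence reproducible.

Transplants match metabolites by id, create missing ones with the donor's
compartment and formula, skip stoichiometric duplicates, rename id
collisions, refuse pool-compartment metabolites (the member-level reaction
must be transplanted instead), and map member↔pool links back to plain
exchanges, since pool plumbing corresponds to medium access rather than to
an enzyme.

## The fixture generators

The toy pair emulates the essential structure of an obligate two-strain
degradation chain: A hydrolyzes S → I + P + X extracellularly but owns no
deaminase, B converts I → Y (carbon) and P → Q + NH₃ in two steps each, and
both biomass reactions consume ammonia (0.5 and 0.6 per unit growth).  With
the substrate bound u the binding constraints are v_A ≤ u, v_B ≤ u and
0.5·v_A + 0.6·v_B ≤ u, giving the recorded closed forms: free optimum
11u/6 (v_A = u, v_B = 5u/6), equal-scenario optimum 20u/11, singletons 0.
The helper strain C grows on a sugar and reduces nitrate to ammonia
(NO₃⁻ + 9H → NH₃ + 3H₂O), secreting the surplus; on the
substrate+sugar+nitrate medium the trio reaches 30 h⁻¹ versus the pair's
20, and on an ammonia medium without sugar the trio adds nothing — the
growth-promotion pattern a nitrate-assimilating helper should produce.
Substrate bounds (10 for S, 5 for sugar, 10 for nitrate) are round numbers
chosen once to keep the closed forms simple.

Random communities plant ground truth by construction: n strains in a ring,
each growing on a private carbon source (bounds drawn uniformly from
[5, 15]) through a linear pathway, each requiring 0.1 unit of a cofactor
produced as a biomass byproduct of its predecessor.  Because production is
growth-coupled, cutting any ring edge zeroes the whole community — the
generator verifies this by knockout before returning.  Optional "vitamin"
metabolites are producible by two interchangeable strains through
growth-independent side reactions, planting redundant edges whose
robustness tag must come out variable.  All randomness flows through one
seeded generator (default seed 20240601); identical parameters reproduce
byte-identical models.

Fixture metabolite names echo the chemistry of a herbicide-degrading
consortium for readability, and every non-boundary reaction is elementally
balanced over CHON so the balance checker is exercised, but the
stoichiometry is synthetic: passing tests demonstrate the correctness of
the algorithms on models with known ground truth, not biochemical fidelity
to any real organism.  Real GSMMs are hundreds of times larger, carry
charge imbalances, isoenzymes and compartment idiosyncrasies the fixtures
deliberately omit; the combinatorics of the screens, not LP size, is the
practical limit (the default hard cap is 4096 combinations — a full
18-strain exhaustive screen is 2¹⁸ LP batteries and needs the core-plus-k
mode or a cluster).

## Known limitations

Steady-state only: no dynamic or spatial community simulation, no abundance
evolution over time.  No thermodynamic feasibility, loopless FBA or MILP
strain design.  Elemental balance checking requires formulas; charge
balance is not checked, and an SBML round trip cannot distinguish charge 0
from an unset charge.  Exchange-flux magnitudes are pFBA representatives of
a degenerate optimal set; only sign patterns backed by a *stable* tag should
be interpreted as forced.
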