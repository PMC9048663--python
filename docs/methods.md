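# Methods

This note documents the models, conventions and numerical choices behind
`pathcurator`, and what the test suite does and does not demonstrate.

## Model representation and interchange

The in-memory model is a minimal compartmentalised network: id-keyed
metabolites and reactions, named pathway groupings, a linear objective
and a compartment registry. Metabolite ids follow the dominant community
convention `<base>_<compartment>` (`glc__D_c`); the compartment tag at
the end of the id must agree with the metabolite's compartment field.
Reaction stoichiometry maps metabolite ids to signed real coefficients,
negative for consumption. Flux bounds are in the conventional
mmol·gDW⁻¹·h⁻¹ with the community default magnitude 1000: reversible
(−1000, 1000), forward (0, 1000), backward (−1000, 0). A reaction also
records the direction its *source* asserted (`declared_direction`),
which is deliberately independent of the numeric bounds so the curation
battery can report disagreements instead of silently resolving them.

Models interchange as COBRA JSON. Serialization is canonical — keys
sorted, entities ordered by id, floats in shortest-repr form — so
writing the same model twice is byte-identical, which the golden tests
rely on. Unknown keys in a document are preserved opaquely and logged,
never dropped. Pathway membership and declared directions, which plain
COBRA JSON has no field for, ride in the standard `notes` blocks and
round-trip. SBML is out of scope.

## Chemical formulas

Formulas are parsed into element-count multisets with a small grammar:
element tokens `[A-Z][a-z]?` with optional counts, one level of
parenthesised groups with a multiplier, repeated symbols summed. The
generic-group tokens R, X and `*`, common in KEGG, are retained in the
counts but mark the formula *indeterminate*: arithmetic on such a
formula is not meaningful, so mass balance involving one reports
`undetermined` rather than guessing either way.

## Curation battery

Checks run per entity in a fixed order: duplicate → missing formula →
mass balance → reversibility. Duplicates (same id, then any shared
cross-reference pair, then — for reactions — identical stoichiometry)
short-circuit and the entity is skipped; this is what makes adding the
same pathway twice a no-op, a property the suite asserts. Everything
else is added *with* its findings: curation warns, it never blocks.

Mass balance computes, per element, the signed sum of coefficient ×
element count over all participants (products positive); a negative
residual therefore means the product side is short of that element, and
the suggestion text says which side to fix. Charge balance is included
under the same check as a charge residual; a metabolite with no charge
annotation contributes zero to it (only a *formula* absence degrades the
outcome to `undetermined`). The reversibility check flags the three
inconsistent combinations (declared reversible with lb ≥ 0, forward with
lb < 0, backward with ub > 0) and suggests the bound change that would
reconcile each.

The full narrative is appended to a plain-text log
(`timestamp | LEVEL | check | entity | message`); the log is opened
before any model mutation so an unwritable path aborts cleanly. Reports
export as TSV.

## FBA and the non-zero flux test

Plain FBA is solved through COBRApy/optlang (GLPK). The model is
translated in id-sorted order so the LP is constructed identically on
every run, making solutions reproducible. Infeasibility and
unboundedness are encoded in the result status, never raised. The test
suite and the acceptance script check the optima against two independent
routes: the min-capacity closed form for capacitated chains, and a dense
LP assembled directly from the stoichiometry dictionaries and solved
with `scipy.optimize.linprog` (HiGHS), with agreement required to 1e−6.

A *dead end* is a metabolite whose coefficients are sign-uniform across
all reactions — only ever produced or only ever consumed. (A metabolite
referenced by no reaction is not a dead end; it constrains nothing.)
Note the definition is purely structural: a metabolite served only by a
boundary reaction written as `{m: −1}` still counts, which is harmless
because auxiliaries are only tried while the tested reaction remains
blocked.

The non-zero flux test works on a scratch copy. It first maximises the
reaction's flux and, if that is below tolerance and the lower bound
admits it, minimises. While |v| < tolerance it walks metabolites in
breadth-first order from the tested reaction's participants (id-sorted
within each level), restricted to *current* dead ends, inserting one
reversible boundary reaction `SK_<met>` (bounds −1000..1000) at a time
and re-solving. A single reversible construct covers both roles — a
source for an unproducible precursor and a sink for an unconsumable
product — and the suggestion names the role that applied. The default
tolerance, 1e−7, is the conventional LP feasibility scale. Auxiliaries
persist in the user's model only when `keep_auxiliary` is set; by
default the model is structurally untouched, which a test asserts
entity-by-entity. If the tested reaction's bounds are pinned to zero the
report says so explicitly, since no auxiliary can help.

## Retrieval and dialect parsing

Records live in a cache laid out `<cache>/<source>/<kind>/<id>.<ext>`
(`kegg/.txt`, `biocyc/.xml`, `bigg/.json`), stored verbatim as fetched.
A cache miss falls through to a *provider* object; the provider used
throughout the tests serves generated fixture texts from a dictionary,
so no test ever touches a network. Offline mode turns a miss into an
error naming the expected path.

Each dialect parser covers the subset needed for pathway import: KEGG
flat-file records (12-column keyword field, continuation lines, `///`
terminator; `EQUATION` with `n Cxxxxx` terms and the `<=>` arrow meaning
reversible; `FORMULA`; module `REACTION` blocks taken as identifier
tokens in order of appearance), BioCyc ptools-XML (`Reaction` with
`left`/`right` compound references and optional `coefficient` children;
`reaction-direction` literals with the `PHYSIOL-` prefix stripped;
`Compound` formulas from `concise` attributes; `Pathway`
`reaction-list`s), and BiGG JSON records (compartment-tagged metabolite
references; first entry of `formulae`/`charges`; records flagged
`pseudoreaction` rejected, since exchanges and biomass are not
importable pathway content). The user text format is this package's own
documented contract: `M id, name, compartment, formula|-, charge|-`
lines and `R id[, name] | side arrow side [| lb, ub]` lines with arrows
`->`, `<->`, `<-`.

Conversion to model objects resolves each participant in a fixed order —
exact id in the model, then cross-reference lookup, then a stub built
from the cached metabolite record — chosen to minimise spurious
duplicates. Database gene lists become OR-joined gene rules (isozyme
assumption; the supported record subsets carry no complex/subunit
structure). Identifiers are rewritten into the model character set
(non-alphanumerics to `_`) and suffixed with the target compartment;
provenance is kept as identifiers.org-style cross-references
(`kegg.reaction`, `biocyc`, `bigg.reaction`, …), which is also what
duplicate detection keys on.

## Map layout and styling

Pathway reactions are first ordered topologically (edge u→v when a
product of u is a substrate of v under the declared/bound-implied
direction), using Kahn's algorithm with lexicographic tie-breaking;
cycles are broken by releasing the smallest remaining reaction id, and
disconnected components are concatenated by smallest member. Any input
yields a deterministic order.

Layout places one midmarker per reaction left-to-right at
x = margin + i·spacing on a fixed main axis. Each reaction's *primary*
substrate and product — the chain links, chosen as the metabolite shared
with the neighbouring reaction, else the highest-|coefficient|
participant, ties lexicographic — sit on the axis; a link shared by two
consecutive reactions is a single node placed midway between their
midmarkers (a shared node cannot be at the nominal ±spacing/2.5 offset
from both, so the midpoint is used; unshared primaries use the nominal
offset). Remaining participants fan out as side metabolites, substrates
above and products below the axis in id order. One straight segment
(Bézier controls null) joins each participant node to the midmarker, so
segments = Σ_r #participants(r) and nodes = distinct laid-out metabolite
positions + #reactions — the count formula the tests check on generated
pathways. Node ids are consecutive integers from "0". Maps serialize as
the Escher two-element [header, body] array with the standard schema
identifier, canonically (sorted keys), so identical inputs give
byte-identical files.

Flux overlays use |v| — sign only encodes which direction a reversible
reaction ran — normalized either linearly (min–max; all-equal → 1) or by
quantile (average ranks scaled to [0,1]; n=1 → 1), then interpolated
piecewise-linearly per RGB channel through the gradient stops with
half-up rounding; stroke width is 2 + 8·t. Quantile styling is by
construction invariant under any strictly monotone transformation of the
flux magnitudes. Styles are emitted as a sidecar document rather than
mutated into the map, because the Escher map standard carries geometry
only; data overlays are supplied at render time. Cross-condition
comparisons can be normalized on a shared scale by pooling the flux
tables before styling (the `--shared-scale` CLI flag).

## Fixture generator

`generate_toy_model(n, with_exchanges, dead_end_at, seed)` builds a
linear chain M0 → … → Mn with per-step capacities drawn uniformly from
the integers 1–10 (seeded), optional boundary exchanges at both ends,
and optionally one step excreting a byproduct `d_c` that nothing
consumes. Chain metabolites share one formula so the chain steps are
mass-balanced; the byproduct is H2O-shaped, so the dead-end step is
deliberately imbalanced and exercises the mass-balance finding as well.
The chain's FBA optimum is the minimum capacity — the closed form the
FBA tests use. `generate_fixture_records` renders the same network as
KEGG, BioCyc and BiGG records (BiGG has no pathway record type, so the
pathway exists in the other two dialects), which is what the
cross-dialect consistency check runs on.

What the toys do *not* emulate: real database records' field richness
(polymer formulas, protein participants, subscription metadata), large
networks, multiple compartments, and biologically meaningful gene rules.
Passing tests therefore demonstrate the correctness of parsing,
conversion, checking, LP and layout logic on well-defined inputs — not
robustness to the full variety of production database content.

## Problem sizes and determinism

The verification suite uses deliberately small instances: 200 random
reactions for the mass-balance oracle comparison, chains of length 3–10
and 20 random networks of ≤ 8 reactions for the LP cross-checks, and 50
generated pathways for the map-geometry formula — sizes at which the
independent oracles (brute-force tallies, dense LPs) are trivially
exact while still covering the combinatorics. All randomness flows
through explicit integer seeds; the acceptance script derives every
generator from its `--seed` argument, and reruns with the same seed are
bit-reproducible.

## Known limitations

- Imbalances are suggested, never auto-fixed; no proton/water completion
  and no formula inference.
- The flux test's insertion heuristic is greedy and structural; it is
  not MILP gap-filling and may insert more auxiliaries than the minimal
  set on pathological networks (deterministically so).
- Gene rules are flat OR-joins; boolean evaluation and deletion analysis
  are out of scope.
- Only the stated subsets of the three database dialects are parsed;
  authentication-gated content and bulk dumps are not handled.
- Layout is optimised for mostly-linear pathways; highly branched or
  cyclic pathways render deterministically but without aesthetic
  crossing minimisation.
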