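# pathcurator

Pathway-centric curation, extension, functional testing and visualization
of constraint-based metabolic models.

Genome-scale metabolic models (GEMs) describe an organism's metabolism as
a stoichiometric network — metabolites × reactions with flux bounds — and
are analysed with flux balance analysis (FBA): maximise an objective
c·v subject to steady state S·v = 0 and lb ≤ v ≤ ub. Modellers rarely
extend such models one reaction at a time; the natural working unit is
the *pathway*. `pathcurator` is built around that unit: it parses pathway
and reaction records from three database dialects (KEGG flat files,
BioCyc ptools-XML, BiGG JSON) or from a user-curated text format,
converts them into model objects, quality-checks every addition, verifies
that added reactions can actually carry flux, and renders pathways as
[Escher](https://escher.github.io)-compatible maps with flux-to-colour
overlays.

The curation battery checks each candidate entity, in order, for

1. **duplicates** — same id, a shared identifiers.org cross-reference
   (e.g. `kegg.reaction:R00299`), or identical stoichiometry; duplicates
   are skipped, which makes pathway addition idempotent;
2. **missing chemical formulas** — a metabolite without a formula makes
   every reaction that uses it unverifiable;
3. **mass and charge balance** — per element e, the residual
   Σ_m s_m · formula(m)[e] over the reaction's stoichiometric
   coefficients s_m, plus the analogous charge residual; formulas with
   generic groups (R, X, \*) yield *undetermined*, never a guess;
4. **reversibility** — the direction the source database declared versus
   what the numeric bounds allow.

Nothing blocks: every issue becomes a warning with a concrete suggestion,
mirrored to a log file and summarised in a report.

Functionality is verified with a **non-zero flux test**: maximise (and if
reversible, minimise) the flux through a reaction; while |v| stays below
tolerance, insert reversible auxiliary boundary reactions (`SK_<met>`)
for dead-end metabolites — nearest to the tested reaction first — and
re-solve. Each inserted auxiliary is translated into a manual-curation
suggestion ("metabolite X required an auxiliary sink — add a consuming
reaction or transport"). The probing runs on a scratch copy; the user's
model is only modified on request.

All record retrieval goes through a local cache
(`<cache>/<source>/<kind>/<id>.<ext>`); fetched raw text is stored
verbatim so every run is reproducible offline. A fixture generator
produces deterministic toy models *and* matching records in all three
dialects, so the complete workflow runs without any network access.

## Worked example

```python
from pathlib import Path
import pathcurator as pc
from pathcurator.retrieval import make_fetcher

# A 3-step toy chain whose middle reaction excretes a byproduct d_c that
# nothing consumes, plus matching KEGG/BioCyc/BiGG records.
toy = pc.generate_toy_model(3, with_exchanges=True, dead_end_at=1, seed=7)
provider = pc.fixture_provider(toy)
fetcher = make_fetcher(Path("cache"), provider=provider)

model = pc.Model("demo")
model.compartments["c"] = "c"
pathway = pc.create_object(fetcher("kegg", "pathway", "TOYPATH"),
                           "c", model, fetcher)
report = pc.run_curation(model, [pathway], log_path="curation.log")
print(report.summary())
```

```
curation summary: 4 added, 0 skipped (1 findings)
  mass_imbalance: 1
```

Three reactions and the pathway object were added; one finding: the
byproduct-excreting step does not conserve mass (the toy byproduct is
H2O-shaped), and the report says exactly what is missing:

```
mass_imbalance: R1 — element residuals {'H': 2.0, 'O': 1.0}
  suggestion: add 2 H to the reactant side; add 1 O to the reactant side
```

The non-zero flux test finds that R1 is blocked by the dead end, repairs
it with a single auxiliary boundary reaction and reports the curation
step that would fix it for real:

```python
flux = pc.test_non_zero_flux(toy, "R1")
```

```
R1 passed=True flux=7 auxiliary=['SK_d_c']
suggestion: metabolite d_c required an auxiliary sink — add a consuming
reaction or transport
```

(7 is the smallest capacity along the chain, i.e. the FBA optimum.)
Finally, lay the pathway out as an Escher map and colour it by flux:

```python
pw = pc.Pathway("chain", reaction_ids=["R0", "R1", "R2"])
toy.add_pathway(pw)
emap = pc.build_escher_map(pw, toy)
style = pc.map_flux_to_style({"R0": 0.0, "R1": 5.0, "R2": 10.0})
pc.write_escher_json(emap, "chain.json", style=style)
```

```
map: 8 nodes, 7 segments
style: {'R0': ('#FFFFFF', 2.0), 'R1': ('#FF8080', 6.0), 'R2': ('#FF0000', 10.0)}
```

`chain.json` loads directly in Escher; the `.style.json` sidecar carries
the per-reaction colour (here a white→red gradient, linearly normalized)
and stroke width.

The same workflow is available from the shell:

```sh
pathcurator --cache-dir cache fetch kegg TOYPATH pathway
pathcurator --cache-dir cache add-pathway host.json kegg TOYPATH out.json
pathcurator test-flux out.json TOYPATH
pathcurator visualize out.json chain map.json --flux-table flux.tsv
```

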