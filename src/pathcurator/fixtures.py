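"""Deterministic toy models and matching database fixture records.

The generator builds capacitated linear-chain models (M0 → M1 → … → Mn)
with seeded integer capacities, optional boundary exchanges and an
optional dead-end byproduct — the minimal structures on which every
curation, flux-test and layout behaviour of the package can be exercised
without touching any external service.  ``generate_fixture_records``
renders the same network in all three supported database dialects so the
full fetch → convert → curate workflow runs against a purely local
provider.
"""

from __future__ import annotations

import json

import numpy as np

from .formulas import parse_formula
from .model_core import Direction, Metabolite, Model, Pathway, Reaction
from .retrieval import DictProvider

__all__ = [
    "generate_toy_model",
    "generate_fixture_records",
    "fixture_provider",
    "TOY_PATHWAY_ID",
]

TOY_PATHWAY_ID = "TOYPATH"

_CHAIN_FORMULA = "C6H12O6"
_BYPRODUCT_FORMULA = "H2O"


def generate_toy_model(n_reactions: int, with_exchanges: bool = True,
                       dead_end_at: int | None = None,
                       seed: int = 0) -> Model:
    """Linear chain model with seeded capacities in [1, 10].

    Reaction ``Ri`` converts ``Mi_c`` → ``M{i+1}_c`` with a forward bound
    drawn uniformly from the integers 1–10.  With ``with_exchanges``,
    boundary reactions supply ``M0_c`` and drain the terminal metabolite.
    ``dead_end_at=k`` makes reaction ``Rk`` excrete an extra byproduct
    ``d_c`` that nothing consumes.
    """
    if n_reactions < 1:
        raise ValueError("n_reactions must be >= 1")
    if dead_end_at is not None and not 0 <= dead_end_at < n_reactions:
        raise ValueError(
            f"dead_end_at must be in [0, {n_reactions}), got {dead_end_at}"
        )
    rng = np.random.default_rng(seed)
    caps = rng.integers(1, 11, size=n_reactions)
    model = Model(id=f"toy_chain_{n_reactions}_seed{seed}")
    model.compartments["c"] = "cytosol"
    for i in range(n_reactions + 1):
        model.add_metabolite(Metabolite(
            id=f"M{i}_c", name=f"chain metabolite {i}", compartment="c",
            formula=parse_formula(_CHAIN_FORMULA), charge=0,
        ))
    if dead_end_at is not None:
        model.add_metabolite(Metabolite(
            id="d_c", name="dead-end byproduct", compartment="c",
            formula=parse_formula(_BYPRODUCT_FORMULA), charge=0,
        ))
    for i in range(n_reactions):
        stoich = {f"M{i}_c": -1.0, f"M{i + 1}_c": 1.0}
        if dead_end_at == i:
            stoich["d_c"] = 1.0
        model.add_reaction(Reaction(
            id=f"R{i}", name=f"chain step {i}", stoichiometry=stoich,
            lower_bound=0.0, upper_bound=float(caps[i]),
            declared_direction=Direction.FORWARD,
        ))
    if with_exchanges:
        model.add_reaction(Reaction(
            id="EX_M0_c", name="uptake of M0",
            stoichiometry={"M0_c": -1.0},
            lower_bound=-1000.0, upper_bound=0.0,
            declared_direction=Direction.BACKWARD,
        ))
        last = f"M{n_reactions}_c"
        model.add_reaction(Reaction(
            id=f"EX_{last}", name=f"secretion of {last[:-2]}",
            stoichiometry={last: -1.0},
            lower_bound=0.0, upper_bound=1000.0,
            declared_direction=Direction.FORWARD,
        ))
    model.objective = {f"R{n_reactions - 1}": 1.0}
    return model


def _base_id(met_id: str) -> str:
    return met_id.rsplit("_", 1)[0]


def _kegg_compound(met: Metabolite) -> str:
    lines = [f"ENTRY       {_base_id(met.id):<28}Compound",
             f"NAME        {met.name or _base_id(met.id)}"]
    if met.formula is not None:
        lines.append(f"FORMULA     {met.formula}")
    lines.append("///")
    return "\n".join(lines) + "\n"


def _equation_side(items: list[tuple[str, float]]) -> str:
    terms = []
    for mid, coeff in items:
        c = abs(coeff)
        prefix = "" if c == 1 else f"{int(c) if c == int(c) else c} "
        terms.append(f"{prefix}{_base_id(mid)}")
    return " + ".join(terms)


def _kegg_reaction(rxn: Reaction) -> str:
    left = sorted((m, c) for m, c in rxn.stoichiometry.items() if c < 0)
    right = sorted((m, c) for m, c in rxn.stoichiometry.items() if c > 0)
    equation = f"{_equation_side(left)} <=> {_equation_side(right)}"
    return (f"ENTRY       {rxn.id:<28}Reaction\n"
            f"NAME        {rxn.name or rxn.id}\n"
            f"EQUATION    {equation}\n///\n")


def _kegg_module(pathway_id: str, reaction_ids: list[str]) -> str:
    return (f"ENTRY       {pathway_id:<28}Module\n"
            f"NAME        toy pathway\n"
            f"REACTION    {' '.join(reaction_ids)}\n///\n")


def _biocyc_compound(met: Metabolite) -> str:
    inner = ""
    if met.formula is not None:
        concise = " ".join(
            f"{e} {n}" for e, n in sorted(met.formula.element_counts.items())
        )
        charge = met.charge if met.charge is not None else 0
        inner = (f"<cml><molecule formalCharge='{charge}'>"
                 f"<formula concise='{concise}'/></molecule></cml>")
    return (f"<ptools-xml><Compound frameid='{_base_id(met.id)}'>"
            f"<common-name>{met.name or _base_id(met.id)}</common-name>"
            f"{inner}</Compound></ptools-xml>\n")


_BIOCYC_DIR = {
    Direction.FORWARD: "LEFT-TO-RIGHT",
    Direction.BACKWARD: "RIGHT-TO-LEFT",
    Direction.REVERSIBLE: "REVERSIBLE",
    Direction.UNSPECIFIED: "REVERSIBLE",
}


def _biocyc_side(tag: str, items: list[tuple[str, float]]) -> str:
    parts = []
    for mid, coeff in items:
        c = abs(coeff)
        coeff_el = ("" if c == 1 else
                    f"<coefficient>{int(c) if c == int(c) else c}"
                    "</coefficient>")
        parts.append(f"<{tag}><Compound frameid='{_base_id(mid)}'/>"
                     f"{coeff_el}</{tag}>")
    return "".join(parts)


def _biocyc_reaction(rxn: Reaction) -> str:
    left = sorted((m, c) for m, c in rxn.stoichiometry.items() if c < 0)
    right = sorted((m, c) for m, c in rxn.stoichiometry.items() if c > 0)
    return (f"<ptools-xml><Reaction frameid='{rxn.id}'>"
            f"<common-name>{rxn.name or rxn.id}</common-name>"
            f"{_biocyc_side('left', left)}{_biocyc_side('right', right)}"
            f"<reaction-direction>{_BIOCYC_DIR[rxn.declared_direction]}"
            f"</reaction-direction></Reaction></ptools-xml>\n")


def _biocyc_pathway(pathway_id: str, reaction_ids: list[str]) -> str:
    refs = "".join(f"<Reaction frameid='{r}'/>" for r in reaction_ids)
    return (f"<ptools-xml><Pathway frameid='{pathway_id}'>"
            f"<reaction-list>{refs}</reaction-list>"
            f"</Pathway></ptools-xml>\n")


def _bigg_metabolite(met: Metabolite) -> str:
    doc = {
        "bigg_id": _base_id(met.id),
        "name": met.name or _base_id(met.id),
        "formulae": [str(met.formula)] if met.formula is not None else [],
        "charges": [met.charge] if met.charge is not None else [],
    }
    return json.dumps(doc, sort_keys=True) + "\n"


def _bigg_reaction(rxn: Reaction) -> str:
    doc = {
        "bigg_id": rxn.id,
        "name": rxn.name or rxn.id,
        "pseudoreaction": False,
        "metabolites": [
            {"bigg_id": _base_id(mid),
             "compartment_bigg_id": mid.rsplit("_", 1)[1],
             "stoichiometry": coeff}
            for mid, coeff in sorted(rxn.stoichiometry.items())
        ],
    }
    return json.dumps(doc, sort_keys=True) + "\n"


def _is_boundary(rxn: Reaction) -> bool:
    return rxn.id.startswith(("EX_", "SK_", "DM_"))


def generate_fixture_records(model: Model) -> dict[tuple[str, str, str], str]:
    """Dialect-valid records for every non-boundary reaction, every
    metabolite, and one pathway grouping the chain, in all three dialects.

    Keys are ``(source, kind, identifier)`` suitable for
    :class:`~pathcurator.retrieval.DictProvider`.  BiGG carries no pathway
    record type, so the pathway exists in the KEGG and BioCyc dialects.
    """
    records: dict[tuple[str, str, str], str] = {}
    chain = [rid for rid in sorted(model.reactions,
                                   key=lambda r: (len(r), r))
             if not _is_boundary(model.reactions[rid])]
    for mid in sorted(model.metabolites):
        met = model.metabolites[mid]
        base = _base_id(mid)
        records[("kegg", "metabolite", base)] = _kegg_compound(met)
        records[("biocyc", "metabolite", base)] = _biocyc_compound(met)
        records[("bigg", "metabolite", base)] = _bigg_metabolite(met)
    for rid in chain:
        rxn = model.reactions[rid]
        records[("kegg", "reaction", rid)] = _kegg_reaction(rxn)
        records[("biocyc", "reaction", rid)] = _biocyc_reaction(rxn)
        records[("bigg", "reaction", rid)] = _bigg_reaction(rxn)
    records[("kegg", "pathway", TOY_PATHWAY_ID)] = _kegg_module(
        TOY_PATHWAY_ID, chain)
    records[("biocyc", "pathway", TOY_PATHWAY_ID)] = _biocyc_pathway(
        TOY_PATHWAY_ID, chain)
    return records


def fixture_provider(model: Model) -> DictProvider:
    """A :class:`DictProvider` serving the fixture records of ``model``."""
    return DictProvider(generate_fixture_records(model))
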