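"""Flux balance analysis and the non-zero flux capability test.

``solve_fba`` solves the standard LP (maximise c·v subject to S·v = 0 and
elementwise bounds) through COBRApy/optlang.  ``test_non_zero_flux``
checks whether a given reaction can carry flux above a tolerance; if not,
it deterministically inserts reversible ``SK_`` boundary reactions for
dead-end metabolites — nearest to the tested reaction first — until flux
appears, and translates every insertion into a manual-curation
suggestion.  The probing happens on a scratch copy, so the user's model
is untouched unless auxiliaries are explicitly kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import cobra

from .model_core import Direction, Model, Reaction

__all__ = [
    "FluxResult",
    "NonZeroFluxReport",
    "to_cobra",
    "solve_fba",
    "find_dead_ends",
    "add_sink",
    "test_non_zero_flux",
]


@dataclass
class FluxResult:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)


@dataclass
class NonZeroFluxReport:
    reaction_id: str
    passed: bool
    achieved_flux: float
    auxiliary_added: list[str] = field(default_factory=list)
    suggestions: list[str] = field(default_factory=list)
    kept_in_model: bool = False

    def to_tsv_row(self) -> str:
        return "\t".join([
            self.reaction_id,
            "pass" if self.passed else "FAIL",
            f"{self.achieved_flux:.6g}",
            ",".join(self.auxiliary_added) or "-",
            "; ".join(self.suggestions) or "-",
        ])


def to_cobra(model: Model) -> cobra.Model:
    """Translate our model into a COBRApy model (sorted, hence
    deterministic problem construction)."""
    cm = cobra.Model(model.id)
    mets = {}
    for mid in sorted(model.metabolites):
        met = model.metabolites[mid]
        mets[mid] = cobra.Metabolite(mid, compartment=met.compartment or "c")
    rxns = []
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        cr = cobra.Reaction(rid, lower_bound=rxn.lower_bound,
                            upper_bound=rxn.upper_bound)
        rxns.append(cr)
    cm.add_metabolites(list(mets.values()))
    cm.add_reactions(rxns)
    for rid in sorted(model.reactions):
        cm.reactions.get_by_id(rid).add_metabolites({
            mets[mid]: coeff
            for mid, coeff in sorted(model.reactions[rid].stoichiometry.items())
        })
    return cm


def solve_fba(model: Model, objective: dict[str, float] | None = None,
              sense: str = "max") -> FluxResult:
    """Plain flux balance analysis.

    ``objective`` maps reaction ids to weights (defaults to the model's
    stored objective) and must be non-empty.  Infeasibility/unboundedness
    is encoded in the result status, never raised.
    """
    if objective is None:
        objective = model.objective
    if not objective:
        raise ValueError("FBA requires a non-empty objective")
    for rid in objective:
        if rid not in model.reactions:
            raise KeyError(f"objective references unknown reaction {rid!r}")
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    cm = to_cobra(model)
    expr = sum(w * cm.reactions.get_by_id(rid).flux_expression
               for rid, w in sorted(objective.items()))
    cm.objective = expr
    cm.objective_direction = sense
    sol = cm.optimize(raise_error=False)
    if sol.status == "optimal":
        return FluxResult("optimal", float(sol.objective_value),
                          {r: float(v) for r, v in sol.fluxes.items()})
    status = "unbounded" if sol.status == "unbounded" else "infeasible"
    return FluxResult(status, float("nan"), {})


def find_dead_ends(model: Model) -> list[str]:
    """Metabolites that are only produced or only consumed (id-sorted).

    A metabolite referenced by no reaction at all is not a dead end here —
    it simply does not constrain any flux.
    """
    signs: dict[str, set[int]] = {}
    for rxn in model.reactions.values():
        for mid, coeff in rxn.stoichiometry.items():
            signs.setdefault(mid, set()).add(1 if coeff > 0 else -1)
    return sorted(m for m, s in signs.items() if len(s) == 1)


def add_sink(model: Model, metabolite_id: str) -> str:
    """Insert the reversible boundary reaction ``SK_<metabolite_id>``.

    Bounds (−1000, 1000) let it act as a source or a sink as needed.
    """
    if metabolite_id not in model.metabolites:
        raise KeyError(f"unknown metabolite {metabolite_id!r}")
    sid = f"SK_{metabolite_id}"
    if sid in model.reactions:
        raise ValueError(f"auxiliary reaction {sid!r} already present")
    model.add_reaction(Reaction(
        id=sid,
        name=f"auxiliary boundary for {metabolite_id}",
        stoichiometry={metabolite_id: -1.0},
        lower_bound=-1000.0,
        upper_bound=1000.0,
        declared_direction=Direction.REVERSIBLE,
    ))
    return sid


def _bfs_metabolite_order(model: Model, reaction_id: str) -> list[str]:
    """Metabolites by breadth-first distance from the tested reaction's
    participants on the metabolite–reaction graph, id-sorted per level."""
    met_to_rxns: dict[str, list[str]] = {}
    for rid, rxn in model.reactions.items():
        for mid in rxn.stoichiometry:
            met_to_rxns.setdefault(mid, []).append(rid)
    level = sorted(model.reactions[reaction_id].stoichiometry)
    seen = set(level)
    order: list[str] = list(level)
    while level:
        nxt: set[str] = set()
        for mid in level:
            for rid in met_to_rxns.get(mid, []):
                nxt.update(model.reactions[rid].stoichiometry)
        level = sorted(nxt - seen)
        seen.update(level)
        order.extend(level)
    return order


def _best_flux(model: Model, reaction_id: str, tolerance: float) -> float:
    res = solve_fba(model, {reaction_id: 1.0}, "max")
    v = res.fluxes.get(reaction_id, 0.0) if res.status == "optimal" else 0.0
    if abs(v) < tolerance and model.reactions[reaction_id].lower_bound < 0:
        res = solve_fba(model, {reaction_id: 1.0}, "min")
        v2 = res.fluxes.get(reaction_id, 0.0) if res.status == "optimal" else 0.0
        if abs(v2) > abs(v):
            v = v2
    return v


def test_non_zero_flux(model: Model, reaction_id: str,
                       tolerance: float = 1e-7,
                       keep_auxiliary: bool = False) -> NonZeroFluxReport:
    """Can ``reaction_id`` carry a flux of magnitude ≥ ``tolerance``?

    Works on a scratch copy of ``model``: first maximises (and, for
    reversible reactions, minimises) the reaction's flux; while it stays
    below tolerance, dead-end metabolites are given auxiliary ``SK_``
    boundary reactions one at a time, in breadth-first order from the
    tested reaction, re-solving after each insertion.  Each auxiliary
    yields one manual-curation suggestion.  Auxiliaries are copied into
    the user model only when ``keep_auxiliary`` is set.
    """
    if reaction_id not in model.reactions:
        raise KeyError(f"unknown reaction {reaction_id!r}")
    scratch = model.copy()
    achieved = _best_flux(scratch, reaction_id, tolerance)
    auxiliary: list[str] = []
    suggestions: list[str] = []
    if abs(achieved) < tolerance:
        for mid in _bfs_metabolite_order(scratch, reaction_id):
            if abs(achieved) >= tolerance:
                break
            if f"SK_{mid}" in scratch.reactions:
                continue
            if mid not in find_dead_ends(scratch):
                continue
            only_produced = all(
                rxn.stoichiometry.get(mid, 0) >= 0
                for rxn in scratch.reactions.values()
            )
            role = "sink" if only_produced else "source"
            fix = ("add a consuming reaction or transport"
                   if only_produced else
                   "add a producing reaction or transport")
            sid = add_sink(scratch, mid)
            auxiliary.append(sid)
            suggestions.append(
                f"metabolite {mid} required an auxiliary {role} — {fix}"
            )
            achieved = _best_flux(scratch, reaction_id, tolerance)
    passed = abs(achieved) >= tolerance
    rxn = model.reactions[reaction_id]
    if not passed and rxn.lower_bound == rxn.upper_bound == 0:
        suggestions.append(
            f"bounds (0, 0) forbid any flux through {reaction_id}; "
            "relax lower_bound/upper_bound"
        )
    kept = False
    if keep_auxiliary and auxiliary:
        for sid in auxiliary:
            if sid not in model.reactions:
                add_sink(model, sid.removeprefix("SK_"))
        kept = True
    return NonZeroFluxReport(
        reaction_id=reaction_id,
        passed=passed,
        achieved_flux=achieved,
        auxiliary_added=auxiliary,
        suggestions=suggestions,
        kept_in_model=kept,
    )
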