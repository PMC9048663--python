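"""Curation battery for newly added metabolites, reactions and pathways.

Every candidate entity runs through a fixed sequence of checks —
duplicate detection, missing chemical formulas, elemental/charge mass
balance, and declared-direction vs bounds consistency.  Failing a check
never aborts the addition (duplicates excepted, which are skipped to keep
the procedure idempotent); each issue surfaces as a warning
:class:`Finding`, is mirrored to a log file, and is summarised in a
:class:`CurationReport`.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

from .formulas import ChemicalFormula, parse_formula  # re-export  # noqa: F401
from .model_core import (
    DEFAULT_BOUNDS,
    Direction,
    Metabolite,
    Model,
    Pathway,
    Reaction,
    find_by_cross_reference,
)

__all__ = [
    "Finding",
    "CurationReport",
    "MassBalanceResult",
    "parse_formula",
    "check_mass_balance",
    "detect_duplicate",
    "check_reversibility",
    "run_curation",
]

CHECKS = ("duplicate", "missing_formula", "mass_imbalance",
          "charge_imbalance", "reversibility_mismatch",
          "indeterminate_formula")


@dataclass
class Finding:
    check: str
    entity_id: str
    severity: str = "warning"  # curation warns; it never aborts
    message: str = ""
    suggestion: str = ""


@dataclass
class MassBalanceResult:
    """Per-element and charge residuals of a reaction.

    ``residuals[e]`` is the signed sum of coefficient × element count over
    all participants (products positive), so a negative value means the
    product side is short of that element.  ``status`` is ``balanced``,
    ``imbalanced`` or — when any participant lacks a formula or has an
    indeterminate one — ``undetermined``.
    """

    residuals: dict[str, float] = field(default_factory=dict)
    charge_residual: float = 0.0
    status: str = "undetermined"
    missing_formula: list[str] = field(default_factory=list)
    indeterminate: list[str] = field(default_factory=list)


def check_mass_balance(reaction: Reaction, model: Model) -> MassBalanceResult:
    """Elemental and charge balance of ``reaction`` within ``model``.

    Metabolites without a charge contribute 0 to the charge residual;
    missing or generic-group formulas make the outcome ``undetermined``
    rather than guessing.
    """
    result = MassBalanceResult()
    residuals: dict[str, float] = {}
    charge = 0.0
    for mid, coeff in reaction.stoichiometry.items():
        met = model.metabolites[mid]
        if met.formula is None:
            result.missing_formula.append(mid)
            continue
        if met.formula.indeterminate:
            result.indeterminate.append(mid)
            continue
        for element, count in met.formula.element_counts.items():
            residuals[element] = residuals.get(element, 0.0) + coeff * count
        charge += coeff * (met.charge or 0)
    residuals = {e: r for e, r in residuals.items() if r != 0}
    result.residuals = residuals
    result.charge_residual = charge
    if result.missing_formula or result.indeterminate:
        result.status = "undetermined"
    elif residuals or charge != 0:
        result.status = "imbalanced"
    else:
        result.status = "balanced"
    return result


def _balance_suggestion(result: MassBalanceResult) -> str:
    parts = []
    for element in sorted(result.residuals):
        r = result.residuals[element]
        side = "product" if r < 0 else "reactant"
        n = abs(r)
        n = int(n) if n == int(n) else n
        parts.append(f"add {n} {element} to the {side} side")
    if result.charge_residual:
        parts.append(f"charge residual {result.charge_residual:+g}; "
                     "adjust charged species (e.g. protons)")
    return "; ".join(parts)


def detect_duplicate(model: Model, candidate) -> str | None:
    """Id of an existing entity duplicating ``candidate``, or ``None``.

    Match order: identical id; any shared cross-reference pair; for
    reactions, an identical stoichiometry mapping.  First hit wins.
    """
    is_reaction = isinstance(candidate, Reaction)
    namespace = model.reactions if is_reaction else model.metabolites
    if candidate.id in namespace:
        return candidate.id
    for ns, idents in sorted(candidate.cross_refs.items()):
        for ident in idents:
            hit = find_by_cross_reference(model, ns, ident)
            if hit is not None and hit in namespace:
                return hit
    if is_reaction:
        for rid in sorted(model.reactions):
            if model.reactions[rid].stoichiometry == candidate.stoichiometry:
                return rid
    return None


def check_reversibility(reaction: Reaction) -> Finding | None:
    """Mismatch between the declared direction and the numeric bounds."""
    d = reaction.declared_direction
    lb, ub = reaction.lower_bound, reaction.upper_bound
    mismatch = suggestion = None
    if d == Direction.REVERSIBLE and lb >= 0:
        mismatch = f"declared reversible but lower_bound {lb:g} >= 0"
        suggestion = (f"set lower_bound to "
                      f"{DEFAULT_BOUNDS[Direction.REVERSIBLE][0]:g} "
                      "to allow the backward direction")
    elif d == Direction.FORWARD and lb < 0:
        mismatch = f"declared forward but lower_bound {lb:g} < 0"
        suggestion = "set lower_bound to 0"
    elif d == Direction.BACKWARD and ub > 0:
        mismatch = f"declared backward but upper_bound {ub:g} > 0"
        suggestion = "set upper_bound to 0"
    if mismatch is None:
        return None
    return Finding("reversibility_mismatch", reaction.id,
                   message=mismatch, suggestion=suggestion)


@dataclass
class CurationReport:
    findings: list[Finding] = field(default_factory=list)
    entities_added: list[str] = field(default_factory=list)
    entities_skipped: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.findings:
            out[f.check] = out.get(f.check, 0) + 1
        return out

    def summary(self) -> str:
        lines = [
            f"curation summary: {len(self.entities_added)} added, "
            f"{len(self.entities_skipped)} skipped "
            f"({len(self.findings)} findings)"
        ]
        for check in CHECKS:
            n = self.counts.get(check, 0)
            if n:
                lines.append(f"  {check}: {n}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("check\tentity_id\tseverity\tmessage\tsuggestion\n")
            for f in self.findings:
                fh.write(f"{f.check}\t{f.entity_id}\t{f.severity}\t"
                         f"{f.message}\t{f.suggestion}\n")


class _Log:
    def __init__(self, path):
        self.fh = open(path, "a") if path is not None else None

    def write(self, level: str, check: str, entity: str, message: str):
        if self.fh is not None:
            stamp = datetime.datetime.now().isoformat(timespec="seconds")
            self.fh.write(f"{stamp} | {level.upper()} | {check} | "
                          f"{entity} | {message}\n")

    def close(self):
        if self.fh is not None:
            self.fh.close()


def _curate_metabolite(met: Metabolite, model: Model, report: CurationReport,
                       log: _Log) -> None:
    dup = detect_duplicate(model, met)
    if dup is not None:
        f = Finding("duplicate", met.id,
                    message=f"metabolite duplicates existing {dup!r}; skipped")
        report.findings.append(f)
        report.entities_skipped.append(met.id)
        log.write("warning", "duplicate", met.id, f.message)
        return
    if met.formula is None:
        f = Finding("missing_formula", met.id,
                    message="metabolite has no chemical formula",
                    suggestion="supply a formula so reactions using it can "
                               "be mass-balanced")
        report.findings.append(f)
        log.write("warning", "missing_formula", met.id, f.message)
    elif met.formula.indeterminate:
        f = Finding("indeterminate_formula", met.id,
                    message=f"formula {met.formula} contains a generic group")
        report.findings.append(f)
        log.write("warning", "indeterminate_formula", met.id, f.message)
    model.add_metabolite(met)
    report.entities_added.append(met.id)
    log.write("info", "added", met.id, "metabolite added to model")


def _curate_reaction(rxn: Reaction, model: Model, report: CurationReport,
                     log: _Log) -> None:
    dup = detect_duplicate(model, rxn)
    if dup is not None:
        f = Finding("duplicate", rxn.id,
                    message=f"reaction duplicates existing {dup!r}; skipped")
        report.findings.append(f)
        report.entities_skipped.append(rxn.id)
        log.write("warning", "duplicate", rxn.id, f.message)
        return
    model.add_reaction(rxn)  # structural integrity enforced here
    balance = check_mass_balance(rxn, model)
    if balance.status == "undetermined":
        missing = balance.missing_formula + balance.indeterminate
        f = Finding("missing_formula", rxn.id,
                    message="mass balance undetermined; participants without "
                            f"usable formula: {', '.join(sorted(missing))}",
                    suggestion="supply formulas for the listed metabolites")
        report.findings.append(f)
        log.write("warning", "missing_formula", rxn.id, f.message)
    elif balance.status == "imbalanced":
        if balance.residuals:
            f = Finding("mass_imbalance", rxn.id,
                        message=f"element residuals {balance.residuals}",
                        suggestion=_balance_suggestion(balance))
            report.findings.append(f)
            log.write("warning", "mass_imbalance", rxn.id, f.message)
        if balance.charge_residual:
            f = Finding("charge_imbalance", rxn.id,
                        message=f"charge residual "
                                f"{balance.charge_residual:+g}",
                        suggestion=_balance_suggestion(balance))
            report.findings.append(f)
            log.write("warning", "charge_imbalance", rxn.id, f.message)
    rev = check_reversibility(rxn)
    if rev is not None:
        report.findings.append(rev)
        log.write("warning", rev.check, rxn.id, rev.message)
    report.entities_added.append(rxn.id)
    log.write("info", "added", rxn.id, "reaction added to model")


def run_curation(model: Model, entities: list, log_path=None) -> CurationReport:
    """Curate and add ``entities`` (from ``create_object``) to ``model``.

    Checks run per entity in the fixed order duplicate → missing formula →
    mass balance → reversibility.  Duplicates are skipped; everything else
    is added with its findings attached.  The narrative is appended to
    ``log_path`` (opened before any mutation, so an unwritable path leaves
    the model untouched).
    """
    log = _Log(log_path)
    report = CurationReport()
    try:
        for entity in entities:
            if isinstance(entity, Metabolite):
                _curate_metabolite(entity, model, report, log)
            elif isinstance(entity, Reaction):
                _curate_reaction(entity, model, report, log)
            elif isinstance(entity, Pathway):
                for rxn in getattr(entity, "staged_reactions", []):
                    _curate_reaction(rxn, model, report, log)
                if entity.id in model.pathways:
                    log.write("info", "pathway", entity.id,
                              "pathway already registered; left unchanged")
                else:
                    model.add_pathway(entity)
                    report.entities_added.append(entity.id)
                    log.write("info", "added", entity.id,
                              "pathway registered")
            else:
                raise TypeError(
                    f"cannot curate object of type {type(entity).__name__}"
                )
        log.write("info", "summary", model.id,
                  report.summary().replace("\n", "; "))
    finally:
        log.close()
    return report
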