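"""Core constraint-based model structures and COBRA-JSON interchange.

The in-memory representation is deliberately small: a :class:`Model` owns
id-keyed collections of :class:`Metabolite` and :class:`Reaction` plus
named :class:`Pathway` groupings.  Identifiers follow the dominant
community convention of ``<base>_<compartment>`` (e.g. ``glc__D_c``).
Serialization is canonical — sorted keys, entities ordered by id, floats
in shortest-repr form — so that writing the same model twice yields
byte-identical files.
"""

from __future__ import annotations

import copy as _copy
import json
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .formulas import ChemicalFormula, parse_formula

__all__ = [
    "Metabolite",
    "Reaction",
    "Model",
    "Pathway",
    "Direction",
    "DEFAULT_BOUNDS",
    "IntegrityError",
    "ModelFormatError",
    "build_stoichiometric_matrix",
    "StoichiometricMatrix",
    "read_model",
    "write_model",
    "find_by_cross_reference",
]

logger = logging.getLogger("pathcurator")

_MET_ID = re.compile(r"^[A-Za-z0-9_]+_[a-z0-9]+$")

_GENE_RULE_SEP = re.compile(r"\band\b|\bor\b|[()]", re.IGNORECASE)


class IntegrityError(ValueError):
    """A structural invariant of the model is violated."""


class ModelFormatError(ValueError):
    """A model document does not conform to the COBRA JSON schema subset."""


class Direction:
    """Declared reaction directionality, as stated by the source record."""

    REVERSIBLE = "reversible"
    FORWARD = "forward"
    BACKWARD = "backward"
    UNSPECIFIED = "unspecified"

    ALL = (REVERSIBLE, FORWARD, BACKWARD, UNSPECIFIED)


#: Default flux bounds (mmol·gDW⁻¹·h⁻¹) by declared direction.
DEFAULT_BOUNDS = {
    Direction.REVERSIBLE: (-1000.0, 1000.0),
    Direction.FORWARD: (0.0, 1000.0),
    Direction.BACKWARD: (-1000.0, 0.0),
    Direction.UNSPECIFIED: (-1000.0, 1000.0),
}


@dataclass
class Metabolite:
    """A compartmentalised chemical species.

    The id must end in ``_<tag>`` where ``tag`` equals ``compartment``.
    ``formula`` may be absent (a curation finding, not an error), and
    ``cross_refs`` carries identifiers.org-style namespaced annotations,
    e.g. ``{"kegg.compound": ["C00031"]}``.
    """

    id: str
    name: str = ""
    compartment: str = ""
    formula: ChemicalFormula | None = None
    charge: int | None = None
    cross_refs: dict[str, list[str]] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not _MET_ID.match(self.id):
            raise IntegrityError(
                f"metabolite id {self.id!r} must match <base>_<compartment-tag>"
            )
        tag = self.id.rsplit("_", 1)[1]
        if not self.compartment:
            self.compartment = tag
        elif tag != self.compartment:
            raise IntegrityError(
                f"metabolite {self.id!r}: id tag {tag!r} does not match "
                f"compartment {self.compartment!r}"
            )

    def copy(self) -> "Metabolite":
        return _copy.deepcopy(self)


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds.

    ``stoichiometry`` maps metabolite ids to signed coefficients
    (negative = consumed).  ``declared_direction`` records what the source
    database asserted, independently of the numeric bounds; the curation
    battery reports mismatches between the two.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = DEFAULT_BOUNDS[Direction.REVERSIBLE][0]
    upper_bound: float = DEFAULT_BOUNDS[Direction.REVERSIBLE][1]
    gene_rule: str = ""
    declared_direction: str = Direction.UNSPECIFIED
    cross_refs: dict[str, list[str]] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lower_bound = float(self.lower_bound)
        self.upper_bound = float(self.upper_bound)
        if self.lower_bound > self.upper_bound:
            raise IntegrityError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise IntegrityError(f"reaction {self.id!r}: empty stoichiometry")
        for met, coeff in list(self.stoichiometry.items()):
            if coeff == 0:
                raise IntegrityError(
                    f"reaction {self.id!r}: zero coefficient for {met!r}"
                )
            self.stoichiometry[met] = float(coeff)
        if self.declared_direction not in Direction.ALL:
            raise IntegrityError(
                f"reaction {self.id!r}: unknown direction "
                f"{self.declared_direction!r}"
            )

    @property
    def genes(self) -> set[str]:
        """Gene identifiers appearing in the gene rule."""
        if not self.gene_rule:
            return set()
        return {t.strip() for t in _GENE_RULE_SEP.split(self.gene_rule)
                if t.strip()}

    @property
    def substrates(self) -> list[str]:
        return sorted(m for m, c in self.stoichiometry.items() if c < 0)

    @property
    def products(self) -> list[str]:
        return sorted(m for m, c in self.stoichiometry.items() if c > 0)

    def copy(self) -> "Reaction":
        return _copy.deepcopy(self)


@dataclass
class Pathway:
    """An ordered, provenance-tracked set of reaction ids."""

    id: str
    reaction_ids: list[str] = field(default_factory=list)
    source: tuple[str, str] | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.reaction_ids:
            raise IntegrityError(f"pathway {self.id!r}: no reactions")
        if len(set(self.reaction_ids)) != len(self.reaction_ids):
            raise IntegrityError(f"pathway {self.id!r}: duplicate reaction ids")


class Model:
    """A compartmentalised collection of metabolites and reactions."""

    def __init__(self, id: str = "model"):
        self.id = id
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.pathways: dict[str, Pathway] = {}
        self.objective: dict[str, float] = {}
        self.compartments: dict[str, str] = {}
        self.extra: dict = {}

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.genes
        return out

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise IntegrityError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met
        self.compartments.setdefault(met.compartment, met.compartment)

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise IntegrityError(f"duplicate reaction id {rxn.id!r}")
        for mid in rxn.stoichiometry:
            if mid not in self.metabolites:
                raise IntegrityError(
                    f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                )
        self.reactions[rxn.id] = rxn

    def add_pathway(self, pathway: Pathway) -> None:
        for rid in pathway.reaction_ids:
            if rid not in self.reactions:
                raise IntegrityError(
                    f"pathway {pathway.id!r} references unknown reaction {rid!r}"
                )
        self.pathways[pathway.id] = pathway

    def validate(self) -> None:
        """Raise :class:`IntegrityError` on any dangling reference."""
        for rxn in self.reactions.values():
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise IntegrityError(
                        f"reaction {rxn.id!r} references unknown "
                        f"metabolite {mid!r}"
                    )
        for pw in self.pathways.values():
            for rid in pw.reaction_ids:
                if rid not in self.reactions:
                    raise IntegrityError(
                        f"pathway {pw.id!r} references unknown reaction {rid!r}"
                    )
        for rid in self.objective:
            if rid not in self.reactions:
                raise IntegrityError(
                    f"objective references unknown reaction {rid!r}"
                )

    def copy(self) -> "Model":
        return _copy.deepcopy(self)

    def __repr__(self) -> str:
        return (
            f"<Model {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, {len(self.pathways)} pathways>"
        )


class StoichiometricMatrix(NamedTuple):
    matrix: np.ndarray
    metabolite_ids: list[str]
    reaction_ids: list[str]


def build_stoichiometric_matrix(model: Model) -> StoichiometricMatrix:
    """Dense S matrix: rows = metabolites, columns = reactions, id-sorted."""
    model.validate()
    met_ids = sorted(model.metabolites)
    rxn_ids = sorted(model.reactions)
    row = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, rid in enumerate(rxn_ids):
        for mid, coeff in model.reactions[rid].stoichiometry.items():
            S[row[mid], j] = coeff
    return StoichiometricMatrix(S, met_ids, rxn_ids)


def find_by_cross_reference(
    model: Model, namespace: str, identifier: str
) -> str | None:
    """Id of the first (id-sorted) entity annotated ``namespace:identifier``."""
    entities: list[tuple[str, dict]] = [
        (m.id, m.cross_refs) for m in model.metabolites.values()
    ] + [(r.id, r.cross_refs) for r in model.reactions.values()]
    for eid, refs in sorted(entities):
        if identifier in refs.get(namespace, []):
            return eid
    return None


# ---------------------------------------------------------------------------
# COBRA JSON interchange
# ---------------------------------------------------------------------------

_MET_KEYS = {"id", "name", "compartment", "formula", "charge", "annotation",
             "notes"}
_RXN_KEYS = {"id", "name", "metabolites", "lower_bound", "upper_bound",
             "gene_reaction_rule", "objective_coefficient", "annotation",
             "notes"}
_TOP_KEYS = {"id", "metabolites", "reactions", "genes", "compartments",
             "notes", "annotation", "version"}


def _require(doc: dict, key: str, path: str):
    if key not in doc:
        raise ModelFormatError(f"missing key {path}/{key}")
    return doc[key]


def _met_from_dict(d: dict, path: str) -> Metabolite:
    mid = _require(d, "id", path)
    formula = d.get("formula")
    parsed = parse_formula(formula) if formula else None
    extra = {k: v for k, v in d.items() if k not in _MET_KEYS}
    if extra:
        logger.info("metabolite %s: preserving unknown keys %s",
                    mid, sorted(extra))
    try:
        return Metabolite(
            id=mid,
            name=d.get("name", ""),
            compartment=d.get("compartment", ""),
            formula=parsed,
            charge=d.get("charge"),
            cross_refs={k: list(v) for k, v in d.get("annotation", {}).items()},
            extra=extra,
        )
    except IntegrityError as exc:
        raise ModelFormatError(f"{path}: {exc}") from exc


def _rxn_from_dict(d: dict, path: str) -> Reaction:
    rid = _require(d, "id", path)
    notes = d.get("notes", {})
    extra = {k: v for k, v in d.items() if k not in _RXN_KEYS}
    if extra:
        logger.info("reaction %s: preserving unknown keys %s", rid, sorted(extra))
    try:
        return Reaction(
            id=rid,
            name=d.get("name", ""),
            stoichiometry=dict(_require(d, "metabolites", path)),
            lower_bound=_require(d, "lower_bound", path),
            upper_bound=_require(d, "upper_bound", path),
            gene_rule=d.get("gene_reaction_rule", ""),
            declared_direction=notes.get("declared_direction",
                                         Direction.UNSPECIFIED),
            cross_refs={k: list(v) for k, v in d.get("annotation", {}).items()},
            extra=extra,
        )
    except IntegrityError as exc:
        raise ModelFormatError(f"{path}: {exc}") from exc


def read_model(path) -> Model:
    """Read a COBRA JSON model document."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ModelFormatError("top-level document must be an object")
    model = Model(id=_require(doc, "id", ""))
    model.compartments = dict(doc.get("compartments", {}))
    for i, md in enumerate(_require(doc, "metabolites", "")):
        model.add_metabolite(_met_from_dict(md, f"metabolites[{i}]"))
    for i, rd in enumerate(_require(doc, "reactions", "")):
        rxn = _rxn_from_dict(rd, f"reactions[{i}]")
        model.add_reaction(rxn)
        oc = rd.get("objective_coefficient", 0)
        if oc:
            model.objective[rxn.id] = float(oc)
    notes = doc.get("notes", {})
    for pid, pd in notes.get("pathways", {}).items():
        src = pd.get("source")
        model.add_pathway(Pathway(
            id=pid,
            reaction_ids=list(pd["reaction_ids"]),
            source=tuple(src) if src else None,
            notes=pd.get("notes", ""),
        ))
    model.extra = {k: v for k, v in doc.items() if k not in _TOP_KEYS}
    if model.extra:
        logger.info("model %s: preserving unknown keys %s",
                    model.id, sorted(model.extra))
    model.validate()
    return model


def _met_to_dict(met: Metabolite) -> dict:
    d = {
        "id": met.id,
        "name": met.name,
        "compartment": met.compartment,
        "annotation": {k: sorted(v) for k, v in sorted(met.cross_refs.items())},
    }
    if met.formula is not None:
        d["formula"] = str(met.formula)
    if met.charge is not None:
        d["charge"] = met.charge
    d.update(met.extra)
    return d


def _rxn_to_dict(rxn: Reaction, objective: dict[str, float]) -> dict:
    d = {
        "id": rxn.id,
        "name": rxn.name,
        "metabolites": dict(sorted(rxn.stoichiometry.items())),
        "lower_bound": rxn.lower_bound,
        "upper_bound": rxn.upper_bound,
        "gene_reaction_rule": rxn.gene_rule,
        "annotation": {k: sorted(v) for k, v in sorted(rxn.cross_refs.items())},
    }
    if rxn.declared_direction != Direction.UNSPECIFIED:
        d["notes"] = {"declared_direction": rxn.declared_direction}
    if rxn.id in objective:
        d["objective_coefficient"] = objective[rxn.id]
    d.update(rxn.extra)
    return d


def model_to_dict(model: Model) -> dict:
    doc = {
        "id": model.id,
        "version": "1",
        "compartments": dict(sorted(model.compartments.items())),
        "metabolites": [_met_to_dict(model.metabolites[m])
                        for m in sorted(model.metabolites)],
        "reactions": [_rxn_to_dict(model.reactions[r], model.objective)
                      for r in sorted(model.reactions)],
        "genes": [{"id": g, "name": g} for g in sorted(model.genes)],
    }
    if model.pathways:
        pws = {}
        for pid in sorted(model.pathways):
            pw = model.pathways[pid]
            pws[pid] = {
                "reaction_ids": list(pw.reaction_ids),
                "source": list(pw.source) if pw.source else None,
                "notes": pw.notes,
            }
        doc["notes"] = {"pathways": pws}
    doc.update(model.extra)
    return doc


def write_model(model: Model, path) -> None:
    """Write ``model`` as canonical COBRA JSON (byte-stable)."""
    model.validate()
    doc = model_to_dict(model)
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, indent=1)
        fh.write("\n")
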