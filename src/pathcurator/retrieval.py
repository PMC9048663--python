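"""Record retrieval, dialect parsing and conversion to model objects.

Records come from a local cache directory laid out as
``<cache>/<source>/<kind>/<identifier>.<ext>`` (``kegg`` records as
flat-file ``.txt``, ``biocyc`` as ptools ``.xml``, ``bigg`` as ``.json``).
A cache miss falls through to a *provider* — any object with a
``get(source, kind, identifier) -> str`` method — after which the raw text
is cached verbatim so subsequent runs are reproducible without the
provider.  The default provider used throughout the test-suite serves
bundled fixture texts from a dictionary; no network access is involved
anywhere in this module.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from .formulas import ChemicalFormula, parse_formula
from .model_core import (
    DEFAULT_BOUNDS,
    Direction,
    Metabolite,
    Model,
    Pathway,
    Reaction,
    find_by_cross_reference,
    logger,
)

__all__ = [
    "DatabaseRecord",
    "MetaboliteRecord",
    "ReactionRecord",
    "PathwayTemplate",
    "Participant",
    "ParseError",
    "RetrievalError",
    "DictProvider",
    "fetch_record",
    "parse_kegg",
    "parse_biocyc",
    "parse_bigg",
    "parse_user_table",
    "create_object",
]

SOURCES = ("kegg", "biocyc", "bigg", "user")
KINDS = ("metabolite", "reaction", "pathway")

CACHE_EXT = {"kegg": "txt", "biocyc": "xml", "bigg": "json", "user": "txt"}

#: identifiers.org namespace used for each (source, kind) annotation.
CROSS_REF_NAMESPACE = {
    ("kegg", "reaction"): "kegg.reaction",
    ("kegg", "metabolite"): "kegg.compound",
    ("biocyc", "reaction"): "biocyc",
    ("biocyc", "metabolite"): "biocyc",
    ("bigg", "reaction"): "bigg.reaction",
    ("bigg", "metabolite"): "bigg.metabolite",
}


class ParseError(ValueError):
    """A record text does not match its dialect grammar."""


class RetrievalError(RuntimeError):
    """A record could not be obtained (offline cache miss, provider miss)."""


@dataclass
class Participant:
    """One metabolite slot of a reaction record.

    ``compartment`` is set when the dialect itself assigns compartments
    (BiGG); ``in_model_namespace`` marks user records whose identifiers
    are already full model ids (e.g. ``atp_c``).
    """

    identifier: str
    coefficient: float
    compartment: str | None = None
    in_model_namespace: bool = False


@dataclass
class MetaboliteRecord:
    identifier: str
    name: str = ""
    formula: ChemicalFormula | None = None
    charge: int | None = None
    cross_refs: dict[str, list[str]] = field(default_factory=dict)
    compartment: str | None = None


@dataclass
class ReactionRecord:
    identifier: str
    name: str = ""
    participants: list[Participant] = field(default_factory=list)
    direction: str = Direction.UNSPECIFIED
    cross_refs: dict[str, list[str]] = field(default_factory=dict)
    genes: list[str] = field(default_factory=list)
    bounds: tuple[float, float] | None = None

    @property
    def stoichiometry(self) -> dict[str, float]:
        return {p.identifier: p.coefficient for p in self.participants}


@dataclass
class PathwayTemplate:
    identifier: str
    reaction_identifiers: list[str] = field(default_factory=list)
    gene_associations: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: list[str] = []
        for rid in self.reaction_identifiers:
            if rid not in seen:
                seen.append(rid)
        self.reaction_identifiers = seen


@dataclass
class DatabaseRecord:
    source: str
    identifier: str
    kind: str
    raw: str
    parsed: MetaboliteRecord | ReactionRecord | PathwayTemplate


class DictProvider:
    """Provider backed by an in-memory mapping of fixture texts.

    Keys are ``(source, kind, identifier)`` tuples.  ``calls`` counts
    provider invocations, which lets tests verify cache behaviour.
    """

    def __init__(self, records: dict[tuple[str, str, str], str]):
        self.records = dict(records)
        self.calls = 0

    def get(self, source: str, kind: str, identifier: str) -> str:
        self.calls += 1
        try:
            return self.records[(source, kind, identifier)]
        except KeyError:
            raise RetrievalError(
                f"provider has no record for {source}/{kind}/{identifier}"
            ) from None


# ---------------------------------------------------------------------------
# KEGG flat-file dialect
# ---------------------------------------------------------------------------

_KEGG_TERM = re.compile(r"^(?:(\d+)\s+)?([A-Za-z]\w*)$")


def _kegg_side(side: str, which: str) -> list[tuple[str, float]]:
    terms = [t.strip() for t in side.split(" + ")]
    out = []
    for term in terms:
        if not term:
            raise ParseError(f"empty term on {which} side of EQUATION")
        m = _KEGG_TERM.match(term)
        if m is None:
            raise ParseError(f"unparseable EQUATION token {term!r}")
        coeff = int(m.group(1)) if m.group(1) else 1
        out.append((m.group(2), float(coeff)))
    return out


def parse_kegg(text: str) -> DatabaseRecord:
    """Parse a KEGG flat-file record (reaction, compound or module subset).

    The layout is the classic 12-column keyword field with indented
    continuation lines, terminated by ``///``.
    """
    lines = text.splitlines()
    if not any(line.strip() == "///" for line in lines):
        raise ParseError("KEGG record lacks '///' terminator")
    fields: dict[str, list[str]] = {}
    keyword = None
    for line in lines:
        if line.strip() == "///":
            break
        if not line.strip():
            continue
        if line[:1] != " ":
            keyword = line[:12].strip()
            fields.setdefault(keyword, []).append(line[12:].strip())
        else:
            if keyword is None:
                raise ParseError("continuation line before any keyword")
            fields[keyword].append(line[12:].strip())
    if "ENTRY" not in fields:
        raise ParseError("KEGG record lacks ENTRY field")
    entry_tokens = fields["ENTRY"][0].split()
    if not entry_tokens:
        raise ParseError("empty ENTRY field")
    identifier = entry_tokens[0]
    entry_type = entry_tokens[-1].lower() if len(entry_tokens) > 1 else ""
    name = fields.get("NAME", [""])[0].rstrip(";")

    if "EQUATION" in fields or entry_type == "reaction":
        equation = " ".join(fields["EQUATION"])
        if "<=>" not in equation:
            raise ParseError(f"EQUATION lacks '<=>' arrow: {equation!r}")
        lhs, rhs = equation.split("<=>", 1)
        stoich: dict[str, float] = {}
        participants = []
        for cid, coeff in _kegg_side(lhs.strip(), "left"):
            stoich[cid] = stoich.get(cid, 0) - coeff
        for cid, coeff in _kegg_side(rhs.strip(), "right"):
            stoich[cid] = stoich.get(cid, 0) + coeff
        participants = [Participant(cid, c) for cid, c in stoich.items() if c]
        refs = {"kegg.reaction": [identifier]}
        if "ENZYME" in fields:
            refs["ec-code"] = " ".join(fields["ENZYME"]).split()
        parsed: object = ReactionRecord(
            identifier=identifier,
            name=name,
            participants=participants,
            direction=Direction.REVERSIBLE,
            cross_refs=refs,
        )
        kind = "reaction"
    elif "FORMULA" in fields or entry_type == "compound":
        formula = fields.get("FORMULA", [None])[0]
        parsed = MetaboliteRecord(
            identifier=identifier,
            name=name,
            formula=parse_formula(formula) if formula else None,
            cross_refs={"kegg.compound": [identifier]},
        )
        kind = "metabolite"
    elif "REACTION" in fields or entry_type in ("module", "pathway"):
        tokens = []
        for chunk in fields.get("REACTION", []):
            tokens.extend(t for t in re.split(r"[\s,]+", chunk) if t)
        parsed = PathwayTemplate(identifier=identifier,
                                 reaction_identifiers=tokens)
        kind = "pathway"
    else:
        raise ParseError(
            f"cannot determine record kind of KEGG entry {identifier!r}"
        )
    return DatabaseRecord("kegg", identifier, kind, text, parsed)


# ---------------------------------------------------------------------------
# BioCyc ptools-xml dialect
# ---------------------------------------------------------------------------

_BIOCYC_DIRECTION = {
    "LEFT-TO-RIGHT": Direction.FORWARD,
    "RIGHT-TO-LEFT": Direction.BACKWARD,
    "REVERSIBLE": Direction.REVERSIBLE,
}


def _biocyc_sides(rxn_el, tag: str, sign: float) -> list[Participant]:
    out = []
    for side in rxn_el.findall(tag):
        ref = None
        coeff = 1.0
        for child in side:
            if child.tag in ("Compound", "Protein"):
                ref = child.get("frameid")
            elif child.tag == "coefficient":
                coeff = float(child.text.strip())
        if ref is None:
            raise ParseError(f"<{tag}> without Compound/Protein reference")
        out.append(Participant(ref, sign * coeff))
    if not out:
        raise ParseError(f"reaction has empty <{tag}> side")
    return out


def parse_biocyc(text: str) -> DatabaseRecord:
    """Parse a BioCyc web-service XML record (ptools-xml subset)."""
    try:
        root = etree.fromstring(text.encode())
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"invalid XML: {exc}") from exc
    if root.tag != "ptools-xml":
        raise ParseError(f"root element is {root.tag!r}, expected ptools-xml")

    rxn_el = root.find("Reaction")
    if rxn_el is not None:
        frameid = rxn_el.get("frameid")
        if not frameid:
            raise ParseError("Reaction element lacks frameid")
        participants = _biocyc_sides(rxn_el, "left", -1.0)
        participants += _biocyc_sides(rxn_el, "right", +1.0)
        dir_el = rxn_el.find("reaction-direction")
        direction = Direction.UNSPECIFIED
        if dir_el is not None and dir_el.text:
            literal = dir_el.text.strip().upper()
            literal = literal.removeprefix("PHYSIOL-")
            if literal not in _BIOCYC_DIRECTION:
                raise ParseError(f"unknown reaction-direction {dir_el.text!r}")
            direction = _BIOCYC_DIRECTION[literal]
        genes = [g.get("frameid") for g in rxn_el.findall(".//Gene")
                 if g.get("frameid")]
        parsed: object = ReactionRecord(
            identifier=frameid,
            name=(rxn_el.findtext("common-name") or "").strip(),
            participants=participants,
            direction=direction,
            cross_refs={"biocyc": [frameid]},
            genes=genes,
        )
        return DatabaseRecord("biocyc", frameid, "reaction", text, parsed)

    cpd_el = root.find("Compound")
    if cpd_el is not None:
        frameid = cpd_el.get("frameid")
        if not frameid:
            raise ParseError("Compound element lacks frameid")
        formula = None
        f_el = cpd_el.find(".//formula")
        if f_el is not None:
            concise = f_el.get("concise") or (f_el.text or "")
            if concise.strip():
                formula = parse_formula(concise.replace(" ", ""))
        charge = None
        mol = cpd_el.find(".//molecule")
        if mol is not None and mol.get("formalCharge") is not None:
            charge = int(mol.get("formalCharge"))
        parsed = MetaboliteRecord(
            identifier=frameid,
            name=(cpd_el.findtext("common-name") or "").strip(),
            formula=formula,
            charge=charge,
            cross_refs={"biocyc": [frameid]},
        )
        return DatabaseRecord("biocyc", frameid, "metabolite", text, parsed)

    pwy_el = root.find("Pathway")
    if pwy_el is not None:
        frameid = pwy_el.get("frameid")
        if not frameid:
            raise ParseError("Pathway element lacks frameid")
        rl = pwy_el.find("reaction-list")
        if rl is None:
            raise ParseError(f"Pathway {frameid!r} lacks reaction-list")
        rids = [r.get("frameid") for r in rl.findall("Reaction")]
        if not all(rids):
            raise ParseError("reaction-list entry lacks frameid")
        parsed = PathwayTemplate(identifier=frameid, reaction_identifiers=rids)
        return DatabaseRecord("biocyc", frameid, "pathway", text, parsed)

    raise ParseError("no Reaction, Compound or Pathway element found")


# ---------------------------------------------------------------------------
# BiGG JSON dialect
# ---------------------------------------------------------------------------


def parse_bigg(text: str) -> DatabaseRecord:
    """Parse a BiGG-style JSON record (reaction or metabolite)."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "bigg_id" not in doc:
        raise ParseError("BiGG record lacks bigg_id")
    bigg_id = doc["bigg_id"]

    if isinstance(doc.get("metabolites"), list):
        if doc.get("pseudoreaction"):
            raise ParseError(
                f"BiGG reaction {bigg_id!r} is a pseudoreaction "
                "(exchange/biomass); not importable pathway content"
            )
        participants = []
        for entry in doc["metabolites"]:
            participants.append(Participant(
                identifier=entry["bigg_id"],
                coefficient=float(entry["stoichiometry"]),
                compartment=entry.get("compartment_bigg_id"),
            ))
        if not participants:
            raise ParseError(f"BiGG reaction {bigg_id!r} has no metabolites")
        parsed: object = ReactionRecord(
            identifier=bigg_id,
            name=doc.get("name", ""),
            participants=participants,
            direction=Direction.UNSPECIFIED,
            cross_refs={"bigg.reaction": [bigg_id]},
        )
        return DatabaseRecord("bigg", bigg_id, "reaction", text, parsed)

    formulae = doc.get("formulae", [])
    charges = doc.get("charges", [])
    parsed = MetaboliteRecord(
        identifier=bigg_id,
        name=doc.get("name", ""),
        formula=parse_formula(formulae[0]) if formulae else None,
        charge=int(charges[0]) if charges else None,
        cross_refs={"bigg.metabolite": [bigg_id]},
    )
    return DatabaseRecord("bigg", bigg_id, "metabolite", text, parsed)


# ---------------------------------------------------------------------------
# User text format
# ---------------------------------------------------------------------------

_ARROWS = [("<->", Direction.REVERSIBLE), ("->", Direction.FORWARD),
           ("<-", Direction.BACKWARD)]

_USER_TERM = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$")


def _user_side(side: str, lineno: int, col: int) -> list[tuple[str, float]]:
    side = side.strip()
    if not side:
        raise ParseError(f"line {lineno}, column {col}: empty reaction side")
    out = []
    for term in (t.strip() for t in side.split(",")):
        m = _USER_TERM.match(term)
        if m is None:
            raise ParseError(
                f"line {lineno}, column {col}: bad term {term!r}"
            )
        out.append((m.group(2), float(m.group(1)) if m.group(1) else 1.0))
    return out


def parse_user_table(text: str) -> list[DatabaseRecord]:
    """Parse the user-curated text format.

    ``#`` starts a comment.  Metabolite lines:
    ``M <id>, <name>, <compartment>, <formula|->, <charge|->``.
    Reaction lines:
    ``R <id>[, <name>] | <side> <arrow> <side> [| <lb>, <ub>]`` with terms
    ``[coef ]met_id`` comma-separated and arrows ``->``, ``<->``, ``<-``.
    """
    records: list[DatabaseRecord] = []
    seen: set[str] = set()
    for lineno, rawline in enumerate(text.splitlines(), start=1):
        line = rawline.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        tag, _, rest = line.strip().partition(" ")
        if tag == "M":
            parts = [p.strip() for p in rest.split(",")]
            if len(parts) != 5:
                raise ParseError(
                    f"line {lineno}, column 1: metabolite line needs "
                    f"5 comma-separated fields, got {len(parts)}"
                )
            mid, name, comp, formula, charge = parts
            if not mid:
                raise ParseError(f"line {lineno}, column 3: empty id")
            parsed: object = MetaboliteRecord(
                identifier=mid,
                name=name,
                formula=None if formula == "-" else parse_formula(formula),
                charge=None if charge == "-" else int(charge),
                compartment=comp,
            )
            record = DatabaseRecord("user", mid, "metabolite", rawline, parsed)
        elif tag == "R":
            groups = [g.strip() for g in rest.split("|")]
            if len(groups) not in (2, 3):
                raise ParseError(
                    f"line {lineno}, column 1: reaction line needs "
                    "'header | equation [| bounds]'"
                )
            header, equation = groups[0], groups[1]
            rid, _, name = (s.strip() for s in header.partition(","))
            if not rid:
                raise ParseError(f"line {lineno}, column 3: empty id")
            arrow = direction = None
            for a, d in _ARROWS:
                if a in equation:
                    arrow, direction = a, d
                    break
            if arrow is None:
                raise ParseError(
                    f"line {lineno}, column {line.find('|') + 2}: "
                    "equation lacks an arrow (->, <->, <-)"
                )
            lhs, rhs = equation.split(arrow, 1)
            col = line.find("|") + 2
            stoich: dict[str, float] = {}
            for mid2, coeff in _user_side(lhs, lineno, col):
                stoich[mid2] = stoich.get(mid2, 0) - coeff
            for mid2, coeff in _user_side(rhs, lineno,
                                          col + equation.find(arrow)):
                stoich[mid2] = stoich.get(mid2, 0) + coeff
            bounds = None
            if len(groups) == 3:
                try:
                    lb, ub = (float(x) for x in groups[2].split(","))
                except ValueError:
                    raise ParseError(
                        f"line {lineno}: bounds group must be '<lb>, <ub>'"
                    ) from None
                bounds = (lb, ub)
            parsed = ReactionRecord(
                identifier=rid,
                name=name,
                participants=[
                    Participant(m, c, in_model_namespace=True)
                    for m, c in stoich.items() if c
                ],
                direction=direction,
                bounds=bounds,
            )
            record = DatabaseRecord("user", rid, "reaction", rawline, parsed)
        else:
            raise ParseError(
                f"line {lineno}, column 1: unknown line tag {tag!r}"
            )
        if record.identifier in seen:
            raise ParseError(
                f"line {lineno}: duplicate id {record.identifier!r}"
            )
        seen.add(record.identifier)
        records.append(record)
    return records


# ---------------------------------------------------------------------------
# Fetching and conversion
# ---------------------------------------------------------------------------

_DIALECT_PARSERS = {"kegg": parse_kegg, "biocyc": parse_biocyc,
                    "bigg": parse_bigg}


def cache_path(cache_dir, source: str, kind: str, identifier: str) -> Path:
    return (Path(cache_dir) / source / kind /
            f"{identifier}.{CACHE_EXT[source]}")


def fetch_record(source: str, identifier: str, kind: str, cache_dir,
                 offline: bool = False, provider=None) -> DatabaseRecord:
    """Obtain a record from the local cache, or from ``provider`` on a miss.

    Freshly fetched raw text is stored verbatim in the cache so the next
    call is served locally.  With ``offline=True`` a cache miss is an
    error naming the expected path.
    """
    if source not in _DIALECT_PARSERS:
        raise ValueError(f"unknown source {source!r}")
    if kind not in KINDS:
        raise ValueError(f"unknown record kind {kind!r}")
    path = cache_path(cache_dir, source, kind, identifier)
    if path.exists():
        raw = path.read_text()
    else:
        if offline or provider is None:
            raise RetrievalError(
                f"record {source}/{kind}/{identifier} is not cached "
                f"(expected at {path}) and no provider is available"
            )
        raw = provider.get(source, kind, identifier)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(raw)
    record = _DIALECT_PARSERS[source](raw)
    if record.kind != kind:
        raise ParseError(
            f"record {identifier!r} parsed as kind {record.kind!r}, "
            f"expected {kind!r}"
        )
    return record


def make_fetcher(cache_dir, offline: bool = False, provider=None):
    """A ``fetcher(source, kind, identifier)`` callable bound to a cache.

    This is the dependency-resolution hook :func:`create_object` expects;
    it simply reorders arguments into :func:`fetch_record`.
    """
    def fetcher(source: str, kind: str, identifier: str) -> DatabaseRecord:
        return fetch_record(source, identifier, kind, cache_dir,
                            offline=offline, provider=provider)
    return fetcher


def normalize_id(identifier: str) -> str:
    """Rewrite a database identifier into the model id character set."""
    return re.sub(r"[^A-Za-z0-9_]", "_", identifier)


def _metabolite_from_record(rec: MetaboliteRecord, source: str,
                            compartment: str) -> Metabolite:
    comp = rec.compartment or compartment
    if rec.compartment and "_" in rec.identifier and \
            rec.identifier.rsplit("_", 1)[1] == rec.compartment:
        mid = normalize_id(rec.identifier)  # user id already suffixed
    else:
        mid = f"{normalize_id(rec.identifier)}_{comp}"
    refs = {k: list(v) for k, v in rec.cross_refs.items()}
    return Metabolite(id=mid, name=rec.name or rec.identifier,
                      compartment=comp, formula=rec.formula,
                      charge=rec.charge, cross_refs=refs)


def _resolve_participant(p: Participant, source: str, compartment: str,
                         model: Model, fetcher, missing: list[str]) -> str:
    comp = p.compartment or compartment
    if p.in_model_namespace:
        candidate = p.identifier
    else:
        candidate = f"{normalize_id(p.identifier)}_{comp}"
    if candidate in model.metabolites:
        return candidate
    ns = CROSS_REF_NAMESPACE.get((source, "metabolite"))
    if ns is not None:
        hit = find_by_cross_reference(model, ns, p.identifier)
        if hit is not None and hit in model.metabolites:
            return hit
    # stub creation from the cached metabolite record
    if source == "user" or p.in_model_namespace:
        stub = Metabolite(id=candidate, name=p.identifier, compartment=comp)
        model.add_metabolite(stub)
        logger.warning("created bare metabolite stub %s (no formula)",
                       candidate)
        return candidate
    if fetcher is not None:
        try:
            met_rec = fetcher(source, "metabolite", p.identifier)
        except (RetrievalError, KeyError):
            met_rec = None
        if met_rec is not None:
            stub = _metabolite_from_record(met_rec.parsed, source, comp)
            if stub.id not in model.metabolites:
                model.add_metabolite(stub)
            return stub.id
    missing.append(f"{source}/metabolite/{p.identifier}")
    return candidate


def create_object(record: DatabaseRecord, target_compartment: str,
                  model: Model, fetcher=None):
    """Convert a parsed record into a model-namespace object.

    ``fetcher(source, kind, identifier) -> DatabaseRecord`` is used to
    pull dependent records (a pathway's reactions; participant metabolite
    stubs) on demand; wire it to :func:`fetch_record` with the desired
    cache/provider.  Participant metabolite stubs are added to ``model``
    directly; the principal object is returned un-added so it can go
    through curation first.  If the model already holds an entity
    cross-referenced to this record, that entity is returned instead.
    """
    if target_compartment not in model.compartments:
        logger.warning("auto-registering compartment %r", target_compartment)
        model.compartments[target_compartment] = target_compartment

    parsed = record.parsed
    if isinstance(parsed, MetaboliteRecord):
        ns = CROSS_REF_NAMESPACE.get((record.source, "metabolite"))
        if ns:
            hit = find_by_cross_reference(model, ns, record.identifier)
            if hit in model.metabolites:
                return model.metabolites[hit]
        met = _metabolite_from_record(parsed, record.source,
                                      target_compartment)
        if met.id in model.metabolites:
            return model.metabolites[met.id]
        return met

    if isinstance(parsed, ReactionRecord):
        ns = CROSS_REF_NAMESPACE.get((record.source, "reaction"))
        if ns:
            hit = find_by_cross_reference(model, ns, record.identifier)
            if hit in model.reactions:
                return model.reactions[hit]
        missing: list[str] = []
        stoich: dict[str, float] = {}
        for p in parsed.participants:
            mid = _resolve_participant(p, record.source, target_compartment,
                                       model, fetcher, missing)
            stoich[mid] = stoich.get(mid, 0) + p.coefficient
        if missing:
            raise RetrievalError(
                "unresolvable reaction participants; missing records: "
                + ", ".join(missing)
            )
        bounds = parsed.bounds or DEFAULT_BOUNDS[parsed.direction]
        refs = {k: list(v) for k, v in parsed.cross_refs.items()}
        gene_rule = " or ".join(sorted(set(parsed.genes)))
        return Reaction(
            id=normalize_id(parsed.identifier),
            name=parsed.name or parsed.identifier,
            stoichiometry={m: c for m, c in stoich.items() if c},
            lower_bound=bounds[0],
            upper_bound=bounds[1],
            gene_rule=gene_rule,
            declared_direction=parsed.direction,
            cross_refs=refs,
        )

    if isinstance(parsed, PathwayTemplate):
        if fetcher is None:
            raise RetrievalError(
                "converting a pathway requires a fetcher for its reactions"
            )
        staged: list[Reaction] = []
        rids: list[str] = []
        for db_rid in parsed.reaction_identifiers:
            rrec = fetcher(record.source, "reaction", db_rid)
            rxn = create_object(rrec, target_compartment, model, fetcher)
            genes = parsed.gene_associations.get(db_rid, [])
            if genes and not rxn.gene_rule:
                rxn.gene_rule = " or ".join(sorted(set(genes)))
            if rxn.id not in rids:
                rids.append(rxn.id)
                staged.append(rxn)
        pathway = Pathway(
            id=normalize_id(parsed.identifier),
            reaction_ids=rids,
            source=(record.source, record.identifier),
        )
        pathway.staged_reactions = staged
        return pathway

    raise TypeError(f"cannot convert record of type {type(parsed).__name__}")
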