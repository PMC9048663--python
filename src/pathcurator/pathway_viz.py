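"""Pathway ordering, Escher map generation and flux-to-colour styling.

Maps are emitted as the Escher map JSON standard — a two-element array of
header and body, with node/segment geometry — laid out automatically:
reactions left-to-right along a main axis in topological order, chain-link
metabolites shared between consecutive reactions on the axis, cofactors
fanned above (substrates) and below (products).  Flux overlays are
expressed as a sidecar style document (reaction id → colour/stroke width)
since the map standard itself carries geometry only.
"""

from __future__ import annotations

import heapq
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

from scipy.stats import rankdata

from .model_core import Direction, Model, Pathway

__all__ = [
    "EscherMap",
    "GradientSpec",
    "DEFAULT_GRADIENT",
    "MapError",
    "order_reactions",
    "build_escher_map",
    "map_flux_to_style",
    "write_escher_json",
    "read_escher_json",
]

ESCHER_SCHEMA = "https://escher.github.io/escher/jsonschema/1-0-0#"
MAIN_Y = 300.0
SIDE_DY = 80.0


class MapError(ValueError):
    """A map document violates the geometry invariants."""


@dataclass
class EscherMap:
    header: dict
    reactions: dict = field(default_factory=dict)
    nodes: dict = field(default_factory=dict)
    text_labels: dict = field(default_factory=dict)
    canvas: dict = field(default_factory=dict)

    def body(self) -> dict:
        return {
            "reactions": self.reactions,
            "nodes": self.nodes,
            "text_labels": self.text_labels,
            "canvas": self.canvas,
        }

    def validate(self) -> None:
        ids = sorted(int(i) for i in self.nodes)
        if ids != list(range(len(ids))):
            raise MapError("node ids must be consecutive integers from 0")
        for rid, rxn in self.reactions.items():
            mid_reached = False
            for sid, seg in rxn["segments"].items():
                for end in ("from_node_id", "to_node_id"):
                    if seg[end] not in self.nodes:
                        raise MapError(
                            f"segment {sid} of reaction {rid} references "
                            f"missing node {seg[end]!r}"
                        )
                    if self.nodes[seg[end]]["node_type"] in ("midmarker",
                                                             "multimarker"):
                        mid_reached = True
            if not mid_reached:
                raise MapError(
                    f"reaction {rid} has no midmarker reachable via its "
                    "segments"
                )


@dataclass
class GradientSpec:
    """Colour gradient with a normalization mode.

    ``stops`` are (position, "#RRGGBB") pairs; positions strictly increase
    from 0 to 1.  ``normalization`` is ``linear`` (min-max on flux
    magnitudes) or ``quantile`` (average ranks), matching the two ways a
    flux distribution can be mapped onto the gradient.
    """

    stops: list[tuple[float, str]]
    normalization: str = "linear"

    def __post_init__(self) -> None:
        if len(self.stops) < 2:
            raise ValueError("gradient needs at least 2 stops")
        positions = [p for p, _ in self.stops]
        if positions[0] != 0 or positions[-1] != 1:
            raise ValueError("gradient stops must start at 0 and end at 1")
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("gradient positions must strictly increase")
        for _, color in self.stops:
            if not re.fullmatch(r"#[0-9A-Fa-f]{6}", color):
                raise ValueError(f"bad hex colour {color!r}")
        if self.normalization not in ("linear", "quantile"):
            raise ValueError(
                f"unknown normalization {self.normalization!r}"
            )


DEFAULT_GRADIENT = GradientSpec(
    stops=[(0.0, "#FFFFFF"), (1.0, "#FF0000")], normalization="linear"
)


def _oriented(rxn) -> tuple[list[str], list[str]]:
    """(substrates, products) under declared/bound-implied direction;
    reversible reactions keep their stoichiometric orientation."""
    subs, prods = rxn.substrates, rxn.products
    backward = rxn.declared_direction == Direction.BACKWARD or (
        rxn.declared_direction == Direction.UNSPECIFIED
        and rxn.upper_bound <= 0
    )
    return (prods, subs) if backward else (subs, prods)


def order_reactions(pathway: Pathway, model: Model) -> list[str]:
    """Deterministic topological order of the pathway's reactions.

    Edge u→v whenever a product of u is a substrate of v.  Kahn's
    algorithm with lexicographic tie-breaking; a cycle is broken by
    releasing its lexicographically smallest reaction; weakly connected
    components are concatenated by smallest member id.
    """
    rids = list(pathway.reaction_ids)
    for rid in rids:
        if rid not in model.reactions:
            raise KeyError(f"pathway reaction {rid!r} not in model")
    out_edges: dict[str, set[str]] = {r: set() for r in rids}
    indeg: dict[str, int] = {r: 0 for r in rids}
    oriented = {r: _oriented(model.reactions[r]) for r in rids}
    for u in rids:
        for v in rids:
            if u == v:
                continue
            if set(oriented[u][1]) & set(oriented[v][0]):
                if v not in out_edges[u]:
                    out_edges[u].add(v)
                    indeg[v] += 1

    # weakly connected components of the edge graph
    comp_of: dict[str, int] = {}
    comps: list[list[str]] = []
    for r in sorted(rids):
        if r in comp_of:
            continue
        stack, members = [r], []
        comp_of[r] = len(comps)
        while stack:
            u = stack.pop()
            members.append(u)
            neighbours = out_edges[u] | {w for w in rids if u in out_edges[w]}
            for w in neighbours:
                if w not in comp_of:
                    comp_of[w] = len(comps)
                    stack.append(w)
        comps.append(members)
    comps.sort(key=min)

    order: list[str] = []
    for members in comps:
        local_indeg = {r: indeg[r] for r in members}
        done: set[str] = set()
        heap = [r for r in members if local_indeg[r] == 0]
        heapq.heapify(heap)
        while len(done) < len(members):
            if not heap:
                # cycle: release the smallest remaining id
                smallest = min(r for r in members if r not in done)
                local_indeg[smallest] = 0
                heapq.heappush(heap, smallest)
            u = heapq.heappop(heap)
            if u in done:
                continue
            done.add(u)
            order.append(u)
            for v in out_edges[u]:
                if v in done or comp_of[v] != comp_of[u]:
                    continue
                local_indeg[v] -= 1
                if local_indeg[v] == 0:
                    heapq.heappush(heap, v)
    return order


def _pick_primary(candidates: list[str], shared: set[str], rxn) -> str:
    pool = sorted(shared) if shared else candidates
    return min(pool, key=lambda m: (-abs(rxn.stoichiometry[m]), m))


def build_escher_map(pathway: Pathway, model: Model, spacing: float = 300.0,
                     canvas_margin: float = 150.0) -> EscherMap:
    """Automatic left-to-right layout of a pathway as an Escher map.

    One midmarker per reaction on the main axis; the primary substrate and
    product (chain links where consecutive reactions share a metabolite)
    sit on the axis — a shared link is a single node at the midpoint
    between the two midmarkers — and the remaining participants fan out
    above (substrates) and below (products).  One straight segment joins
    each participant node to its reaction's midmarker.
    """
    if not pathway.reaction_ids:
        raise MapError("cannot lay out an empty pathway")
    order = order_reactions(pathway, model)
    n = len(order)
    oriented = {r: _oriented(model.reactions[r]) for r in order}

    prim_sub: dict[str, str] = {}
    prim_prod: dict[str, str] = {}
    for i, rid in enumerate(order):
        rxn = model.reactions[rid]
        subs, prods = oriented[rid]
        shared_prev = (set(subs) & set(oriented[order[i - 1]][1])
                       if i > 0 else set())
        shared_next = (set(prods) & set(oriented[order[i + 1]][0])
                       if i < n - 1 else set())
        prim_sub[rid] = _pick_primary(subs, shared_prev, rxn) if subs else None
        prim_prod[rid] = (_pick_primary(prods, shared_next, rxn)
                          if prods else None)

    nodes: dict[str, dict] = {}
    node_counter = 0

    def new_node(node: dict) -> str:
        nonlocal node_counter
        nid = str(node_counter)
        node_counter += 1
        nodes[nid] = node
        return nid

    def met_node(mid: str, x: float, y: float, primary: bool) -> str:
        met = model.metabolites[mid]
        return new_node({
            "node_type": "metabolite",
            "x": x, "y": y,
            "bigg_id": mid,
            "name": met.name or mid,
            "label_x": x + 25.0, "label_y": y + 10.0,
            "node_is_primary": primary,
        })

    reactions_body: dict[str, dict] = {}
    seg_counter = 0
    prev_prod_node: str | None = None
    prev_prod_met: str | None = None
    for i, rid in enumerate(order):
        rxn = model.reactions[rid]
        subs, prods = oriented[rid]
        x_mid = canvas_margin + i * spacing
        participant_nodes: dict[str, str] = {}

        if prim_sub[rid] is not None:
            if prev_prod_met is not None and prim_sub[rid] == prev_prod_met:
                participant_nodes[prim_sub[rid]] = prev_prod_node
            else:
                participant_nodes[prim_sub[rid]] = met_node(
                    prim_sub[rid], x_mid - spacing / 2.5, MAIN_Y, True)
        for k, mid in enumerate(m for m in subs if m != prim_sub[rid]):
            participant_nodes[mid] = met_node(
                mid, x_mid - 50.0 - 30.0 * k, MAIN_Y - SIDE_DY, False)

        mid_node = new_node({"node_type": "midmarker",
                             "x": x_mid, "y": MAIN_Y})

        prev_prod_node = prev_prod_met = None
        if prim_prod[rid] is not None:
            shared_with_next = (
                i < n - 1 and prim_prod[rid] == prim_sub[order[i + 1]]
            )
            x_prod = (x_mid + spacing / 2.0 if shared_with_next
                      else x_mid + spacing / 2.5)
            nid = met_node(prim_prod[rid], x_prod, MAIN_Y, True)
            participant_nodes[prim_prod[rid]] = nid
            if shared_with_next:
                prev_prod_node, prev_prod_met = nid, prim_prod[rid]
        for k, mid in enumerate(m for m in prods if m != prim_prod[rid]):
            participant_nodes[mid] = met_node(
                mid, x_mid + 50.0 + 30.0 * k, MAIN_Y + SIDE_DY, False)

        segments: dict[str, dict] = {}
        for mid in sorted(rxn.stoichiometry):
            segments[str(seg_counter)] = {
                "from_node_id": participant_nodes[mid],
                "to_node_id": mid_node,
                "b1": None, "b2": None,
            }
            seg_counter += 1
        reactions_body[str(i)] = {
            "name": rxn.name or rid,
            "bigg_id": rid,
            "reversibility": rxn.lower_bound < 0 < rxn.upper_bound,
            "label_x": x_mid, "label_y": MAIN_Y - 40.0,
            "gene_reaction_rule": rxn.gene_rule,
            "metabolites": [
                {"bigg_id": m, "coefficient": c}
                for m, c in sorted(rxn.stoichiometry.items())
            ],
            "segments": segments,
        }

    xs = [nd["x"] for nd in nodes.values()]
    ys = [nd["y"] for nd in nodes.values()]
    canvas = {
        "x": min(xs) - canvas_margin,
        "y": min(ys) - canvas_margin,
        "width": (max(xs) - min(xs)) + 2 * canvas_margin,
        "height": (max(ys) - min(ys)) + 2 * canvas_margin,
    }
    emap = EscherMap(
        header={
            "map_name": pathway.id,
            "map_id": pathway.id,
            "map_description": f"automatic layout of pathway {pathway.id}",
            "homepage": "https://escher.github.io",
            "schema": ESCHER_SCHEMA,
        },
        reactions=reactions_body,
        nodes=nodes,
        text_labels={},
        canvas=canvas,
    )
    emap.validate()
    return emap


def _interp_color(t: float, stops: list[tuple[float, str]]) -> str:
    for (p0, c0), (p1, c1) in zip(stops, stops[1:]):
        if p0 <= t <= p1:
            frac = 0.0 if p1 == p0 else (t - p0) / (p1 - p0)
            rgb = []
            for k in range(3):
                a = int(c0[1 + 2 * k: 3 + 2 * k], 16)
                b = int(c1[1 + 2 * k: 3 + 2 * k], 16)
                rgb.append(int(math.floor(a + (b - a) * frac + 0.5)))
            return "#" + "".join(f"{v:02X}" for v in rgb)
    raise ValueError(f"normalized value {t} outside [0, 1]")


def map_flux_to_style(fluxes: dict[str, float], gradient: GradientSpec =
                      DEFAULT_GRADIENT) -> dict[str, tuple[str, float]]:
    """Colour and stroke width per reaction from flux magnitudes.

    Linear normalization is min–max on |v| (all-equal → 1); quantile uses
    average ranks, so it is invariant under monotone rescaling.  Stroke
    width grows from 2 to 10 with the normalized value.
    """
    if not fluxes:
        raise ValueError("need at least one flux value")
    rids = sorted(fluxes)
    mags = [abs(fluxes[r]) for r in rids]
    n = len(mags)
    if gradient.normalization == "linear":
        lo, hi = min(mags), max(mags)
        ts = [1.0] * n if hi == lo else [(v - lo) / (hi - lo) for v in mags]
    else:
        ts = ([1.0] if n == 1 else
              [float(r - 1.0) / (n - 1.0) for r in rankdata(mags)])
    return {
        rid: (_interp_color(t, gradient.stops), 2.0 + 8.0 * t)
        for rid, t in zip(rids, ts)
    }


def _canonical(doc) -> str:
    return json.dumps(doc, sort_keys=True, indent=1) + "\n"


def write_escher_json(emap: EscherMap, path,
                      style: dict[str, tuple[str, float]] | None = None
                      ) -> None:
    """Serialize as the Escher two-element [header, body] array.

    Styling, when given, goes to a ``<stem>.style.json`` sidecar next to
    the map, since the map standard carries geometry only.
    """
    emap.validate()
    path = Path(path)
    path.write_text(_canonical([emap.header, emap.body()]))
    if style is not None:
        sidecar = path.with_name(
            (path.name[:-len(path.suffix)] if path.suffix else path.name)
            + ".style.json")
        sidecar.write_text(_canonical({
            rid: {"color": color, "stroke_width": width}
            for rid, (color, width) in sorted(style.items())
        }))


def read_escher_json(path) -> EscherMap:
    doc = json.loads(Path(path).read_text())
    if not (isinstance(doc, list) and len(doc) == 2):
        raise MapError("Escher map must be a two-element [header, body] array")
    header, body = doc
    emap = EscherMap(
        header=header,
        reactions=body.get("reactions", {}),
        nodes=body.get("nodes", {}),
        text_labels=body.get("text_labels", {}),
        canvas=body.get("canvas", {}),
    )
    emap.validate()
    return emap
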