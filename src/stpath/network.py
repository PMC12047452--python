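"""Merging pathways into a directed weighted interaction network.

Each distinct (source, target, ST code) triple becomes one edge; parallel
edges between the same node pair that carry different ST codes stay
distinct.  Every edge is annotated with its level-1 category digit (the
class used for color-coding in visualizations) and the set of pathways
supporting it.  Two weighting schemes are available:

* ``"multiplicity"`` (default) — the weight is the number of distinct
  pathways containing the interaction, so interactions recurring across
  pathways carry more influence in downstream ranking;
* ``"unit"`` — every edge weighs 1, reproducing an unweighted analysis.

Networks export to GraphML and to a JSON node-link document, both of
which round-trip losslessly.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Literal

import networkx as nx

from .pathway_io import Pathway
from .st_core import STCode, category_labels, parse_st_code

__all__ = [
    "PathwayNetwork",
    "build_network",
    "export_graphml",
    "import_graphml",
    "export_json",
    "import_json",
]

WeightScheme = Literal["multiplicity", "unit"]


@dataclass(frozen=True)
class NetworkEdge:
    source: str
    target: str
    code: STCode
    weight: float
    pathways: frozenset[str]

    @property
    def category(self) -> int:
        """Level-1 digit — the color class of the edge."""
        return self.code.level1


@dataclass
class PathwayNetwork:
    """Directed weighted network merged from one or more pathways."""

    edges: dict[tuple[str, str, STCode], NetworkEdge] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for e in self.edges.values():
            out.add(e.source)
            out.add(e.target)
        return out

    def __len__(self) -> int:
        return len(self.edges)

    def pair_weights(self) -> dict[tuple[str, str], float]:
        """Per node-pair weights w(u→v), summing parallel ST-coded edges.

        This is the collapsed weight matrix the key-factor ranking uses.
        """
        out: dict[tuple[str, str], float] = {}
        for e in self.edges.values():
            key = (e.source, e.target)
            out[key] = out.get(key, 0.0) + e.weight
        return out

    def to_multigraph(self) -> nx.MultiDiGraph:
        """networkx view with edge keys = ST-code text."""
        g = nx.MultiDiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for e in sorted(
            self.edges.values(), key=lambda e: (e.source, e.target, e.code)
        ):
            l1, l2 = category_labels(e.code)
            g.add_edge(
                e.source,
                e.target,
                key=str(e.code),
                st_code=str(e.code),
                weight=e.weight,
                category=e.category,
                category_label=l2,
                pathways="|".join(sorted(e.pathways)),
            )
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayNetwork):
            return NotImplemented
        return self.edges == other.edges


def build_network(
    pathways: Iterable[Pathway], weight_scheme: WeightScheme = "multiplicity"
) -> PathwayNetwork:
    """Merge pathways into one network.

    Under ``"multiplicity"`` an edge's weight counts the *distinct* pathway
    ids supporting it — supplying the same pathway twice does not inflate
    weights.  Order-independent: permuting the input yields an identical
    network.
    """
    if weight_scheme not in ("multiplicity", "unit"):
        raise ValueError(f"unknown weight scheme {weight_scheme!r}")
    pathways = list(pathways)
    if not pathways:
        raise ValueError("need at least one pathway to build a network")
    placeholder = sum(
        1
        for pw in pathways
        if any(re.search(r"_n\d+$", s.source) for s in pw.steps)
    )
    if 0 < placeholder < len(pathways):
        warnings.warn(
            "mixing named-entity and placeholder-entity pathways in one network",
            stacklevel=2,
        )
    support: dict[tuple[str, str, STCode], set[str]] = {}
    for pw in pathways:
        for step in pw.steps:
            support.setdefault((step.source, step.target, step.code), set()).add(pw.id)
    edges = {}
    for (source, target, code), pids in support.items():
        weight = float(len(pids)) if weight_scheme == "multiplicity" else 1.0
        edges[(source, target, code)] = NetworkEdge(
            source, target, code, weight, frozenset(pids)
        )
    return PathwayNetwork(edges)


def export_graphml(net: PathwayNetwork, file: str | Path | IO[bytes]) -> None:
    """Write GraphML with st_code / weight / category edge attributes."""
    if not net.edges:
        raise ValueError("refusing to export an empty network")
    nx.write_graphml(net.to_multigraph(), file)


def import_graphml(file: str | Path | IO[bytes]) -> PathwayNetwork:
    g = nx.read_graphml(file, force_multigraph=True)
    edges = {}
    for u, v, _key, data in g.edges(keys=True, data=True):
        code = parse_st_code(data["st_code"])
        pids = frozenset(p for p in data.get("pathways", "").split("|") if p)
        edges[(u, v, code)] = NetworkEdge(u, v, code, float(data["weight"]), pids)
    return PathwayNetwork(edges)


def export_json(net: PathwayNetwork, file: str | Path | IO[str]) -> None:
    """Node-link JSON: {"nodes": [{"id": …}], "links": [{…}]}."""
    if not net.edges:
        raise ValueError("refusing to export an empty network")
    doc = {
        "nodes": [{"id": n} for n in sorted(net.nodes)],
        "links": [
            {
                "source": e.source,
                "target": e.target,
                "st_code": str(e.code),
                "weight": e.weight,
                "category": e.category,
                "category_label": category_labels(e.code)[1],
                "pathways": sorted(e.pathways),
            }
            for e in sorted(
                net.edges.values(), key=lambda e: (e.source, e.target, e.code)
            )
        ],
    }
    if hasattr(file, "write"):
        json.dump(doc, file, indent=1)
    else:
        with open(file, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)


def import_json(file: str | Path | IO[str]) -> PathwayNetwork:
    if hasattr(file, "read"):
        doc = json.load(file)
    else:
        with open(file, encoding="utf-8") as fh:
            doc = json.load(fh)
    edges = {}
    for link in doc["links"]:
        code = parse_st_code(link["st_code"])
        edges[(link["source"], link["target"], code)] = NetworkEdge(
            link["source"],
            link["target"],
            code,
            float(link["weight"]),
            frozenset(link.get("pathways", [])),
        )
    return PathwayNetwork(edges)
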