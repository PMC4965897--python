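"""Directed compound-graph reconstruction from reaction records.

Nodes are compounds; an edge A→B means compound A is a substrate of some
reaction that produces compound B.  Reversible reactions contribute edges in
both directions.  The graph is simple: parallel edges collapse and
self-loops are dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import networkx as nx

from .errors import ReconstructionError
from .kegg_io import ReactionRecord, canonicalize_compound


@dataclass
class MetabolicNetwork:
    """An organism's metabolic compound graph."""

    organism_id: str
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def validate(self) -> None:
        """Check structural invariants (simple graph, endpoints in node set)."""
        for a, b in self.graph.edges:
            if a == b:
                raise ReconstructionError(f"{self.organism_id}: self-loop at {a}")
        # networkx guarantees endpoints are nodes and edges form a set

    def to_json(self) -> str:
        doc = {
            "organism_id": self.organism_id,
            "nodes": sorted(self.graph.nodes),
            "edges": sorted(map(list, self.graph.edges)),
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MetabolicNetwork":
        doc = json.loads(text)
        g = nx.DiGraph()
        g.add_nodes_from(doc["nodes"])
        g.add_edges_from((a, b) for a, b in doc["edges"])
        net = cls(doc["organism_id"], g)
        net.validate()
        return net

    def write_edge_tsv(self, stream: TextIO) -> None:
        """Edge list as ``source<TAB>target``; isolated nodes as ``node<TAB>``."""
        stream.write("source\ttarget\n")
        connected = set()
        for a, b in sorted(self.graph.edges):
            stream.write(f"{a}\t{b}\n")
            connected.update((a, b))
        for node in sorted(self.nodes - connected):
            stream.write(f"{node}\t\n")

    @classmethod
    def read_edge_tsv(cls, stream: TextIO, organism_id: str) -> "MetabolicNetwork":
        g = nx.DiGraph()
        header = next(stream, None)
        if header is None or not header.startswith("source"):
            raise ReconstructionError("edge TSV missing 'source\\ttarget' header")
        for line in stream:
            line = line.rstrip("\n")
            if not line:
                continue
            a, _, b = line.partition("\t")
            if b:
                g.add_edge(a, b)
            else:
                g.add_node(a)
        return cls(organism_id, g)


def reconstruct_network(
    reactions: Iterable[ReactionRecord],
    organism_id: str,
    exclude: Iterable[str] = (),
) -> MetabolicNetwork:
    """Build the compound graph of one organism.

    Parameters
    ----------
    reactions
        Reaction records; each contributes every substrate→product pair
        (and product→substrate if reversible).
    exclude
        Compound identifiers (e.g. currency metabolites such as water or
        ATP) removed before edge construction.  Default empty.

    Raises
    ------
    ReconstructionError
        If no reaction survives exclusion filtering with non-empty sides —
        empty networks are never built.
    """
    excluded = {canonicalize_compound(c) for c in exclude}
    g = nx.DiGraph()
    admitted = 0
    for rec in reactions:
        subs = rec.substrates - excluded
        prods = rec.products - excluded
        if not subs or not prods:
            continue
        admitted += 1
        g.add_nodes_from(subs)
        g.add_nodes_from(prods)
        for s in subs:
            for p in prods:
                if s != p:
                    g.add_edge(s, p)
                    if rec.reversible:
                        g.add_edge(p, s)
    if admitted == 0:
        raise ReconstructionError(
            f"{organism_id}: no admissible reactions after exclusion filtering"
        )
    return MetabolicNetwork(organism_id, g)
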