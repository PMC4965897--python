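"""Seed-set detection by strongly-connected-component decomposition.

The seed set of a metabolic network — the compounds an organism must
acquire from its environment — is read off the network's condensation:
every SCC with no incoming edge from another component and at least one
outgoing edge to another component is a *seed component*.  Because any one
member of such a component would suffice (producing one member produces
them all), each member carries a confidence score of ``1/|SCC|``: seed
compounds in a component are equally likely candidates, and confidences
within a component sum to one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TextIO

import networkx as nx

from .errors import EmptySeedSetError
from .network_reconstruction import MetabolicNetwork


def _ordered_components(components: list[frozenset[str]]) -> list[frozenset[str]]:
    return sorted(components, key=min)


@dataclass(frozen=True)
class SCCPartition:
    """A partition of a network's compounds into maximal SCCs.

    Components are ordered deterministically by their lexicographically
    smallest member.
    """

    components: tuple[frozenset[str], ...]
    component_of: dict[str, int]

    @classmethod
    def from_components(cls, components: list[frozenset[str]]) -> "SCCPartition":
        ordered = tuple(_ordered_components(components))
        return cls(ordered, {c: i for i, comp in enumerate(ordered) for c in comp})

    def sizes(self) -> list[int]:
        return [len(c) for c in self.components]


@dataclass(frozen=True)
class SeedSet:
    """The source SCCs of a network with per-compound confidence scores."""

    organism_id: str
    seed_components: tuple[frozenset[str], ...]
    confidence: dict[str, float]

    @property
    def is_empty(self) -> bool:
        return not self.seed_components

    @property
    def seed_compounds(self) -> frozenset[str]:
        return frozenset(self.confidence)

    @property
    def total_confidence(self) -> float:
        """Equals the number of seed components (each sums to one)."""
        return float(len(self.seed_components))

    def require_nonempty(self) -> "SeedSet":
        if self.is_empty:
            raise EmptySeedSetError(
                f"organism {self.organism_id!r} has an empty seed set; "
                "interaction indices are undefined"
            )
        return self

    def write_tsv(self, stream: TextIO) -> None:
        stream.write("compound_id\tcomponent_index\tconfidence\n")
        for i, comp in enumerate(self.seed_components):
            for c in sorted(comp):
                stream.write(f"{c}\t{i}\t{self.confidence[c]:.10g}\n")

    def to_json(self) -> str:
        return json.dumps(
            {
                "organism_id": self.organism_id,
                "seed_components": [sorted(c) for c in self.seed_components],
                "confidence": {c: self.confidence[c] for c in sorted(self.confidence)},
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SeedSet":
        doc = json.loads(text)
        return cls(
            doc["organism_id"],
            tuple(frozenset(c) for c in doc["seed_components"]),
            dict(doc["confidence"]),
        )


def strongly_connected_components(network: MetabolicNetwork) -> SCCPartition:
    """Decompose a network into its maximal SCC partition.

    The partition of a digraph into maximal strongly connected components
    is unique, so any correct algorithm yields the same result; ordering is
    made deterministic afterwards.
    """
    if len(network) == 0:
        raise EmptySeedSetError(f"organism {network.organism_id!r}: empty network")
    comps = [frozenset(c) for c in nx.strongly_connected_components(network.graph)]
    return SCCPartition.from_components(comps)


def identify_seed_set(
    network: MetabolicNetwork, partition: SCCPartition | None = None
) -> SeedSet:
    """Identify the seed components of a network.

    A component qualifies when, in the condensation, it has in-degree zero
    and out-degree at least one.  Internal edges (including self-loops of a
    singleton) are ignored: only edges between *different* components
    count.  A network whose condensation has no qualifying component (e.g.
    a single SCC) yields an empty — and for index computation, poisoned —
    seed set.
    """
    if partition is None:
        partition = strongly_connected_components(network)
    has_incoming = [False] * len(partition.components)
    has_outgoing = [False] * len(partition.components)
    for a, b in network.graph.edges:
        ca, cb = partition.component_of[a], partition.component_of[b]
        if ca != cb:
            has_outgoing[ca] = True
            has_incoming[cb] = True
    seeds = [
        comp
        for i, comp in enumerate(partition.components)
        if not has_incoming[i] and has_outgoing[i]
    ]
    confidence = {c: 1.0 / len(comp) for comp in seeds for c in comp}
    return SeedSet(network.organism_id, tuple(_ordered_components(seeds)), confidence)
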