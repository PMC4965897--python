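"""Pairwise species interaction indices from seed sets.

Two directed, confidence-weighted indices quantify how species A relates to
species B:

* **competition** — the weighted fraction of A's candidate seed compounds
  that are also candidate seed compounds of B (overlapping nutritional
  requirements);
* **complementarity** — the weighted fraction of A's candidate seed
  compounds that occur in B's metabolic network but *not* in B's seed set
  (compounds B can synthesise and could in principle supply to A).

Each candidate seed compound of A carries its confidence ``1/|SCC|``; both
indices are normalised by A's total seed confidence (= the number of A's
seed components), so self-competition is exactly 1, self-complementarity
exactly 0, and both indices lie in [0, 1].  The two membership predicates
are disjoint, so competition + complementarity ≤ 1 for every ordered pair.

Significance is assessed with a permutation null that resamples *which*
SCCs of B act as sources, preserving B's SCC size spectrum (and hence the
confidence weights), conditioning on B's network modularity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence, TextIO

import numpy as np

from .errors import EmptySeedSetError, ReverseEcologyError
from .network_reconstruction import MetabolicNetwork
from .seed_detection import SCCPartition, SeedSet, strongly_connected_components

IndexKind = Literal["competition", "complementarity"]

Community = Sequence[tuple[MetabolicNetwork, SeedSet]]


@dataclass
class InteractionMatrix:
    """Square matrix of a directed interaction index over a community.

    ``values[i, j]`` scores species ``i`` (the "A" role) against species
    ``j``; the matrix is generally asymmetric.
    """

    species_ids: list[str]
    values: np.ndarray
    index_kind: IndexKind
    pvalues: np.ndarray | None = None

    def write_tsv(self, stream: TextIO, matrix: np.ndarray | None = None) -> None:
        m = self.values if matrix is None else matrix
        stream.write("\t".join(["species_id", *self.species_ids]) + "\n")
        for sid, row in zip(self.species_ids, m):
            stream.write(sid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    def write_long_tsv(self, stream: TextIO) -> None:
        cols = ["species_a", "species_b", "index_kind", "value"]
        if self.pvalues is not None:
            cols.append("p")
        stream.write("\t".join(cols) + "\n")
        for i, a in enumerate(self.species_ids):
            for j, b in enumerate(self.species_ids):
                row = [a, b, self.index_kind, f"{self.values[i, j]:.10g}"]
                if self.pvalues is not None:
                    row.append(f"{self.pvalues[i, j]:.10g}")
                stream.write("\t".join(row) + "\n")


def competition_index(seed_a: SeedSet, seed_b: SeedSet) -> float:
    """Weighted fraction of A's seed compounds that are also seeds of B."""
    seed_a.require_nonempty()
    seed_b.require_nonempty()
    b_seeds = seed_b.seed_compounds
    num = sum(w for c, w in seed_a.confidence.items() if c in b_seeds)
    return num / seed_a.total_confidence


def complementarity_index(
    seed_a: SeedSet, network_b: MetabolicNetwork, seed_b: SeedSet
) -> float:
    """Weighted fraction of A's seeds inside B's network but outside B's seeds."""
    seed_a.require_nonempty()
    if len(network_b) == 0:
        raise ReverseEcologyError(f"network of {network_b.organism_id!r} is empty")
    b_nodes = network_b.nodes
    b_seeds = seed_b.seed_compounds
    num = sum(
        w
        for c, w in seed_a.confidence.items()
        if c in b_nodes and c not in b_seeds
    )
    return num / seed_a.total_confidence


def _validate_community(community: Community) -> list[str]:
    if len(community) < 2:
        raise ReverseEcologyError("a community needs at least two species")
    ids = [net.organism_id for net, _ in community]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ReverseEcologyError(f"duplicate organism ids: {', '.join(dupes)}")
    for net, seeds in community:
        if seeds.is_empty:
            raise EmptySeedSetError(
                f"organism {net.organism_id!r} has an empty seed set"
            )
    return ids


def interaction_matrices(
    community: Community,
) -> tuple[InteractionMatrix, InteractionMatrix]:
    """Compute the full competition and complementarity matrices.

    Row species plays the "A" role; both matrices share the species order
    of the input community.
    """
    ids = _validate_community(community)
    n = len(community)
    comp = np.zeros((n, n))
    compl = np.zeros((n, n))
    for i, (_, seed_a) in enumerate(community):
        for j, (net_b, seed_b) in enumerate(community):
            comp[i, j] = competition_index(seed_a, seed_b)
            compl[i, j] = complementarity_index(seed_a, net_b, seed_b)
    return (
        InteractionMatrix(ids, comp, "competition"),
        InteractionMatrix(ids, compl, "complementarity"),
    )


def _null_seed_sets(
    net: MetabolicNetwork,
    seeds: SeedSet,
    partition: SCCPartition,
    n_perm: int,
    rng: np.random.Generator,
) -> list[SeedSet]:
    """Draw null seed sets: resample which SCCs are sources, sizes preserved."""
    k = len(seeds.seed_components)
    n_comp = len(partition.components)
    draws = []
    for _ in range(n_perm):
        chosen = rng.choice(n_comp, size=k, replace=False)
        comps = [partition.components[i] for i in chosen]
        conf = {c: 1.0 / len(comp) for comp in comps for c in comp}
        draws.append(SeedSet(net.organism_id, tuple(comps), conf))
    return draws


def permutation_pvalues(
    community: Community,
    index_kind: IndexKind,
    n_perm: int = 999,
    rng_seed: int = 0,
) -> np.ndarray:
    """Permutation p-values for every ordered species pair.

    For pair (A, B) the null redraws B's seed placement: sample as many
    components as B has seed components, uniformly without replacement from
    B's full SCC partition, and recompute the index against A's observed
    seed set.  ``p = (1 + #{null ≥ observed}) / (1 + n_perm)`` (add-one
    estimator, so p is never zero); deterministic given ``rng_seed``.
    """
    if index_kind not in ("competition", "complementarity"):
        raise ReverseEcologyError(f"unknown index kind {index_kind!r}")
    if n_perm < 99:
        raise ReverseEcologyError(
            f"n_perm={n_perm} gives too coarse a p resolution; need >= 99"
        )
    _validate_community(community)
    rng = np.random.default_rng(rng_seed)
    n = len(community)
    pvals = np.ones((n, n))
    for j, (net_b, seed_b) in enumerate(community):
        partition = strongly_connected_components(net_b)
        nulls = _null_seed_sets(net_b, seed_b, partition, n_perm, rng)
        for i, (_, seed_a) in enumerate(community):
            if index_kind == "competition":
                obs = competition_index(seed_a, seed_b)
                null_vals = [competition_index(seed_a, nb) for nb in nulls]
            else:
                obs = complementarity_index(seed_a, net_b, seed_b)
                null_vals = [
                    complementarity_index(seed_a, net_b, nb) for nb in nulls
                ]
            exceed = sum(1 for v in null_vals if v >= obs - 1e-12)
            pvals[i, j] = (1 + exceed) / (1 + n_perm)
    return pvals
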