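"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the code paths they check: SCC
partitions come from a transitive-closure reachability matrix, seed
components from degree counting over that oracle partition, and Mantel
p-values from exhaustive permutation enumeration with a plain Pearson
formula.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from reverse_ecology.kegg_io import ReactionRecord
from reverse_ecology.network_reconstruction import MetabolicNetwork, reconstruct_network
from reverse_ecology.seed_detection import identify_seed_set


# ---------------------------------------------------------------- oracles


def reachability_matrix(nodes: list[str], edges: set[tuple[str, str]]) -> np.ndarray:
    """Boolean reachability closure (Floyd–Warshall style), reflexive."""
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    r = np.eye(n, dtype=bool)
    for a, b in edges:
        r[idx[a], idx[b]] = True
    for k in range(n):
        r |= r[:, k : k + 1] & r[k : k + 1, :]
    return r


def scc_oracle(network: MetabolicNetwork) -> set[frozenset[str]]:
    """SCCs as mutual-reachability equivalence classes."""
    nodes = sorted(network.nodes)
    r = reachability_matrix(nodes, network.edges)
    mutual = r & r.T
    return {
        frozenset(nodes[j] for j in np.flatnonzero(mutual[i]))
        for i in range(len(nodes))
    }


def seed_components_oracle(network: MetabolicNetwork) -> set[frozenset[str]]:
    """Condensation components with in-degree 0 and out-degree >= 1."""
    comps = list(scc_oracle(network))
    comp_of = {v: i for i, c in enumerate(comps) for v in c}
    has_in = [False] * len(comps)
    has_out = [False] * len(comps)
    for a, b in network.edges:
        if comp_of[a] != comp_of[b]:
            has_out[comp_of[a]] = True
            has_in[comp_of[b]] = True
    return {
        c for i, c in enumerate(comps) if not has_in[i] and has_out[i]
    }


def pearson_offdiag(m1: np.ndarray, m2: np.ndarray) -> float:
    mask = ~np.eye(m1.shape[0], dtype=bool)
    x, y = m1[mask], m2[mask]
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def mantel_exact_oracle(m1: np.ndarray, m2: np.ndarray) -> tuple[float, float]:
    """Exhaustive two-sided Mantel over all n! joint row/column permutations."""
    n = m1.shape[0]
    r_obs = pearson_offdiag(m1, m2)
    exceed = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        p = list(perm)
        r = pearson_offdiag(m1, m2[np.ix_(p, p)])
        total += 1
        if abs(r) >= abs(r_obs) - 1e-12:
            exceed += 1
    return r_obs, exceed / total


def random_digraph(rng: np.random.Generator, max_nodes: int = 30) -> MetabolicNetwork:
    """A random non-empty digraph wrapped as a MetabolicNetwork."""
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.02, 0.3))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)), directed=True)
    relabel = {i: f"C{i:03d}" for i in g.nodes}
    return MetabolicNetwork("random", nx.relabel_nodes(g, relabel))


# ------------------------------------------------------- toy communities


def _irrev(rid: str, subs: set[str], prods: set[str]) -> ReactionRecord:
    return ReactionRecord(rid, frozenset(subs), frozenset(prods), False)


def _rev(rid: str, subs: set[str], prods: set[str]) -> ReactionRecord:
    return ReactionRecord(rid, frozenset(subs), frozenset(prods), True)


@pytest.fixture(scope="session")
def toy_community():
    """Three hand-built species with hand-computed interaction matrices.

    S1: a→m, b↔c, c→m   — seeds {a: 1, b: 0.5, c: 0.5}
    S2: a→n, b→n, n→c   — seeds {a: 1, b: 1}; c internal
    S3: q→b, q→m        — seeds {q: 1}; b, m internal
    """
    s1 = reconstruct_network(
        [_irrev("r1", {"a"}, {"m"}), _rev("r2", {"b"}, {"c"}),
         _irrev("r3", {"c"}, {"m"})],
        "S1",
    )
    s2 = reconstruct_network(
        [_irrev("r1", {"a"}, {"n"}), _irrev("r2", {"b"}, {"n"}),
         _irrev("r3", {"n"}, {"c"})],
        "S2",
    )
    s3 = reconstruct_network(
        [_irrev("r1", {"q"}, {"b"}), _irrev("r2", {"q"}, {"m"})], "S3"
    )
    members = [(net, identify_seed_set(net)) for net in (s1, s2, s3)]
    expected_competition = np.array(
        [[1.0, 0.75, 0.0],
         [1.0, 1.0, 0.0],
         [0.0, 0.0, 1.0]]
    )
    expected_complementarity = np.array(
        [[0.0, 0.25, 0.25],
         [0.0, 0.0, 0.5],
         [0.0, 0.0, 0.0]]
    )
    return members, expected_competition, expected_complementarity


def random_community(rng: np.random.Generator, n_species: int = 3):
    """Species drawn over a shared compound universe; retries until all
    members have non-empty seed sets."""
    from reverse_ecology.fixtures import random_reaction_set

    members = []
    while len(members) < n_species:
        recs = random_reaction_set(
            n_compounds=30,
            n_reactions=15,
            reversible_prob=0.3,
            rng_seed=int(rng.integers(2**31)),
        )
        net = reconstruct_network(recs, f"SP{len(members):02d}")
        seeds = identify_seed_set(net)
        if not seeds.is_empty:
            members.append((net, seeds))
    return members
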