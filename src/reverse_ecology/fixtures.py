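"""Synthetic data generators: random reaction sets, planted communities,
and null abundance tables.

These generators define the study conditions for the rest of the package:
random reaction sets exercise parsing and reconstruction, planted
communities carry exact ground-truth seed sets and interaction structure,
and null abundance tables calibrate the co-occurrence statistics.

Planted species are built bottom-up from their seed compounds outward as
acyclic, irreversible reaction chains, so every compound is its own SCC and
the planted seeds are exactly the detector's sources (each with confidence
1).  The generator then re-runs the detector and refuses to hand out a
community whose ground truth it cannot verify.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ReverseEcologyError
from .kegg_io import ReactionRecord, write_reaction_flatfile
from .network_reconstruction import MetabolicNetwork, reconstruct_network
from .seed_detection import SeedSet, identify_seed_set


class GenerationError(ReverseEcologyError):
    """A community specification is infeasible or failed verification."""


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a planted synthetic community."""

    n_species: int = 6
    compound_universe_size: int = 2000
    n_reactions_per_species: int = 40
    seed_overlap: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_species, self.compound_universe_size,
               self.n_reactions_per_species) <= 0:
            raise GenerationError("all counts must be positive")
        if not 0.0 <= self.seed_overlap <= 1.0:
            raise GenerationError("seed_overlap must lie in [0, 1]")


@dataclass
class PlantedCommunity:
    """A synthetic community with exact ground-truth interaction structure.

    ``competitor_pairs`` are ordered index pairs engineered to share a
    ``seed_overlap`` fraction of seed compounds; in ``complementary_pairs``
    (a, b), species a's seeds are embedded as internal (non-seed) nodes of
    species b's network; ``unrelated_pairs`` share no compounds at all.
    """

    members: list[tuple[MetabolicNetwork, SeedSet]]
    reactions: dict[str, list[ReactionRecord]]
    true_seeds: dict[str, frozenset[str]]
    competitor_pairs: list[tuple[int, int]]
    complementary_pairs: list[tuple[int, int]]
    unrelated_pairs: list[tuple[int, int]]

    @property
    def species_ids(self) -> list[str]:
        return [net.organism_id for net, _ in self.members]


def random_reaction_set(
    n_compounds: int,
    n_reactions: int,
    reversible_prob: float = 0.3,
    rng_seed: int = 0,
) -> list[ReactionRecord]:
    """Draw random reactions over a compound universe ``C00001..``.

    Each reaction has 1–3 substrates and 1–3 products, disjoint within the
    reaction; deterministic given ``rng_seed``.
    """
    if n_compounds < 2:
        raise ReverseEcologyError("need at least two compounds")
    if n_reactions < 1:
        raise ReverseEcologyError("need at least one reaction")
    rng = np.random.default_rng(rng_seed)
    compounds = np.array([f"C{i:05d}" for i in range(1, n_compounds + 1)])
    records = []
    for k in range(n_reactions):
        max_side = min(3, n_compounds // 2) or 1
        ns = int(rng.integers(1, max_side + 1))
        np_ = int(rng.integers(1, min(max_side, n_compounds - ns) + 1))
        chosen = rng.choice(n_compounds, size=ns + np_, replace=False)
        records.append(
            ReactionRecord(
                reaction_id=f"R{k + 1:05d}",
                substrates=frozenset(compounds[chosen[:ns]]),
                products=frozenset(compounds[chosen[ns:]]),
                reversible=bool(rng.random() < reversible_prob),
            )
        )
    return records


class _CompoundPool:
    """Hands out fresh compound identifiers from a finite universe."""

    def __init__(self, size: int) -> None:
        self.size = size
        self.next_id = 1

    def take(self, n: int) -> list[str]:
        if self.next_id + n - 1 > self.size:
            raise GenerationError(
                "compound universe exhausted: overlap/size demands exceed "
                f"universe of {self.size}"
            )
        out = [f"C{i:05d}" for i in range(self.next_id, self.next_id + n)]
        self.next_id += n
        return out


def _build_species(
    organism_id: str,
    seeds: list[str],
    internals: list[str],
    rng: np.random.Generator,
) -> list[ReactionRecord]:
    """Acyclic irreversible chains from seeds through internal compounds."""
    records = []
    for k, (s, t) in enumerate(zip(seeds, internals)):
        records.append(
            ReactionRecord(f"{organism_id}_R{k + 1:04d}", frozenset({s}),
                           frozenset({t}), False)
        )
    for k in range(len(seeds), len(internals)):
        src = internals[int(rng.integers(0, k))]  # earlier internal: stays acyclic
        records.append(
            ReactionRecord(f"{organism_id}_R{k + 1:04d}", frozenset({src}),
                           frozenset({internals[k]}), False)
        )
    return records


def planted_community(spec: CommunitySpec) -> PlantedCommunity:
    """Generate a community with planted competitor and complementary pairs.

    Species 0 and 1 are competitors sharing ``seed_overlap`` of their seed
    compounds; when the community has at least four members, species 2's
    seeds are embedded as internal nodes of species 3 (a complementary
    pair).  All other compounds are unique per species, so the remaining
    pairs are unrelated with both indices exactly zero.
    """
    rng = np.random.default_rng(spec.rng_seed)
    pool = _CompoundPool(spec.compound_universe_size)
    n_seeds = max(2, min(spec.n_reactions_per_species // 4, 8))
    if spec.n_reactions_per_species < n_seeds:
        raise GenerationError("n_reactions_per_species too small for seed count")
    n_shared = int(round(spec.seed_overlap * n_seeds))

    shared_seeds = pool.take(n_shared) if n_shared else []
    seed_lists: list[list[str]] = []
    reactions: dict[str, list[ReactionRecord]] = {}
    ids = [f"SP{i:02d}" for i in range(spec.n_species)]
    for i, org in enumerate(ids):
        if i in (0, 1) and spec.n_species >= 2:
            seeds = shared_seeds + pool.take(n_seeds - n_shared)
        else:
            seeds = pool.take(n_seeds)
        internals = pool.take(spec.n_reactions_per_species)
        seed_lists.append(seeds)
        reactions[org] = _build_species(org, seeds, internals, rng)

    competitor_pairs = [(0, 1), (1, 0)] if spec.n_species >= 2 else []
    complementary_pairs: list[tuple[int, int]] = []
    if spec.n_species >= 4:
        # embed species 2's seeds as produced (internal) nodes of species 3
        donor_internals = [
            next(iter(r.products))
            for r in reactions[ids[3]][: len(seed_lists[2])]
        ]
        for k, seed_c in enumerate(seed_lists[2]):
            reactions[ids[3]].append(
                ReactionRecord(
                    f"{ids[3]}_X{k + 1:04d}",
                    frozenset({donor_internals[k % len(donor_internals)]}),
                    frozenset({seed_c}),
                    False,
                )
            )
        complementary_pairs = [(2, 3)]

    members: list[tuple[MetabolicNetwork, SeedSet]] = []
    true_seeds: dict[str, frozenset[str]] = {}
    for i, org in enumerate(ids):
        net = reconstruct_network(reactions[org], org)
        detected = identify_seed_set(net)
        planted = frozenset(seed_lists[i])
        if detected.seed_compounds != planted:
            raise GenerationError(
                f"{org}: detector found seeds {sorted(detected.seed_compounds)} "
                f"but {sorted(planted)} were planted"
            )
        members.append((net, detected))
        true_seeds[org] = planted

    designated = set(competitor_pairs) | set(complementary_pairs)
    unrelated = [
        (i, j)
        for i in range(spec.n_species)
        for j in range(spec.n_species)
        if i != j and (i, j) not in designated
        and (j, i) not in set(complementary_pairs)
    ]
    return PlantedCommunity(
        members, reactions, true_seeds, competitor_pairs, complementary_pairs,
        unrelated,
    )


def null_abundance_table(
    n_species: int,
    n_samples: int,
    rng_seed: int = 0,
    sparsity: float = 0.5,
) -> "pd.DataFrame":
    """Null species×sample abundances: independent sparse lognormal counts."""
    rng = np.random.default_rng(rng_seed)
    ab = rng.lognormal(mean=0.0, sigma=1.0, size=(n_species, n_samples))
    ab[rng.random((n_species, n_samples)) < sparsity] = 0.0
    return pd.DataFrame(
        ab,
        index=[f"SP{i:02d}" for i in range(n_species)],
        columns=[f"S{j:03d}" for j in range(n_samples)],
    )


def write_community_flatfiles(community: PlantedCommunity, out_dir: str | Path) -> None:
    """Write each member's reactions in the KEGG-style flat dialect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for org, recs in community.reactions.items():
        with open(out / f"{org}.reactions.txt", "w") as fh:
            write_reaction_flatfile(recs, fh)
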