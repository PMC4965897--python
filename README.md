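# reverse-ecology

Reverse-ecology analysis of microbial communities from genome-derived
metabolic networks.

Most microbes cannot be cultured, so their nutritional requirements and
interactions with neighbours cannot be observed directly. Reverse ecology
infers them from genomes instead: an organism's annotated reactions define
a directed *compound graph*, the graph's topology reveals which compounds
the organism must take up from its environment (its **seed set**), and
pairwise comparison of seed sets quantifies how strongly two species
compete for, or can supply, each other's nutrients. This package
implements that pipeline for metagenomics and microbiome researchers:

1. **Network reconstruction** — from KEGG-style reaction records (flat
   files, KO annotation profiles, or a cached KEGG REST fetch), build a
   directed graph with an edge A→B whenever compound A is a substrate of a
   reaction producing B (both directions for reversible reactions).
2. **Seed detection** — decompose the graph into strongly connected
   components (SCCs). Seed components are the sources of the condensation:
   SCCs with no incoming edge from another component and at least one
   outgoing edge. Since producing any one member of an SCC produces them
   all, each member of a seed component of size *k* is a candidate seed
   compound with confidence *1/k*.
3. **Interaction indices** — for an ordered species pair (A, B), with
   *S_A* the candidate seed compounds of A and *w(c)* their confidences,

   - competition(A, B) = Σ\_{c ∈ S_A ∩ S_B} w(c) / Σ\_{c ∈ S_A} w(c)
   - complementarity(A, B) = Σ\_{c ∈ S_A ∩ (V_B \ S_B)} w(c) / Σ\_{c ∈ S_A} w(c)

   where *V_B* is B's node set. Both lie in [0, 1], are directed
   (generally asymmetric), and sum to at most 1 per pair. Significance
   comes from a permutation null that resamples which of B's SCCs act as
   sources, preserving B's SCC size spectrum.
4. **Co-occurrence statistics** — Jaccard similarity of species
   presence/absence profiles across samples, and a Mantel permutation test
   relating an interaction matrix to a co-occurrence matrix over all
   off-diagonal cells.

## Worked example

```bash
reverse-ecology simulate --n-species 4 --seed 11 --out-dir sim
reverse-ecology reconstruct --reactions sim/SP00.reactions.txt \
    --organism-id SP00 --out-dir net
reverse-ecology seeds --network net/SP00.network.json --out-dir seeds
# ... reconstruct SP01–SP03 the same way, then:
reverse-ecology interact --network net/SP00.network.json \
    --network net/SP01.network.json --network net/SP02.network.json \
    --network net/SP03.network.json --n-perm 199 --seed 5 --out-dir ix
```

prints to stderr

```
4 species written to sim
SP00: 48 compounds, 40 edges
SP00: 8 candidate seed compounds in 8 components
4 species; matrices written to ix
```

and `ix/competition.tsv` contains

```
species_id	SP00	SP01	SP02	SP03
SP00	1	0.75	0	0
SP01	0.75	1	0	0
SP02	0	0	1	0
SP03	0	0	0	1
```

The simulated community plants species SP00 and SP01 as competitors
sharing 80 % of their seed compounds (6 of 8 after rounding, hence 0.75):
each must import the same six compounds, so they compete for them. The
diagonal is 1 by definition (a species overlaps its own requirements
completely), and unrelated species share no compounds at all. The
complementarity matrix (`ix/complementarity.tsv`) scores SP02 against SP03
at 1.0: every compound SP02 needs is an internal product of SP03's
network, so SP03 can in principle feed SP02.

The same functions are importable from Python (`reverse_ecology.
reconstruct_network`, `identify_seed_set`, `interaction_matrices`,
`jaccard_cooccurrence`, `mantel_test`, ...); the CLI is a thin shell over
them.

Genome-scale data can be pulled straight from KEGG with
`fetch_org_metabolic_data("eco", cache_dir)`; results are cached as flat
files so later calls run offline.

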