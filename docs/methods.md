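# Methods

## Model

An organism's metabolism is represented purely topologically. Each
reaction contributes its substrate set *S* and product set *P*; the
compound graph has an edge s→p for every (s, p) ∈ S×P with s ≠ p, and the
reverse edges as well when the reaction is reversible. Stoichiometric
coefficients are stripped during parsing — the framework asks only
*whether* a compound can be produced from another, never in what ratio —
and compound identifiers are opaque strings canonicalised by uppercasing
and trimming (KEGG C-numbers in practice, but nothing depends on that).

The **seed set** is the topological proxy for exogenously acquired
nutrients. Decomposing the graph into maximal strongly connected
components and contracting each to a node yields the condensation DAG;
components with condensation in-degree 0 and out-degree ≥ 1 are the seed
components. In-degree 0 means nothing inside the network produces these
compounds; out-degree ≥ 1 means they actually feed the rest of the
metabolism. Picking one representative from every in-degree-0 component
makes the whole network reachable, which is the sense in which the seed
set is a minimal nutritional footprint. Because any single member of a
seed SCC would do, each member is exported as a candidate with confidence
1/|SCC|; confidences within a component sum to 1, and no one-per-component
selection is enumerated (downstream indices consume the weighted
candidates directly).

Degenerate cases: a network that is one big SCC (or whose only sources
have no outgoing edge, e.g. an isolated node or a singleton with a
self-loop) has an *empty* seed set. Empty seed sets are representable and
serialisable but poisoned for index computation — asking for an
interaction index raises an error rather than silently returning 0.

## Interaction indices

For an ordered pair (A, B), with w_A the confidence map of A's candidate
seed compounds:

- competition(A→B) = Σ w_A(c) over c that are candidate seeds of both,
  divided by Σ w_A(c) over all of A's candidates;
- complementarity(A→B) = Σ w_A(c) over c that are nodes of B's network
  but not candidate seeds of B, same denominator.

The denominator equals A's number of seed components, which makes
self-competition exactly 1, self-complementarity exactly 0, and both
indices lie in [0, 1]. The two numerator predicates are disjoint subsets
of A's candidates, so competition + complementarity ≤ 1 for every ordered
pair. Membership is tested at the compound-identifier level against B's
full candidate set, not against any one-per-SCC selection. A
compatibility note: other formulations of the "support of A by B" index
normalise by the number of A's seeds found in B's network rather than by
all of A's seeds; the normalisation used here is the one that preserves
the shared [0, 1] scale and the ≤ 1 bound with competition.

### Permutation null

No closed-form null exists for these indices, so significance is
estimated by resampling *which* SCCs of B act as sources: each null
replicate draws |B's seed components| components uniformly without
replacement from B's full SCC partition, keeps their sizes (hence their
1/|SCC| confidences), and recomputes the index against A's observed
seeds. This conditions on B's network modularity (the SCC size spectrum)
and randomises only seed placement. The p-value uses the add-one
estimator p = (1 + #{null ≥ observed})/(1 + n_perm), so p > 0 always;
n_perm < 99 is rejected as too coarse. All draws derive from a single
integer seed and are reproducible.

## Co-occurrence and the Mantel test

Presence of a species in a sample means abundance strictly greater than
`presence_threshold` (default 0, i.e. any positive abundance; coverage-
style cutoffs such as 1 % are selection criteria for which species to
analyse, not presence calls, so they are settable but not the default).
Co-occurrence of two species is the Jaccard similarity of their presence
profiles — |samples with both| / |samples with either| — with 0 by
convention for pairs present nowhere; species absent from every sample
are kept (with a warning) and score 0 off-diagonal.

The Mantel statistic is the Pearson correlation over **all** n(n−1)
off-diagonal cells of the two matrices. Using all cells (rather than one
triangle) is deliberate: interaction matrices are directed and genuinely
asymmetric, and for symmetric matrices the two conventions give the same
correlation. The null permutes rows and columns of the second matrix
jointly (permuting either matrix is equivalent; the second is fixed for
reproducibility). The default alternative is two-sided on |r|, since both
positive (competition vs co-occurrence) and negative (complementarity vs
co-occurrence) associations are of interest; one-sided variants are
available. Sampled nulls use the add-one estimator; `exact=True`
enumerates all n! permutations (capped at n = 8) and reports the exact
orbit fraction, identity included. Tie handling uses a 1e-12 tolerance so
the observed statistic always counts as its own exceedance. Constant
off-diagonal input makes the correlation undefined and is an error, not a
silent 0.

## Synthetic data generator

The generator is first-class code: it defines the conditions under which
every statistical claim in the test suite is evaluated.

`random_reaction_set` draws reactions with 1–3 substrates and 1–3
products, disjoint within a reaction, over a universe of C-numbered
compounds, with independent Bernoulli reversibility (default 0.3, roughly
the proportion of reactions KEGG marks reversible in genome-scale sets).

`planted_community` builds species bottom-up from their seed compounds
outward: every species is an acyclic cascade of irreversible single-
substrate reactions, so all SCCs are singletons, the planted seeds are
exactly the sources, and every confidence is 1 — ground truth is exact,
not approximate. Competitor pairs share a `seed_overlap` fraction of seed
compounds (default 0.8, rounded to whole compounds); a complementary pair
embeds one species' seeds as produced, non-seed nodes of the other; all
remaining compounds are unique per species, so unrelated pairs score
exactly 0 on both indices. After construction the generator re-runs the
detector and raises if the detected seeds differ from the planted ones,
rather than trusting its own construction. Defaults are 6 species, 40
reactions per species, 8 seed compounds each, a 2000-compound universe —
small enough to run thousands of communities in seconds, large enough
that index denominators are not trivially small.

What the generator does *not* emulate: realistic (scale-free) degree
distributions, currency-metabolite hubs, multi-substrate coupling between
species, or annotation noise. Passing the planted-recovery tests
therefore shows the indices recover engineered structure through the full
pipeline, not that they are robust to the hub compounds and incomplete
annotations of real genomes — for real data the `exclude` list exists
precisely because seed sets are sensitive to hub compounds, and its
default is empty.

`null_abundance_table` produces independent sparse lognormal abundances
(50 % zeros), i.e. no true co-occurrence structure, for calibrating the
Jaccard/Mantel stack.

## Numerical and design choices

- Reaction direction is taken from the equation arrow; sources lacking a
  direction flag default to reversible (the conservative choice for KGML-
  style inputs), switchable in configuration.
- Component ordering (by lexicographically smallest member) and all
  serialisations are deterministic, so outputs are byte-reproducible.
- Confidence sums are checked to 1e-9; index closed-form comparisons in
  tests use 1e-12; permutation tie tolerance is 1e-12.
- SCC computation delegates to networkx; its output — the unique maximal
  SCC partition — is verified in tests against an independent
  transitive-closure mutual-reachability oracle on hundreds of random
  digraphs.
- The KEGG fetcher caches per organism in the same flat format the parser
  reads, making repeated analyses offline and cache contents
  human-inspectable; stdlib urllib is used for the two REST endpoints
  involved (link/reaction and get).
- Problem sizes in the test suite and acceptance script (digraphs ≤ 30
  nodes, 100-community batches, 1000 Mantel replicates at 999
  permutations) were chosen so each check is statistically meaningful yet
  the whole suite runs in seconds; the Mantel permutations are evaluated
  as one vectorised batch per replicate.

## Known limitations

- Topology-only modelling ignores stoichiometry, cofactor balance and
  flux feasibility; it can call a compound producible when no feasible
  flux distribution produces it.
- Indices depend on annotation completeness; missing reactions inflate
  seed sets and can inflate competition between well-annotated relatives.
- The permutation null conditions on the SCC size spectrum but not on
  degree structure; networks whose sources are topologically atypical may
  receive conservative p-values.
- Live KEGG retrieval requires network access on first use; only the
  cached path is exercised by the offline test suite.
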