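# Methods

## Model and assumptions

The package predicts protein–protein interactions (PPIs) from domain
content alone. The underlying assumption is that interactions are
mediated by domain–domain contacts: if proteins carrying domains
`d_a` and `d_b` are repeatedly observed to interact, a new pair carrying
the same domains is likely to interact too. Everything downstream —
features, labels, negative sampling — is expressed over unordered Pfam
domain pairs; sequences are never touched. Protein pairs are unordered
(`(a,b) ≡ (b,a)`), enforced by lexicographic canonicalization at
construction so duplicates cannot survive parsing.

Consequences of the assumption worth keeping in mind: proteins without
Pfam annotation are unusable and are filtered (with counts) at read
time; paralogs with identical domain architecture receive identical
scores; and a domain pair never seen in training can only be scored
through the embedding geometry, not through its observation weight.

## Dataset construction

**DDI inference** takes, for each positive pair, the full cross product
of the two domain sets, accumulated with multiplicity (a shared domain
yields a self-pair). This deliberately over-generates: each observed
interaction names every domain pair that *could* mediate it.

**Negative sampling** draws human–human pairs satisfying three rules:
disjoint, nonempty tissue-label sets (proteins never co-expressed in an
organ are unlikely to meet); no cross-product domain pair in the
golden-standard DDI set; absence from the positive set and the known
human interactome. Sampling is uniform over the qualifying pairs for a
fixed seed. Cross-species negatives are possible via a flag but off by
default — the tissue rule is only meaningful for host proteins.

**Splitting** partitions at the requested fractions (default
0.70/0.11/0.19), then repairs: any held-out positive whose inferred DDI
set is not covered by the training positives moves to training, iterated
to a fixed point. Moves only grow the training DDI set, so the loop
terminates; records are moved, never dropped. Negatives split freely —
the coverage constraint is defined on DDIs inferred from interacting
pairs. The realized fractions therefore drift toward training; the
coverage report states the per-partition DDI counts.

## Pair representation

The corpus has one sentence per positive training pair: candidate DDIs
as two sequential tokens, cross pairs in lexicographic order, and the
bacterial protein's domain first in cross-species pairs (a fixed
convention so reruns are identical; for same-species pairs the
lexicographically smaller protein id leads). The skip-gram window of 1
keeps each token's context dominated by its DDI partner; the spurious
adjacency between the last token of one candidate DDI and the first of
the next is accepted as part of the sentence design.

The trainer is a minibatched skip-gram with negative sampling written on
numpy: unigram^0.75 noise distribution, 5 negatives per positive,
linearly decaying learning rate from 0.025 to 1e-4, logits clipped to
±30 for a stable sigmoid, minibatch 512 with gradient accumulation via
scatter-add. Batched SGD (rather than per-pair updates) is what makes
single-threaded training fast while remaining exactly reproducible for a
fixed seed. Defaults: dimension 100 per domain (so the concatenated
pair vector is 200-long), 10 epochs, min-count 1 (domain vocabularies
are small compared to natural-language ones; discarding rare domains
would silently drop proteins).

Pair vectors are weighted means, not sums, so multi-domain proteins stay
on the same scale as single-domain ones; the weight of a domain pair is
its observation count among training positives plus a pseudo-count of 1,
so unseen combinations remain representable at prediction time. The
vector is a convex combination of the concatenated domain-pair vectors —
coordinate-bounded, invariant to domain listing order and to rescaling
all weights by a constant.

## Classifier protocol

The forest is scikit-learn's `RandomForestClassifier` used as a
contract: bagged trees, per-split feature subsampling, probability =
mean of tree votes. The module's substance is the protocol: grid search
(trees × feature rule) scored by validation accuracy with ties broken by
grid order; decision-threshold tuning as an exhaustive scan over the
distinct predicted validation probabilities (classification rule
`score ≥ t`), keeping the smallest threshold among ties; F1 is the
default objective (Youden's J and accuracy are alternatives) because the
deployment regime — screening a vastly imbalanced candidate space —
cares about the precision/recall trade-off. After tuning, the forest is
refit on train+validation with the chosen configuration and evaluated
once on test at the fixed threshold; a leakage guard raises if any pair
key appears on both sides.

Metric edge cases: PREC/REC with zero denominators return 0 with a
warning (a degenerate evaluation should be reportable, not fatal); ROC
vertices are grouped per distinct score and AUC is the trapezoidal area,
which equals the normalized Mann–Whitney U statistic.

## Network assembly and clustering

All host × bacterial pairs are enumerated deterministically (sorted
pools, host-major) and scored in batches; the default cutoff of 0.99
operationalizes "probability approaching 1" and is exposed. Isolated
proteins are not added as nodes. Sequence-identity clustering is an
*input* (a precomputed UniRef90-style map), not a computation —
reimplementing MMseqs2 would be out of proportion; the identity map is
used when given and defaults to the identity function. Parallel edges
merge keeping the maximum probability, preserving the high-confidence
selection semantics (mean and count are alternatives).

Fuzzy clustering merges same-side clusters when normalized Levenshtein
similarity of case-folded gene names is ≥ 0.70 AND the Pfam sets
intersect, with single-linkage components labeled by their smallest
member. Clusters with empty gene names only merge with other unnamed
clusters carrying an identical Pfam set (logged); name similarity with
an empty string is meaningless and treated as 0.

## Network analytics

All statistics run on simple undirected graphs; path-based terms are
computed per connected component.

* **IVI.** Three multiplied factors — (degree + H-index + sum of
  neighbor H-indices), (neighborhood connectivity + ClusterRank),
  (betweenness + collective influence) — with every component min–max
  scaled to [1, 100] before summation, and the product scaled to
  [1, 100] again; on any non-regular network the top node scores exactly
  100. A component that is constant across nodes scales to 1 for all
  (degenerate-range rule; a single-node graph scores 1). Ranges within
  relative 1e-9 of zero count as constant so floating-point jitter in
  accumulated path counts cannot masquerade as structure. ClusterRank
  uses `f(c) = 10^(−c)` (the original dampening) and plain degree for
  the neighbor out-degree term, since the network is undirected.
  Betweenness is the unnormalized unordered-pair path-fraction sum
  (scikit-network-style Brandes via networkx). Collective influence
  uses shell radius ℓ = 3 by default, capped per node at its
  eccentricity within its component — a fixed small radius is the
  standard choice and the cap keeps small components well-defined.
* **Assortativity** is the Pearson correlation of remaining degrees
  (degree − 1) across edge endpoints, equivalently the double sum over
  the joint remaining-degree distribution. Regular graphs have zero
  remaining-degree variance and return an undefined sentinel (`None`)
  rather than raising or dividing by zero.
* **Null model.** Degree-preserving double-edge-swap rewiring with
  10·|E| attempted swaps, rejecting self-loops and parallel edges;
  graphs whose nodes carry a two-valued `side` attribute are rewired
  within the bipartition. The degree sequence is exactly invariant.
* **Correlation profile.** Joint edge fractions over log2-width degree
  bins (stable sparse tails; bin = ⌊log2 k⌋), compared to the mean and
  standard deviation over the randomized ensemble: Z = (P − E[P_r])/σ.
  Bins with zero ensemble variance are reported as missing, never
  infinite. Note the statistical floor of this statistic: for a graph
  exchangeable with its own ensemble, a dense bin's |Z| averages ~0.8
  (half-normal), and a sparse bin spikes to ~1/√p on the rare draws
  that contain it, so even a perfect null shows a nonzero mean |Z|; the
  profile is meant to be read against that baseline, which is exactly
  what the structured-versus-randomized test does.

## Synthetic worlds

The generator emulates the statistical structure the pipeline assumes:
a planted set of interacting domain pairs (5 % of all pairs by default)
of which a random half plays the golden-standard role; interaction
probability β = 0.9 for pairs sharing a planted DDI against ε = 0.02
background noise; 150 human proteins with 1–2 tissue labels from a pool
of 6; 5 strains × 40 bacterial proteins; 1–4 domains per protein from a
60-domain vocabulary with one domain tied to the protein's gene-name
root (so fuzzy clusters have recoverable planted structure); gene names
as root+suffix with roots kept ≥ 2 edits apart (names from different
roots can never reach the 0.70 merge threshold); 1500 positives drawn by
rejection over random pairs (linear in the request, not quadratic in the
catalog); 1500 negatives drawn by the real sampler so the exclusion
rules hold by construction; a 300-pair known human interactome;
lognormal strain abundances normalized to fractions; disorder fractions
nonzero for ~25 % of human and ~2 % of bacterial proteins (Beta(2,4)
when nonzero), mirroring the qualitative host/bacteria contrast of
disorder annotation databases.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: the heavy-tailed frequency
distribution of real Pfam domains, correlated domain architectures,
taxonomic structure among strains, tissue-ontology relationships between
organ labels, and label noise in curated PPI databases beyond the flat ε
background. In particular, the residual test error in the recovery
experiment is dominated by a designed ambiguity: negatives may share
*non-golden* planted DDIs (the golden filter covers only half the rules),
so a fraction of negatives is genuinely indistinguishable from positives
in domain space.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline at the
default world size (350 proteins, 3000 labeled pairs, 30 000 candidate
pairs), which this package treats as its reference desk-scale
experiment; brute-force oracles run on graphs of up to 50 nodes, where
exhaustive path enumeration is exact. Every stochastic step — world
generation, splitting, embedding initialization and batching, negative
sampling, forest construction, edge swapping — draws from a seeded
generator; derived seeds are spawned from the top-level seed, and two
runs with the same seed produce byte-identical output files.

## Known limitations

* Scoring all pairs is exhaustive by design; for proteome-scale pools
  the streaming scorer bounds memory but not time.
* The identity-cluster map must be provided for true sequence-redundancy
  collapse; the default identity map only exercises the mechanics.
* The decision-threshold objective and the grid ranges are configuration,
  not dogma; on real data they should be revisited.
* Fuzzy clustering's idempotence holds for name structures like the
  planted root+suffix scheme; adversarial name sets could in principle
  chain further on a second pass because merged clusters inherit a
  representative name and the union of Pfam sets.
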