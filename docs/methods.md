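# Methods

## Model

`nbclda` treats every lncRNA–disease pair (l, d) as a binary class variable
(associated / not associated) and the pair's common neighbours in a
heterogeneous network as the evidence.  Under the naive conditional
independence assumption, the posterior odds of association factorize over
features:

    S(l, d) = φ · ∏_f  φ⁻¹ · (N_f⁺ + 1) / (N_f⁻ + 1)

* φ = p₁ / (1 − p₁), with p₁ = |known associations| / (n·r), is the prior
  odds that a uniformly random pair is associated.  By default n and r are
  the full registry sizes — every lncRNA and disease seen in any layer
  counts, including those with no known association (`restrict_to_ldn`
  switches to the covered-nodes convention).
* A feature f is a common neighbour of l and d.  On the tripartite
  network these are miRNAs adjacent to l (miRNA–lncRNA layer) and to d
  (miRNA–disease layer).  On the quadruple network, genes join via the
  gene–lncRNA and gene–disease layers, and a common miRNA m and common
  gene g that interact (gene–miRNA layer) merge into one *pair feature*
  whose adjacency requires adjacency to both m and g.
* N_f⁺ is the number of known associations whose two endpoints are both
  adjacent to f; N_f⁻ = Nl_f·Nd_f − N_f⁺ is the number of unknown pairs in
  f's adjacency rectangle.  Conservation N⁺ + N⁻ = Nl·Nd is enforced at
  construction of every count object.
* Laplace add-one smoothing keeps every factor positive, so with at least
  one known association all scores are strictly positive.

Design choices where the formulation was genuinely open:

* **One φ⁻¹ per feature.**  In the quadruple network each feature —
  singleton miRNA, singleton gene, or miRNA–gene pair — contributes
  exactly one φ⁻¹ factor, so k features contribute φ^(1−k) overall.  This
  keeps the quadruple score a strict generalization of the tripartite one:
  with empty gene layers the two are identical (tested).
* **All connected combinations become pairs.**  When one common miRNA
  interacts with several common genes (or vice versa), every connected
  (m, g) combination becomes a pair feature, and any node covered by at
  least one pair is removed from the singletons.  This rule is
  deterministic and order-independent, unlike a maximal matching.
* **Saturated and empty priors.**  |known| = 0 gives φ = 0 and an all-zero
  score matrix; the degenerate case where every pair is known gives
  infinite odds and an all-infinite matrix.  Neither occurs in evaluation
  (leave-one-out always removes an edge).

Normalization is S′ = ln(S)/λ (natural log; the base only rescales and
never re-ranks).  `lambda_mode="auto"` sets λ = max |ln S| over positive
entries, mapping scores into [−1, 1]; a fixed positive λ is also accepted
for replication attempts.  λ is global, not per-disease.  Zero raw scores
map to a sentinel one unit below the minimum finite normalized score so
they rank strictly last.

## Disease semantic similarity

Each disease's MeSH tree numbers expand by dotted prefixes into an
ancestor DAG; node identity is the tree-number string, so one MeSH heading
occupying two tree positions counts as two nodes (a plain tree-number
table carries no heading-merge information; this is a documented
divergence risk versus pipelines that merge headings).  An ancestor at
minimum hop distance k contributes Δ^k (the max-over-children recursion),
with Δ ∈ (0, 1], default 0.5 — the standard choice for this family of
measures.  DV(d) is the sum of contributions and

    SD(di, dj) = Σ_{t ∈ Ti ∩ Tj} (D_i(t) + D_j(t)) / (DV(di) + DV(dj))

is symmetric with unit diagonal and values in [0, 1].  Diseases without
tree numbers receive identity rows.  The combined score S = S′ × SD is
implemented as a disease-space matrix product (smoothing each pair's score
over semantically similar diseases); an element-wise reading would need a
reference disease the formula does not supply, so the matrix product is
the implemented interpretation.

## Evaluation

**LOOCV.**  Each known association is held out in turn; the prior and all
per-feature counts are recomputed without it (no label leakage), scores
are normalized and optionally similarity-combined, and the held-out pair
is ranked among all candidate pairs outside the training positives.
Candidates are global (the full n×r grid minus training edges) by default;
`per_disease=True` restricts them to the held-out disease's column, which
is the other defensible reading of per-disease candidate ranking.  Ties
receive half credit (Mann–Whitney convention), the round statistic is
(#negatives below + 0.5·#ties)/#negatives, and the pooled AUC is the mean
over rounds.  The reported ROC is the empirical CDF of the per-round false
positive rates.  Because normalization is monotone and similarity
combination is applied after it, the AUC is exactly invariant to λ
(tested for λ ∈ {1, 10, auto}).

**Top-k F1.**  A seeded generator samples ⌈train_fraction·|known|⌉
associations (default 20 %) as the training set; the network is rescored
with only those known; the top-k candidates (score descending, ties broken
by lncRNA then disease name) are compared against the held-out
associations.  Precision = TP/k, recall = TP/|held out|, F1 harmonic.
Identical seeds reproduce reports bit-for-bit.

## Synthetic data

The generator emulates the statistical structure the scorer assumes:
association probability rising with shared neighbours.  Each evidence
layer is i.i.d. Bernoulli(density); each (l, d) pair is planted as a known
association with probability logistic(a + b·k) where k is its common
miRNA-plus-gene neighbour count.  Defaults: 40 lncRNAs, 30 diseases, 25
miRNAs, 15 genes, density 0.1, a = −3, b = 1.2 — sparse layers (expected
common-neighbour count ≈ 0.4 per pair) and roughly 5–10 % association
density, sizes at which a leave-one-out run over all ~100 planted
associations completes in well under a second.  The logistic planting is
deliberately *not* the scoring formula, so signal recovery is not
self-confirmation.  The two-level random ontology (diseases sharing a
random root prefix are similar) exercises the semantic-similarity
machinery but is statistically independent of the planted associations —
so on synthetic data similarity re-weighting verifies mechanics and
cannot be expected to raise the AUC, unlike on real MeSH annotations where
similar diseases share associated lncRNAs.  The generator also makes no
attempt to match the heavy-tailed degree distributions of curated
databases; passing tests demonstrate correctness of the computation and
recoverability of planted signal, not real-data performance.

Registries returned by `generate` include isolated nodes, keeping the
candidate grid at exactly n×r.  Reading a written dataset back through the
edge-list files rebuilds registries from edge endpoints, so a node that is
isolated in every layer drops out; at the default densities this is rare
and only perturbs the prior denominator slightly.

## Numerical notes

* `score_all` evaluates the product in log space over boolean adjacency
  matrices and agrees with the definition-level per-pair path to ~1e−10
  relative; the per-pair path agrees with an independent brute-force
  enumeration oracle to 1e−12 relative (tested on hundreds of random
  networks).
* AUC uses midrank-based Mann–Whitney (`scipy.stats.rankdata`), which is
  exactly the exhaustive pairwise count with half-credit ties.
* All output tables sort deterministically (score descending, then name
  order), and every source of randomness funnels through one integer seed.

## Limitations

* The conditional-independence assumption ignores correlation between
  overlapping features (e.g. two miRNAs with near-identical neighbour
  sets count twice).
* Pairs with no common neighbours all collapse to the prior odds φ and tie
  in the ranking; the method cannot order them.
* Name matching is exact string equality after trimming; alias resolution
  must happen upstream.
* Whether per-disease or global candidate sets (and tie handling) are used
  shifts third-decimal AUC values; both are exposed, global is the
  default for stability on sparse association sets.
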