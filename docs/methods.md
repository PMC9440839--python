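# Methods

## Model

`biodocsim` scores the similarity of two biomedical documents from three
evidences and fuses them in two stages.

**MeSH evidence.** MeSH headings occupy nodes of a forest of 16 category
subtrees; a node is addressed by a dotted tree number whose segments encode
the full ancestor chain, so depth, lowest common ancestor (LCA) and path
length are prefix computations — no graph search is needed, and two nodes
whose first segments differ have no common ancestor and score 0. Node
similarity is one of:

* Wu–Palmer: `2·depth(lca) / (depth(v) + depth(v'))`, with the convention
  that a top-level segment has depth 1 (this keeps the measure positive and
  well defined for every within-subtree pair);
* Leacock–Chodorow: `log(nodepath / 2·Dmax) / log(1 / 2·Dmax)` where
  `nodepath` is the edge path length plus one (avoiding `log 0` at identity)
  and `Dmax` is the maximum node depth of the shared subtree; the division by
  the measure's maximum rescales it to [0, 1] so it is commensurate with the
  other evidences;
* Lin: `2·IC(lca) / (IC(v) + IC(v'))`, defined as 1 at identical nodes and 0
  otherwise when both IC values are 0;
* Jiang–Conrath: distance `d = IC(v) + IC(v') − 2·IC(lca)` mapped to a
  similarity by `1/(1 + λ·d)`. The damping parameter λ > 0 (default 1)
  controls how quickly similarity decays with IC distance; the transform maps
  [0, ∞) onto (0, 1] and equals 1 at d = 0. Other decay shapes (e.g.
  `exp(−λ·d)`) would fit behind the same interface; the rational form was
  chosen because it gives λ a plain damping role over the 1–5 range the
  measure is typically swept over.

Information content is corpus-based with IS-A propagation: every node's
cumulative count is its own annotation count plus its descendants'; implicit
ancestors (prefixes that carry no heading) are materialized so the chain is
complete. Probabilities are normalized **per subtree** — each category is its
own probability space — because cross-subtree similarity is fixed at 0 and a
global normalizer would never be consumed. `IC(v) = −log p(v)`, so each
top-level node has IC 0 and IC never decreases toward the leaves. Annotation
counts default to dataset-local frequencies (each document increments every
tree number of every heading it carries); add-one smoothing (default 1) keeps
IC finite on sparse corpora where most nodes are never annotated.

Sets aggregate by **average maximum match** (AMM): for sets M, M′ with
pairwise similarities `sim`,

```
AMM(M, M') = [ Σ_{v∈M} max_{v'∈M'} sim(v,v') + Σ_{v'∈M'} max_{v∈M} sim(v,v') ]
             / (|M| + |M'|)
```

applied twice — node sets → heading similarity, heading sets → document
similarity. AMM avoids the downward bias of all-pairs averaging when a
heading has several nodes of which only one is relevant. Headings absent from
the forest are dropped with a warning (vocabulary mismatch is not
dissimilarity) and do not count toward |M|; a document with no resolvable
headings has undefined MeSH evidence and is an error by default, with an
opt-in policy that scores its pairs 0.

**Embedding evidence.** A document's average semantic vector (ASV) is the sum
of its in-vocabulary token vectors divided by their count (token multiplicity
counts, out-of-vocabulary tokens are skipped), then Z-scored across its own
components with the population standard deviation (the estimator choice only
rescales the vector and cancels in cosine, but fixing it makes the contract
testable). Document similarity is the cosine of the two ASVs. Cosine can be
negative; the matrix builder maps evidences to the shared [0, 1] scale with a
"clip negatives to 0" default ("shift" `(x+1)/2` and "raw" are selectable) —
clipping distorts least near the operating range, where meaningful
similarities are positive.

**Content evidence.** TF-IDF with raw term frequency and smoothed idf
`ln((1+N)/(1+df)) + 1` (classic `ln(N/df)` selectable), compared by cosine of
the nonnegative vectors; a zero vector scores 0 against everything.

**Fusion.** A feedforward network with 2 inputs, 300 ReLU hidden units and a
sigmoid output maps (Sim_MeSH, Sim_WE) to a single semantic similarity.
Training pairs come from per-topic relevance labels: both documents DR
(definitely relevant) for the same topic → target 0.9, both PR (possibly
relevant) for the same topic → 0.5, anything else → 0.1. The loss is mean
squared error, optimized full-batch with Adam (learning rate 1e-3) for 100
epochs; weights are initialized uniformly in ±1/√fan_in from the run seed, so
training is deterministic given (pairs, seed). A ReLU on the *input* layer is
the identity on [0, 1] similarities and is therefore a documented no-op. The
network is retrained per experiment (it encodes the dataset's label geometry)
and is JSON-serializable for reuse. Pairs whose evidence is undefined never
enter training (with the default error policy they cannot arise).

The fused similarity is `Sim_F = w·Sim_Con + (1 − w)·Sim_Sem` with
w ∈ [0, 1], default 0.7, after both matrices are normalized to [0, 1].
The default normalization is min-max over the off-diagonal entries (diagonal
pinned at 1; a constant off-diagonal maps to all zeros). A "sumnorm" variant
— divide by the off-diagonal sum, then the same [0, 1] rescale — is kept
selectable; note that because the rescale is affine, the two coincide except
for the degenerate zero-sum case.

## Evaluation protocol

Spectral clustering on the fused matrix: symmetric-normalized graph Laplacian
`I − D^{-1/2} S D^{-1/2}`, the k smallest-eigenvalue eigenvectors
(`scipy.linalg.eigh`), row normalization, then k-means with a seeded
initialization (`sklearn`, `n_init=10`). Isolated vertices are handled by an
additive 1e-10 on the adjacency, logged. k is the number of true topics in
each dataset.

Metrics are computed from the truth×prediction contingency table: purity
(majority-class share per predicted cluster), Rand index from conventional
pair counts (TP = same class & same cluster, FP = same class & different
clusters, FN = different classes & same cluster, TN = the rest), adjusted
Rand index via the Hubert–Arabie closed form of the permutation-model
expectation (the degenerate all-in-one case is defined as 1), NMI with
natural-log entropies and the geometric-mean denominator (arithmetic mean
selectable; a zero-entropy side gives 0, both sides zero gives 1), and the
Fowlkes–Mallows index `TP/√((TP+FP)(TP+FN))` (0 when undefined).

Dataset construction mirrors the retrieval-judgment protocol: documents
judged under two or more topics are removed first, then topics with nine or
fewer documents. Doing the multi-topic removal first makes the filter
idempotent (the opposite order can push a topic below the threshold only on a
second pass). 100 datasets are sampled, each a uniform-size random subset of
3–12 topics, without replacement within a subset, reproducibly under a seed.
In `evaluate_datasets` the evidences and the fusion net are computed once on
the full corpus; per dataset, the semantic and content matrices are subset,
re-normalized within the dataset, fused, and clustered — recomputing TF-IDF
and retraining per dataset would change little on well-separated corpora and
would multiply runtime by the dataset count.

## Synthetic data

The generator emulates what the method assumes of real MEDLINE data and
nothing more: topic-specific MeSH headings placed as near-siblings of one
deep branch (within-topic node pairs meet at depth 3 of a depth-4 leaf,
cross-topic pairs meet at depth 1 or not at all; every third heading carries
a second node in a separate subtree to exercise multi-node headings),
topic-clustered word vectors (topic center = a random direction scaled to the
separation parameter, per-word gaussian noise), and bag-of-words documents
drawn from a 70/30 mixture of topic and shared vocabulary. Defaults: 5 topics
× 40 documents, 6 headings/topic with 20% shared, 4 headings/document,
80-word topic vocabularies plus 40 shared words, 60 tokens/document,
dimension 50, separation 3.0, noise sd 0.5, half of each topic's documents
DR and half PR. These sizes are desk-scale and well separated but not
trivial; they are the conditions under which the package's end-to-end tests
and the acceptance script operate.

What the generator does **not** emulate: real MeSH topology (16 subtrees,
thousands of nodes, qualifier structure), natural language (no grammar, no
Zipfian vocabulary, no polysemy), realistic label noise (every document's
topic is correct by construction), and corpus-scale class imbalance. Passing
tests therefore demonstrate the correctness and integration of the machinery
— measure formulas, aggregation, training dynamics, clustering and metrics —
not retrieval performance on real literature, where the evidences are far
noisier and the fused matrix's advantage is an empirical question.

## Numerical choices and edge cases

* Natural logarithms throughout (base cancels in Lin and NMI, rescales λ in
  Jiang–Conrath).
* The Jiang–Conrath distance is clamped at 0 before the transform to absorb
  float cancellation.
* Matrix builders evaluate the same reduction as the pairwise functions on
  the same cached values, so matrix and pairwise paths agree bit-for-bit (a
  tested contract); heading-pair similarities are cached once per matrix.
* Ties inside AMM's max need no tie-breaking (the max is over values).
* min-max normalization of a constant off-diagonal yields all zeros by
  convention; normalization requires n ≥ 2.
* Fusion weights 0 and 1 short-circuit to exact copies, making the limit
  contracts (`w=0` ↦ Sim_Sem, `w=1` ↦ Sim_Con) bitwise.
* Degenerate inputs raise typed errors: no in-vocabulary tokens or no
  resolvable headings (`UndefinedEvidenceError`), a constant averaged vector
  (`DegenerateVectorError`), zero cumulative counts with zero smoothing.
* Token-order invariance of the ASV holds to float-summation tolerance
  (~1e-15 per component), not bitwise; appending out-of-vocabulary tokens is
  bitwise invariant.

## Known limitations

* The word2vec reader handles the text keyed-vector format only (the binary
  variant is out of scope); `restrict_vocab` keeps memory proportional to the
  retained vocabulary for large files.
* MeSH qualifiers, supplementary concept records and year-to-year vocabulary
  versioning are not modeled.
* The spectral embedding's k-means step is seeded but, like all k-means,
  only locally optimal; `n_init=10` makes flips on well-separated data
  vanishingly rare rather than impossible.
* `evaluate_datasets` shares one TF-IDF fit and one trained net across
  datasets (see above); pass separate corpora if per-dataset fits are needed.
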