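# Methods

## Problem and model

`dtlink` treats drug–target interaction (DTI) discovery as link prediction
on a bipartite chemogenomic graph. The working assumption is the classic
similarity principle: similar drugs tend to bind similar targets. The
pipeline therefore never looks at 3D structure; its only inputs are
compound structures (or precomputed fingerprints), protein sequences, and
a partially observed interaction table.

Two weighted, undirected similarity networks carry all the signal:

- **M_DDS (drug–drug).** Each compound is a 166-bit structural-key (MACCS)
  fingerprint; the edge weight is the Tanimoto coefficient
  |A∩B| / |A∪B| ∈ [0, 1]. Fingerprinting is delegated to RDKit; its
  167-bit MACCS vector has an unused bit 0 which is dropped.
- **M_PPS (protein–protein).** The edge weight is a normalized pairwise
  alignment score, S(a,b) / √(S(a,a)·S(b,b)), clamped to [0, 1] so that
  self-similarity is exactly 1.

Node embeddings turn these networks into features: second-order biased
random walks generate a corpus of node sequences, and skip-gram with
negative sampling learns an n-dimensional vector per node. A (drug,
target) pair is represented by concatenating the two vectors (2n columns,
drug block first) and classified by a gradient-boosted tree ensemble that
outputs an interaction probability. Unknown pairs are then ranked by that
probability and filtered for repurposing (high confidence + approved
drug).

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| embedding dim n | 100 | per-network vector size; pairs get 2n = 200 features |
| walk bias p, q | 1, 1 | return / in-out bias; 1,1 reduces to weight-proportional walks |
| walks per node r, length l | 10, 80 | corpus size per node (word2vec/node2vec reference defaults) |
| window w, negatives k | 10, 5 | skip-gram context width and noise samples per positive |
| epochs, learning rate | 5, 0.025 | SGD passes; lr decays linearly to 1e-4 of its start |
| activity threshold | 5.5 pChEMBL | positive-label cutoff (≈ 3 µM); sub-threshold actives are "weak" and excluded |
| external fraction | 0.1 | one stratified hold-out drawn before any training |
| folds × repeats | 10 × 5 | stratified CV on the internal pool, folds redrawn per repeat |
| tree depth / subsample / min child weight / γ | 4 / 1.0 / 2 / 0.8 | boosted-tree regularization (fixed winning values) |
| boosting rounds | ≤ 200 | early stopping on validation log-loss, patience 20, whenever a fold's test set is available; refits without a validation set use all rounds |
| probability threshold | 0.99 | candidate cutoff for repurposing |
| f_β selection metric | β=2 or 1 | β=2 (recall-weighted) when negatives are sampled from unknowns, because false positives are then unreliable; β=1 with validated negatives |

Alignment defaults are local mode, BLOSUM62, gap open −10, gap extend
−0.5 (a length-L gap costs open + (L−1)·extend). The substitution matrix
is modified so that the ambiguity residue X scores 0 against everything —
a neutral treatment that neither rewards nor penalizes unknown residues.
The alignment mode, matrix, penalties and normalization are configurable;
they are conventions of the similarity-calculation tools common in this
area, not uniquely determined choices.

## Evaluation protocol

The external test fraction is drawn once (stratified). For each repeat the
internal pool is split into stratified folds; a grid search (when a grid
is supplied) scores every candidate hyperparameter setting by mean
internal-test f_β over the folds, with ties broken toward smaller depth and
then a fixed lexicographic parameter order so candidate enumeration order
is irrelevant. The repeat's winner is refit on the whole internal pool and
applied exactly once to the external test. External pairs never
participate in grid search, model selection or fitting; the split object
validates disjointness explicitly. The final deliverable model is refit on
all labelled pairs with the most frequently selected spec.

Metrics: precision and recall from the confusion matrix at threshold 0.5
(precision defined as 0 when nothing is predicted positive), f_β from the
standard formula, AUC as the Mann–Whitney statistic (ties count ½), and
AUPR by the step-wise average-precision construction. The test suite
cross-checks each against independent brute-force oracles (set counting,
a separately written Gotoh dynamic program, O(P·N) pair counting, and a
threshold-sweep AP sum).

## Determinism

Every stochastic stage draws its seed from a single root seed through
named child seeds (stage name CRC32 mixed into a `SeedSequence`), so
stages are reproducible independently of each other. The walk and
skip-gram inner loops are numba-compiled with their own explicit RNGs
(xorshift64*), trees are built single-threaded with the histogram method,
and graphs are canonicalized to sorted-node-id order before walking —
permuting the node insertion order changes no per-node vector. Two full
pipeline runs under one seed are bit-identical end to end; the acceptance
script measures this difference and reports 0.

Skip-gram is trained by plain sequential SGD in the word2vec style
(dynamic context windows of size uniform in 1..w, noise distribution
∝ corpus frequency^0.75, negatives equal to the context node skipped).
The similarity matrices have a unit diagonal by definition; walks treat
that as a non-edge — a walker never steps from a node to itself.

## Synthetic data

The fixture generator plants exactly the structure the method assumes:

- drug clusters: one random 166-bit prototype per cluster, members get
  independent bit flips (default 5%);
- protein families: one random ancestor sequence per family (default
  length 120), members get per-site substitutions to a different residue
  (default 5%);
- interactions: pair (d, t) is truly active with probability
  block[cluster(d), family(t)] — default 0.9 in-block, 0.05 out —
  then the observed label flips with 2% noise. Positives carry a
  synthesized pChEMBL activity uniform in [5.5, 10); negatives carry an
  inactive flag, so both labelling routes are exercised.

The reference conditions are 60 drugs in 4 clusters and 50 proteins in 3
families with balanced negatives, which gives ≈ 2,000 labelled pairs.
Under those conditions the pipeline's external-test AUC is ≈ 0.87–0.92
and recall ≈ 0.82–0.90 across seeds (the acceptance script recomputes
this).

What the generator does *not* emulate: real chemistry (fingerprints are
random bit patterns, not molecules), phylogenetics (star-shaped families,
uniform substitutions, no indels), assay heterogeneity (one activity per
pair, uniform activity distribution), and the extreme class imbalance and
sparsity of real interaction tables. Passing the planted-structure tests
shows the machinery recovers block signal transmitted through fingerprint
and sequence similarity; it does not certify performance on any real
compound or target collection.

## Numerical and design choices

- Tanimoto of two all-zero fingerprints is defined as 1 (both featureless)
  and logged, avoiding 0/0 while flagging uninformative compounds.
- Similarity matrices are computed once per unordered pair, so symmetry is
  exact; entries are float64 and written with 6 decimals (embeddings and
  features are written at full precision and round-trip to 1e-12).
- Similarity graphs are kept dense by default; `sparsify` is opt-in and
  reports nodes it isolates.
- An explicit inactive flag beats any activity value during labelling;
  conflicts are counted and logged. Duplicate measurements for one pair
  can be median-reduced at read time (`duplicates="median"`); the default
  is a hard error.
- Weak pairs (0 < pChEMBL < threshold, not flagged inactive) are excluded
  from training *and* from the unknown pool used for prediction.
- CV splits are over pairs (warm-start); a drug or target may appear on
  both sides of a split. Cold-start splitting is a known harder setting
  and out of scope here.
- Negative sampling from unknowns is drawn once per run seed, not redrawn
  per repeat.
- The boosted-tree "γ = 0.8" is interpreted as the tree-split
  regularization parameter (min loss reduction), not the learning rate,
  which stays a separate, grid-searchable parameter.
- Probability cutoff 0.99 for candidates: the method's stated cutoff reads
  "≥ 0.99%", which would be vacuous against a ranking goal; it is read as
  probability ≥ 0.99 and is configurable.

## Problem sizes used in the checks

The automated checks run the reference fixture (above, ≈ 40 s per full
pipeline run), alignment-oracle comparisons on random sequences of length
≤ 12 where exhaustive dynamic programming is cheap, Monte-Carlo walk
checks with ≥ 5,000 observed transitions (3σ binomial bands), and the
printed-size unknown-pair identities up to 791 × 989 pairs. Metric oracles
run on hundreds of random small instances with deliberate score ties.

## Known limitations

- Skip-gram quality on very small graphs (< ~15 nodes) is noisy; the
  embedding is meant for networks with real neighborhood structure.
- Dense second-order walks cost O(|V|) per step; for very large dense
  similarity matrices the walk stage dominates and sparsification is
  advisable.
- The classifier's probabilities are used as a ranking score and a
  high-confidence filter; they are not calibrated.
- Alignment parameters are conventions, not fitted values; protein
  similarity based on whole-sequence alignment underweights domain-level
  relationships.
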