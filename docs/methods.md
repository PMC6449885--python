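# Methods

## Model

The predictor treats miRNA–disease association as a bipartite link
prediction problem solved by neighborhood recommendation on two
similarity networks that are built *independently of the association
matrix*.

### Information-weighted profile similarity

Both the miRNA network and the disease functional network use the same
kernel. An entity's profile is a target set (mRNAs for miRNAs, genes
for diseases). Each target t has a global weight p(t) = n(t)/N, where
n(t) is the number of sources interacting with t and N the total
number of unique interactions in the table. The profile "entropy"

    H(S) = − Σ_{t ∈ S} p(t)·log2 p(t)

is computed literally as FCMDAP defines it: the p(t) over a
profile do not sum to one, so H is a sum of per-target information
weights rather than the entropy of a normalised distribution
(pseudo-entropy). We deliberately do not renormalise. Similarity is

    SM(A, B) = 2·H(T_A ∩ T_B) / (H(T_A) + H(T_B)).

Properties relied upon (and tested): SM ∈ [0, 1], because the
intersection's nonnegative term sum is contained in each profile's;
exact symmetry; base-invariance of the ratio (base 2 fixed so entropy
values themselves are reproducible). The kernel is *not* provably
monotone in added shared targets — adding a shared target also inflates
the denominators — so monotonicity is probed empirically, not asserted
pairwise.

Degenerate inputs: an entity absent from the table has an empty
profile, H = 0, all similarities 0, *including its diagonal* — an
entity with no evidence is deliberately not "similar to itself" so the
recommender never routes weight through it. A target with p(t) = 1
contributes 0 (log 1 = 0).

### Family boost and genomic clusters

Same-family pairs (miRBase miFam-style assignments) have their
similarity doubled: miRNAsim = SM·(1 + FAM). The result may exceed 1
(range [0, 2]) and is left uncapped: every downstream score normalises
by the same weights, so scores stay in [0, 1], and capping would
silently erase the family signal exactly where SM is already high.

The cluster relation CLU(i, j) = 1 holds when two miRNAs lie on the
same chromosome with an inter-interval gap (0 if overlapping) strictly
below 20 kb (default; configurable in bp). Strand is ignored and no
transitive closure is taken — the relation is pairwise. FAM and CLU
diagonals are forced to 0; self-pairs never enter neighbor sums.

### Disease semantic similarity

MeSH Category-C tree numbers define a DAG: tree number a.b.c has
parent a.b, and an edge links a disease to the disease owning the
parent number. A disease with several tree numbers unions its ancestor
sets. Contributions decay per edge with Δ = 0.5 (the conventional
decay of this family of semantic measures): D_A(A) = 1,
D_A(t) = Δ·max over children of t on paths toward A, implemented as a
max-relaxation over the parent map (terminates because the DAG is
acyclic and Δ < 1); DV(A) = Σ_t D_A(t).

    DD(A, B) = [Σ_{t∈T_A∩T_B} D_A(t) + Σ_{t∈T_A∩T_B} D_B(t)] / (2·min(DV(A), DV(B)))

The **min** in the denominator is the form FCMDAP defines, although
this family of semantic measures conventionally uses
DV(A) + DV(B). We follow the min form by default and expose the
conventional one (`denominator="sum"`). Because the min-form is not
provably bounded by 1, values above 1 are clamped with a warning rather
than silently propagated; the sum-form never needs the clamp.

Integrated disease similarity: SD = γ·SDF + (1−γ)·DD, applied as-is —
a disease missing from the gene table contributes SDF = 0, one missing
from the DAG contributes DD = 0.

Disease names are matched between the association table and the
gene/MeSH tables case-insensitively after trimming whitespace, because
the source databases capitalise inconsistently; ids are otherwise kept
verbatim.

### Scores

For pair (i, j), with neighbor selection always excluding the entity
itself and ties in descending-similarity sorts broken by stable input
id order (bit-reproducible runs):

* s1: over the top-k1 positive-similarity neighbors of miRNA i,
  Σ sim·AS(k, j) / Σ sim (fewer than k1 positive neighbors: use those;
  zero denominator: 0);
* s2: same form over i's cluster members (no cluster: 0);
* S_miRNA = α·s1 + (1−α)·s2, applied unconditionally — a miRNA with no
  cluster gets α·s1, exactly as the formula dictates. The alternative
  fallback (S_miRNA = s1 when the cluster is empty) is available via
  `cluster_fallback=True`;
* S_disease: over the top-k2 neighbor diseases of j,
  Σ AS(i, k)·SD(k, j) / Σ SD(k, j);
* FC = β·S_miRNA + (1−β)·S_disease.

The zero-denominator convention (score 0) encodes "no evidence"
uniformly. Every component is a weighted mean of 0/1 values followed by
convex combinations, hence in [0, 1]. Cold-start behaviour needs no
special casing: an all-zero association column zeroes the miRNA-space
score and an all-zero row zeroes the disease-space score.

### Parameters

| name | default | meaning |
|------|---------|---------|
| alpha | 0.5 | weight of the k-NN score vs the cluster score in miRNA space |
| beta | 0.8 | weight of miRNA space vs disease space |
| gamma | 0.5 | weight of functional vs semantic disease similarity |
| k1 | 50 | miRNA neighbors |
| k2 | 30 | disease neighbors |
| delta | 0.5 | semantic decay per DAG edge |
| cluster_threshold_bp | 20000 | genomic cluster gap cutoff (bp) |

Defaults are the operating point reported for the benchmark corpus
this method was developed on (α, β from a 0.1-step grid search; γ, k1,
k2 set by experience there). On small datasets k1/k2 may exceed the
entity count, in which case all positive-similarity neighbors are
used.

## Evaluation

Leave-one-out cross-validation deletes each known association (i, j)
in turn, rescores disease j's column, and ranks i among the candidate
miRNAs (those with no verified association to j in the full data, plus
i). Similarity matrices are computed once outside the loop — they
never depend on AS, so nothing about the held-out pair leaks. The
per-fold work is a column-restricted computation that is tested to
agree with naive full-matrix recomputation rank-for-rank (numerically,
the vectorised column and matrix paths agree to floating round-off).
One subtlety makes this cheap: the disease-space score for column j
never weights column j itself, so removing (i, j) changes only the
miRNA-space part of the column.

The ROC pools a rank cutoff c over all folds: a fold's top min(c, n)
candidates are called positive, its single positive is recovered iff
rank ≤ c; TPR = TP/(TP+FN) and FPR = FP/(TN+FP) are computed from
summed counts and the AUC is the trapezoidal integral. This pooled AUC
is tested to agree with the tie-corrected Mann–Whitney concordance of
the fold ranks to within 1/(2·candidate count). Both the global pooled
AUC and the unweighted per-disease mean are reported, since "average
AUC" is ambiguous between the two readings.

Cold-start evaluation zeroes an entity's associations, rescores, and
takes the tie-corrected Mann–Whitney AUC of true vs non-associated
partners; an all-zero score vector gives 0.5 by construction.

The grid sweep re-blends cached per-fold score components for each
(α, β) pair rather than re-running the pipeline.

## Synthetic data

The generator emulates the statistical structure the method exploits,
at desk scale: 50 miRNAs, 20 diseases, 5 blocks, 200 mRNAs, 150 genes.
miRNAs are assigned round-robin to blocks and diseases to matching
groups. Within a block, each miRNA draws 10 targets, each with
probability 0.7 (`target_overlap_within_block`) from a 20-mRNA block
pool and otherwise uniformly; diseases draw 8 genes against a 15-gene
group pool. Group members sit as siblings under a per-group root in
the generated tree-number table. Associations are planted only inside
block/group pairs, with the within-block probability calibrated so the
matrix density equals `association_density` (0.15) *after* the noise
channel flips each cell with probability `noise_rate` (0.02); every
miRNA and disease is then guaranteed at least one association, matching
the min-degree-1 property of real curated networks. Half of the blocks
(in expectation) are additionally marked as a family and half placed
as a genomic cluster (members 1580 bp apart, so every within-block
pair is inside the 20 kb cutoff; non-clustered miRNAs are megabases
apart).

All draws come from named sub-streams of a single seed, so bundles are
bit-reproducible and adding a component never perturbs existing ones.
Disease columns are reordered to row-major first-appearance order so
that exporting the pair table and re-reading it reproduces the bundle
exactly.

What the generator does *not* emulate: realistic name vocabularies,
genome-scale sizes, degree heavy tails, deep or multi-parent MeSH
topologies, and correlated database biases. Passing the planted-signal
tests therefore shows the pipeline recovers the kinds of structure the
method assumes (target sharing, family/cluster co-association, DAG
adjacency) at small scale — not that it attains any particular
performance on real corpora.

Noise-flipped cross-block associations are genuinely unpredictable by
design; at the defaults ~10% of folds are such noise, which bounds the
attainable LOOCV AUC below 1. The negative control shuffles the miRNA
assignments *within each disease column* (preserving disease degrees);
note that permuting whole columns between disease labels would leave
the miRNA-space signal intact, since s1/s2 consume the association
column as a unit, so the within-column shuffle is the meaningful null.

## Numerical and design choices

* Log base 2 everywhere; the similarity ratio is base-invariant.
* Ties broken by stable input order at every sort; runs are
  deterministic given inputs and seed.
* Duplicated input pairs are dropped with a warning; a miRNA assigned
  to two families is an error (ambiguous membership); duplicate GFF3
  records keep the first with a warning.
* Problem sizes in the test-suite oracles (brute-force similarity at
  ≤10×15, DAG path enumeration at ≤8 nodes, naive LOOCV at ≤20×10,
  10⁴-fold Monte-Carlo ROC null) are chosen so each oracle is
  exhaustive yet runs in seconds.

## Known limitations

* The min-denominator semantic similarity is kept as printed; with the
  clamp it is bounded, but it is not the measure's conventional form.
* k1 = 50 exceeds the synthetic miRNA count, so at desk scale s1
  averages over all positive-similarity neighbors; discrimination
  comes from the similarity weights alone.
* The evaluation protocol scores one held-out pair per fold against
  candidates defined by the *full* data (standard for this family of
  methods), which slightly flatters methods when a disease has many
  known associations.
* No score calibration to probabilities and no negative-sample model;
  scores are ranking scores only.
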