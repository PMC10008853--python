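# Methods

This note records the model, the numerical choices and the limits of what
the test suite demonstrates. Notation: an expression matrix X of n genes by
d features (min-max normalized per feature), memberships U (n×k),
prototypes V (k×d), a sparse symmetric penalty-weight matrix W over gene
pairs.

## Density-tracking constraint mining

Density of gene i is `1 / max_{j in N_b(i)} ||x_i − x_j||`, the inverse
radius of its b-nearest-neighbour ball (plain Euclidean norm). From each
gene we repeatedly step to the *closest* strictly-denser gene inside the
current gene's b-neighbourhood; the resulting chain ends at a gene with no
denser neighbour in its own neighbourhood. Because the step out of a gene
depends only on that gene, chains that meet anywhere share their entire
suffix, so grouping chains "by common endpoint" is the same as taking
connected components of the successor forest — that is how groups are
computed. Centrality of a gene is the number of chains it appears in
(equivalently its subtree size in the successor forest; every gene's own
chain counts, including length-1 chains), and a chain's centrality is the
sum over its members.

Impurity is the product of two terms: the Gini impurity of the group
composition of S = {i} ∪ N_b(i) (size b+1), and the relative density
deficit 1 − Density(i)/Density(endpoint). The product form makes sparse
boundary genes maximally impure and chain endpoints exactly pure. The
formula as printed admits more than one bracketing; the product reading is
implemented because it is the one consistent with the stated purpose
(scoring cluster-boundary genes). Values are clamped to [0, 1].

Constraint generation (quotas default to max(10, n/20) per kind):

* **CL**: per descending impurity, pair the gene with its nearest gene
  outside its density group. With a single group the CL set is empty and a
  warning is emitted.
* **ML (boundary)**: per descending impurity, pair the gene with its chain
  successor j if Density(j) ≥ ε·Density(endpoint); ε defaults to 0.8.
* **ML (skeleton)**: per descending chain centrality, walk each chain from
  its start emitting (c[t], c[t+stride]) pairs; stride defaults to 2. The
  walk interval is not fixed by the method description, so it is a
  configurable parameter.

Impurity and neighbour ties break toward the lowest gene index, making the
mining fully deterministic. A pair is never emitted as both ML and CL
(first-come, CL first by stage order).

## Ontology similarity and fusion

p(t) is the annotation frequency of term t under the true-path rule
(a gene annotated to t counts toward every ancestor of t), with the number
of annotated genes in the loaded map as denominator — the artifact is
self-contained and does not consult any external annotation corpus.
IC(t) = −log p(t) in nats; SW(t) = 1/(1+exp(−1/IC(t))) with the continuity
value SW = 1 at IC = 0 (the root); SV(t) sums SW over the ancestor closure
T_t (t included). Term similarity is 2·Σ_{T_t1∩T_t2} SW / (SV₁+SV₂); gene
similarity is the symmetric best-match average over the two annotation
sets. Thresholds 0.9 / 0.1 are strict inequalities; unannotated genes
contribute no ontology constraints and similarity queries on them raise an
explicit error rather than returning 0.

Fusion assigns, for θ ∈ (0, 1):

| expression \ ontology | ML* | absent | CL* |
|---|---|---|---|
| ML | 1+θ | 1−θ | removed (contradictory) |
| CL | removed | −(1−θ) | −(1+θ) |

Pairs present only in the ontology set carry weight 0 but remain in the
candidate pool, so the evolutionary selection can still pick them (their
value is then informational only). θ ≥ 1 flips the sign of single-source
weights and is allowed with a warning. Contradictory pairs are removed from
both constraint sets before anything downstream sees them.

## Objectives and membership update

The two minimized objectives are the Xie–Beni index
XB = Σ u²d² / (n·min prototype separation²) and the penalized
quadratic-regularized fuzzy c-means cost
J_P = Σ u·d² + (η/2)Σu² − (β/2)ΣΣ w_ij⟨u_i, u_j⟩, with squared Euclidean
distances throughout. Memberships come from the closed-form update
u = 1/k + (1/η)u^Q + β·u^P, where u^Q is the per-gene centred negative
squared distance and u^P propagates membership along constraint weights.
Both corrections are zero-sum over clusters, so rows of U sum to 1
analytically; memberships are **not** clipped to [0,1] — with η = 0.001
they are signed and large (magnitude ~1/η), which is intrinsic to the
quadratic regularization, and crisp labels are taken by argmax. u^P depends
on U, so the update iterates as a fixed point from u^P = 0, at most 10
passes or until the max-abs change drops below 1e-6 (the update is a
contraction for the β values used; in practice 2–3 passes suffice).

Degenerate cases: coincident prototypes give XB = +∞ (a sentinel fitness
the selection naturally discards); a cluster with zero membership mass
keeps its incumbent prototype in `recompute_prototypes`.

### Why there is no Lamarckian prototype write-back

An obvious refinement is to recompute V from U after each evaluation and
write it back into the chromosome. With signed memberships of magnitude
~1/η the weighted-mean update has near-zero or negative column masses and
throws prototypes to the corners of [0,1]^d: starting from density-peak
prototypes that reproduce the planted partition exactly, three write-back
iterations degrade the ARI from 1.0 to ~0.7 on the standard synthetic
study. Prototypes are therefore pure decision variables refined only by the
genetic operators; `recompute_prototypes` remains available as a library
function.

## Evolutionary loop

Mixed encoding: k×d reals in [0,1] plus s distinct integers in [1, 2s]
indexing the candidate pool (drawn uniformly without replacement from the
post-fusion union of both constraint sets — the union, so ontology-only
pairs are selectable). Half the initial population (⌈N/2⌉) carries
density-peak prototypes (largest ρ·δ, where δ is the distance to the
nearest denser gene and, for the global maximum, the largest pairwise
distance), the rest uniform random.

Operators per generation: rank-biased roulette selection with score
α(1−α)^(rank−1), normalized over the population (the raw scores are not
probabilities); normal-distribution crossover for prototypes with one
shared |N(0,1)| per coordinate (offspring conserve the parents' sum until
clamping); single-point crossover with duplicate repair for the selection
block; polynomial mutation (distribution index η_m) per prototype site with
probability p_m; single-site random-reset mutation of the selection block
with probability p_m per individual ("first randomly select a position" —
one site, not per-site). Survivors are the best N of parents + offspring by
(rank, crowding); crowding-distance boundary points get +∞. The penalty
parameter β doubles after generations ⌈0.5·L_max⌉ and ⌈0.8·L_max⌉. The
run returns the final rank-1 set; the reported solution is the front member
whose crisp labels maximize the silhouette index, ties toward lower XB then
lower J_P. Front members whose labels collapse to one cluster are
silhouette-undefined and rank last.

Each individual is evaluated against only its s selected constraints —
that restriction is the mechanism by which selection suppresses noisy
constraints. A `force_all_constraints` switch evaluates every individual
against the whole pool and serves as the ablation baseline.

Default parameters (reference configuration): ε = 0.8, b = 10, η = 0.001,
β = 0.1, N = 100, L_max = 300, α = 0.3, η_m = 5, p_c = 0.8, p_m = 0.1,
θ = 0.5 (mid-range of the 0.4–0.7 that per-dataset tuning typically
selects; the silhouette is quite insensitive to θ). One seeded RNG drives
every stochastic step, so runs are bit-reproducible.

## Validation

Silhouette uses plain (not squared) Euclidean distances; singleton clusters
get width 0, and the all-singleton labeling has index 0 by the same
convention. The adjusted Rand index is the standard contingency-table form
(scikit-learn). Both are invariant to label permutation; the silhouette is
additionally translation invariant.

## Synthetic study and what it shows

`make_expression` draws k isotropic Gaussian blobs. Separation follows the
c-separation convention for Gaussian mixtures: minimum pairwise mean
distance = separation·σ·√d, i.e. separation is measured against the
within-cluster RMS radius σ√d, which is the scale on which blobs actually
overlap in high dimension (a 6σ Euclidean gap in d = 10 would still mix
neighbourhoods badly). `make_ontology` gives each cluster one branch of a
two-level tree under a common root (head, two mid terms, two leaves) and
annotates each gene with 2–4 terms of its own branch, except an
`annotation_noise` fraction annotated in a foreign branch.
`inject_constraint_noise` replaces an exact rounded fraction of constraints
with label-inconsistent pairs of the same kind.

The benchmark (`linkclust.benchmark`, also driven by
`scripts/acceptance.py`) uses n = 200, d = 10, k = 4, separation 6, five
replicate seeds, and a scaled-down evolutionary budget of N = 40,
L_max = 50 — a run finishes in roughly a second and the qualitative
behaviour is stable at this size. The density-tracking neighbourhood for
this study is b = n/(2k) = 25: b must be commensurate with the expected
cluster size, since a neighbourhood much smaller than a cluster leaves
several density peaks per cluster and oversegments the group structure
(the b = 10 default is the reference setting for real datasets of a few
hundred genes, where cluster sizes are smaller).

What passing tests show: on well-separated Gaussian clusters with
concordant annotations the mined constraints are label-consistent, the
planted partition is recovered (ARI 1 at this separation), constraints
never hurt the silhouette, and under 30% pool noise constraint selection
does at least as well as being forced to use every candidate. What they do
not show: behaviour on real microarray time courses (autocorrelated
features, non-Gaussian noise, unbalanced clusters), on sparse or biased
real GO annotation (where the 0.9/0.1 thresholds interact with annotation
depth), or the full-scale reference configuration (N = 100, L_max = 300) whose
extra budget mostly matters on harder, less separated data.

## Known limitations

* k is fixed by the user; there is no automatic model selection over k.
* The O(n²) distance matrix and the all-pairs gene-similarity scan limit
  the practical size to a few thousand annotated genes.
* Only `is_a` ontology edges are honoured (`part_of` is ignored), and no
  evidence-code filtering is applied to annotations; namespace filtering is
  available as a CLI option but off by default.
* Silhouette-based final selection can prefer a coarser partition when
  clusters are barely separated.
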