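# Methods

## The model

### Disease DAGs and information content

A disease is identified with a MeSH Category C descriptor. Its DAG
contains the descriptor plus the owner of every proper dotted prefix of
each of its tree numbers, with edges from the more general to the more
specific term; a heading reachable through several tree numbers appears
once. When an intermediate tree number has no descriptor record (possible
in truncated files), the level is skipped and the child is attached to the
nearest resolvable ancestor, with a logged warning.

Information content of a term t is IC(t) = −log(N_DAG(t)/TN_DAG), where
N_DAG(t) counts the disease DAGs containing t and TN_DAG is the number of
diseases in the corpus. The corpus is, by default, the set of diseases in
the loaded association table rather than all of MeSH Category C: the
specificity of a term is then relative to the diseases actually under
study, and every similarity value reflects the dataset at hand. The
natural log is the default; the choice is immaterial because densities
normalize by the maximum IC, so the base cancels (verified by a dedicated
test to 1e−8).

### Fuzzy densities and the Sugeno λ-measure

Densities are FD(t) = cap · IC(t)/max_d IC(d). Terms with IC = 0 (present
in every DAG) carry no discriminating information and are pruned. The
**cap** (default 0.999) keeps the single maximum-IC term strictly below
density 1: at FD = 1 the λ equation

  1 + λ = ∏ᵢ (1 + λ·FDᵢ)

loses its root in the required interval whenever that term co-occurs with
others (the density sum exceeds 1 but the objective stays negative on
(−1, 0)). Scaling every density by the same cap preserves ordering and
restores a guaranteed bracket. The cap is configurable; results are
insensitive to it in (0.99, 0.9999).

λ solving: the equation always has the trivial root λ = 0; the
measure-defining root is negative when Σ FD > 1 and positive when
Σ FD < 1. We use bracketed Brent iteration — (−1 + 1e−12, 0) or (0, hi)
with hi doubled until a sign change — followed by a few Newton steps in
extended (80-bit) precision with the analytic derivative, because at large
roots (tiny densities) a float64 product evaluation rounds at ~eps·|λ| and
would mask convergence. Degenerate cases fixed by definition: a singleton
density set and a set with Σ FD = 1 (within 1e−12) get λ = 0, the additive
limit, which is the unique continuous choice. If ∏(1−FDᵢ) underflows the
bracket offset the root is numerically −1 + 1e−12; the residual there is
below 1e−12.

The Sugeno measure of a subset is evaluated by the defining recursion
g(T) = FD(t) + g(T∖t) + λ·FD(t)·g(T∖t), which is order-independent and
equals the closed form (∏(1 + λ·FDᵢ) − 1)/λ; the test suite checks the two
against each other rather than collapsing them into one code path. The
empty set measures 0, a singleton its own density — so the similarity of
two diseases sharing exactly one term is that term's density, independent
of either λ.

Disease similarity: FS(a, b) = (g_{λₐ}(Tᵢ) + g_{λᵦ}(Tᵢ))/2 over the shared
term set Tᵢ (densities are global, so both sides agree on them). An empty
intersection scores 0. FS(a, a) = 1 because λ is defined exactly so that
the full set measures 1; the matrix builder pins the diagonal to 1 to
avoid solver-tolerance noise. A disease whose every term is universal has
an empty density set; its row is 0 (including the diagonal) and downstream
integration treats it like an unmapped disease.

### LncRNA functional similarity

Best-match group average (see README for the formula). The matrix
construction exists twice: a per-pair reference used by the public API and
a vectorized path (one matrix product after per-lncRNA best-match
reductions) used inside cross-validation loops; a test pins them to each
other at 1e−12.

### Kernels, integration and the predictor

Gaussian interaction-profile kernel: K(i,j) = exp(−γ‖IP(i)−IP(j)‖²) with
γ = γ′ / mean‖IP‖², γ′ = 1 by default. All-zero profiles contribute zero
to the bandwidth mean and are otherwise legal; only an entirely empty
matrix is rejected.

Expression similarity is Spearman correlation mapped affinely to [0, 1] by
(r+1)/2 so every similarity component shares a range; a clamp-at-0 mapping
is available where anticorrelation should not rank above independence.
Constant profiles have undefined rank correlation: their off-diagonal
entries are set to 0 and the lncRNA is flagged to the caller.

Integration is the unweighted entry-wise mean of the available components
(semantic + kernel for diseases; functional + kernel [+ expression] for
lncRNAs). Entries involving an entity with no semantic/functional score —
a disease name that failed MeSH mapping, a lncRNA whose training-time
disease group is empty — fall back to the kernel value alone, so no entity
is silently dropped.

The predictor solves F = (I + ηL)⁻¹Y with L = I − D^(−1/2)·W·D^(−1/2) in
the lncRNA space and, on the transposed label matrix, in the disease
space, then averages the two score matrices with weight w. Defaults
η_lnc = η_dis = 1.0 and w = 0.5, all configurable and snapshotted into
every evaluation output. This is a standard normalized-Laplacian
regularized least-squares formulation of the two-space scoring scheme;
I + ηL is symmetric positive definite for any η > 0, and a zero-sum
similarity row falls back to the identity (labels pass through
unsmoothed), which also yields the exact F = Y limit for an identity
similarity.

## Cross-validation design

Global LOOCV withholds each known association in turn; repeated k-fold
(default 5 folds, 100 repeats) withholds fold-sized batches. In both, the
Gaussian kernels **and** the group-based functional similarity are
recomputed from the masked training matrix — the functional similarity
depends on the association matrix through the disease groups, so freezing
it would leak the held-out label. The disease semantic similarity depends
only on MeSH and is computed once. A test instruments the scorer to verify
that every training matrix seen during LOOCV has exactly the held-out
entry zeroed.

Held-out pairs are ranked against the candidate set: all pairs never
observed as associated in the full data. The ROC curve is the average of
per-positive step curves in candidate-rank space; a positive tied with c
candidates contributes a linear ramp across the tied block, which makes
the trapezoidal area equal the Mann–Whitney statistic with half-credit
ties exactly (cross-checked to 1e−10). Ranked candidate lists break score
ties lexicographically on lncRNA id so outputs are byte-reproducible.

## The synthetic corpus

`FixtureConfig` defaults: a 120-term forest (depth ≤ 4, fan-out ≤ 4),
25 diseases in 5 DAG-coherent blocks (each block drawn from one subtree),
40 lncRNAs assigned evenly to blocks, association probability 0.6 within a
block against a 0.02 background, and 12-sample expression profiles built
from block means plus Gaussian noise (σ = 0.5). These sizes keep a full
LOOCV under a second while leaving ~120 planted positives, and the
within/background contrast plants the "similar lncRNAs — similar diseases"
structure the model assumes. `shuffle_associations` provides the matching
null: a uniform permutation of the association labels that preserves the
positive count but destroys the block alignment.

What the generator does **not** emulate: the long-tailed term-frequency
and annotation-depth imbalance of real MeSH (every synthetic disease has a
single tree number and similar DAG depth), literature-curation bias in
association databases, and dependence between expression and disease
blocks beyond the shared assignment. Passing tests therefore demonstrate
correctness of the computation and recoverability of a planted signal at
desk scale, not expected AUCs on any particular curated database; the CLI
runs unchanged on real MeSH descriptor files and database exports.

## Known limitations

- Converting a DAG to a density set discards the hierarchy itself; two
  diseases sharing terms at very different depths are compared only
  through the shared terms' global specificity.
- Name reconciliation is exact (normalized) matching only; synonyms such
  as "lung cancer" vs the heading "Lung Neoplasms" must be resolved
  upstream, and unmatched names are surfaced rather than guessed.
- MeSH is read in the ASCII `*NEWRECORD` dialect only; supplementary
  concept records, qualifiers and the XML distribution are out of scope.
- The predictor is the standard two-space Laplacian-RLS scheme with a
  single η per space; no kernel learning or weighted fusion beyond the
  configurable averaging weights.
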