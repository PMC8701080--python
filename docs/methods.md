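# Methods

## Problem setting

The input is a cells × genotype-sites matrix of binary somatic-mutation
calls from single-cell DNA sequencing: 1 = mutation present, 0 = absent,
plus a missing state for sites with no usable read. Three error processes
corrupt it: false positives with rate FPR (amplification artifacts turning
a true 0 into 1), false negatives with rate FNR (allelic dropout turning a
true 1 into 0), and missing entries with rate MR. Because the cells of a
tumor belong to a modest number of subclones, the clean matrix is
(approximately) low-rank: it has only as many distinct rows as there are
subclones. The package exploits exactly that structure.

## Extended robust deep autoencoder

The observed matrix `X` (missing entries zero-filled; Ω = observed index
set) is decomposed as `X = LD + S` by minimising

```
‖LD − D_θ(E_θ(LD))‖²_F + λ‖P_Ω S‖₁   s.t.  LD + S = X
```

- `LD` is the "low-rank" part — not constrained by an explicit rank but by
  having to pass through a bottlenecked autoencoder.
- `S` collects entrywise errors. Penalising only `P_Ω S` is the crux of the
  extension: outside Ω the pair (LD, S) is unconstrained except for
  `LD + S = X = 0`, so `S = −LD` there carries the imputation residual and
  the missing entries of `LD` are free — they converge to whatever the
  autoencoder predicts from the cell's observed profile.

The alternating solver (one outer iteration):

1. `LD ← X − S`
2. refit θ: `inner_epochs` passes of minibatch Adam on the reconstruction
   loss of the rows of `LD`, warm-starting from the previous θ
3. `LD ← D_θ(E_θ(LD))`
4. `S ← X − LD`; on Ω, `S ← sign(S)·max(|S| − λ, 0)` (the proximal map of
   λ‖·‖₁); entries off Ω are left untouched
5. convergence: `c1 = ‖X − LD − S‖_F / ‖X‖_F` and
   `c2 = ‖LS − LD − S‖_F / ‖X‖_F` with `LS` the previous `LD + S`; stop
   when either drops below ε or the iteration cap is reached

After step 4, `LD + S = X` holds exactly off Ω at every iteration (a unit
invariant), and on Ω the residual equals precisely the mass removed by the
soft-threshold — `c1` is therefore a direct readout of how much observed
signal is being attributed to noise.

`LD` is binarised at 0.5 (`≥` wins ties): with a sigmoid output layer each
entry of `LD` is a mutation probability, and 0.5 is the Bayes cut for
symmetric costs.

### Architecture and optimiser defaults

| parameter | default | rationale |
|---|---|---|
| encoder widths | `(min(512,m), min(128,m), max(8, ⌈m/8⌉))`, bottleneck clamped < m | smallest stack that compresses typical clone structure; decoder mirrors it |
| hidden activation | tanh | with relu the alternating loop reproducibly stalls in a collapsed fixed point that drops the private sites of small, late-arising subclones (dead-unit saturation); tanh reaches exact recovery of clean clone matrices |
| output activation | sigmoid | entries are probabilities in [0, 1] |
| inner_epochs | 30 | enough stochastic passes per outer sweep at desk scale |
| batch_cells | 64 | the per-step cost is fixed regardless of n (near-linear total runtime); 64 rather than a larger batch because at a few hundred cells a large batch collapses an epoch into one or two Adam steps, visibly degrading subclone separation |
| learning rate | 1e-3 (Adam) | standard; raise to ~1e-2 only for very small matrices where an epoch is a single step |
| λ | `1/√max(n, m)` | the classical robust-decomposition default; larger λ → sparser S (more aggressive denoising), override per dataset |
| ε | 1e-6; max 30 outer iterations | the normalised residuals plateau well before 30 sweeps at desk scale; hitting the cap returns the last iterate with `converged=False`, which is routine for noisy data since `c1` is bounded below by the shrinkage mass |

The autoencoder is a plain numpy MLP with hand-written backpropagation and
Adam — at these matrix sizes (thousands of cells, hundreds to a couple of
thousand sites) this runs in seconds to minutes on one CPU and keeps the
package free of heavyweight dependencies.

Determinism: every random draw (parameter init, batch shuffles, simulator,
Louvain) flows from explicit seeds; the same inputs, configuration and seed
give bit-identical traces, calls and trees. One scale caveat: the
normalised residuals c1/c2 and the shrink step are jointly scale-
equivariant (tested), but the end-to-end trace is not invariant to
rescaling X by a constant, because a sigmoid-output network is not
scale-equivariant and neither is an Adam trajectory.

## Subclone clustering

Exact k-nearest neighbours (k = 20, clamped to n−1) on Euclidean distance
between binarised genotype rows, distance ties broken by lower cell index;
edges re-weighted by Jaccard similarity of neighbour sets (shared-nearest-
neighbour weighting, zero-overlap edges dropped); Louvain modularity
optimisation at resolution 1.0. Clustering runs on the binary calls, not
the continuous `LD`, so it is invariant to the autoencoder's output scale.
The number of subclones is emergent. Labels are renumbered by decreasing
cluster size. `min_cluster_size` (default 1 = off) optionally folds tiny
clusters into their nearest cluster by consensus-genotype distance, for
noisy real data.

Louvain's greedy passes are order-sensitive on modularity plateaus; node
order is shuffled deterministically by the seed, so results are
reproducible, and permutation equivariance holds exactly on well-separated
data (asserted in tests) but only approximately near plateau ties.
Resolution sensitivity is likewise a property of the input: on recovered
matrices the partition is stable across resolution 0.5–1.5 (tested), on raw
noisy matrices it is not — which is an argument for denoising first, not a
knob to tune.

## Clonal tree

Per subclone, the consensus genotype takes the per-site majority among
member cells; an exact 50/50 tie resolves to 0, biasing toward the
ancestral (unmutated) state. The tree is the minimum spanning tree of
pairwise Euclidean distances between consensus genotypes — Kruskal with
lexicographic tie-breaking, because equal distances are common on binary
genotypes and the tree should not depend on iteration order. The root is
the subclone with the smallest mutation burden (the most-normal genotype;
ties → lowest label), edges are oriented away from it, and the tree is
serialised as Newick with the Euclidean edge weights as branch lengths.

## Simulator

`simulate_dataset` emulates the benchmark design for clone-structured SCGS
data:

- **Tree**: uniform attachment — clone k (k ≥ 1) picks its parent uniformly
  among clones 0..k−1; clone 0 is the unmutated normal root.
- **Mutations**: infinite sites — each site is placed on exactly one tree
  edge (uniformly), with every non-root clone guaranteed ≥ 1 private site;
  a clone's genotype is the union of mutations on its root path, so
  child ⊇ parent along every lineage and there is no back-mutation.
- **Cells**: every clone receives `min_cells_per_clone` (default 3, so
  consensus calls are majority-defined) and the remainder is multinomial
  with uniform clone probabilities.
- **Noise**: independent per entry — true 0 → 1 with probability FPR,
  true 1 → 0 with probability FNR, then the entry is erased to missing with
  probability MR. Masking after flipping keeps the three rates independent,
  as a factorial sweep design assumes. `degrade_missing` additionally
  raises the missing fraction of an existing matrix to a target rate, for
  robustness-to-sparsity experiments.

Defaults (300 cells × 200 sites × 10 subclones, FPR = FNR = 0.15,
MR = 0.3) are the benchmark operating point at desk scale. What the
simulator does **not** model: doublets, copy-number events, site- or
cell-specific error rates, and back-mutation. Tests passing on these data
therefore demonstrate correctness of the algorithmic machinery and
robustness to iid flip/missing noise — not performance under structured
artifacts present in real scSNV data.

## Evaluation metrics

Against a ground-truth matrix: FPNR = FP/(FP+TN) + FN/(FN+TP) ("positive"
= mutation); the FPNR ratio divides the recovered matrix's FPNR (all
entries) by the raw input's FPNR (observed entries only — a missing entry
has no call to be wrong), so values < 1 quantify denoising gain;
missing-imputation accuracy is the fraction of Ω̄ entries recovered
correctly (denominator = exact |Ω̄| rather than n·m·MR, avoiding rounding
bias and identical when MR is exact); error is the fraction of all n·m
entries wrong. Clustering is scored by ARI (permutation-model chance
correction), with NMI (arithmetic-mean normalisation) and V-measure as
auxiliary views. Sklearn supplies ARI/NMI/V-measure; the test suite checks
ARI against a from-scratch contingency-table implementation.

## Problem sizes used in the shipped checks

The packaged test suite and `scripts/acceptance.py` run the pipeline at
300 × 200 × 10 (clean and missing-only), 500 × 200 × 10 (full noise), and
sweep 200 × 120 × 8 along the FNR and MR axes with three replicates —
sizes chosen so the whole battery completes in minutes on a single CPU
while keeping ≥ 20 cells per clone, which is where the kNN default (k = 20)
is meaningful. The decomposition itself scales to thousands of cells ×
thousands of sites on one CPU because each Adam step touches a fixed
number of cells.

## Known limitations

- Binary genotypes only: no ternary/CNV states, no doublet deconvolution.
- The recovered matrix is only as identifiable as the clone structure:
  clones distinguished by very few sites can be merged by the clustering
  even when `LD` separates them (the README example finds 9 of 10 clones
  for exactly this reason).
- MST-on-consensus assumes subclone genotypes are close to their members'
  majority; heavily mixed clusters violate this before the tree does.
- Louvain determinism is seed-based, not canonical: a different seed can
  pick a different partition among near-equal-modularity optima.
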