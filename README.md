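# rdaclone

Denoising, subclone identification and clonal-tree inference for single-cell
SNV genotype matrices.

Single-cell genomics sequencing yields, per cell, a binary call for each
candidate mutation site — but the calls are corrupted by amplification
artifacts (false positives), allelic dropout (false negatives, often
10–40%), and missing bases (frequently over half the matrix). `rdaclone`
recovers the clean genotype matrix from such data with an **extended robust
deep autoencoder**, clusters the cells into tumor subclones with
**Louvain–Jaccard** community detection, and reconstructs the subclone
evolutionary tree as a rooted **minimum spanning tree** over consensus
genotypes. A ground-truthed simulator and the matching evaluation metrics
make the whole pipeline testable end to end without any external dataset.

## The model

Given the observed cells × sites matrix `X ∈ R^{n×m}` with observed-entry
index set Ω (missing entries zero-filled), the decomposition solves

```
min_θ  ‖LD − D_θ(E_θ(LD))‖²_F + λ‖P_Ω S‖₁    s.t.  LD + S = X
```

where `E_θ`/`D_θ` are the encoder/decoder of a small fully connected
autoencoder, `S` is a sparse error matrix, and `P_Ω` keeps only observed
entries. Restricting the ℓ1 penalty to Ω makes the missing entries free
parameters: they are imputed through the low-rank part `LD`. The problem is
solved by alternating, ADMM-style:

1. `LD ← X − S`; refit θ by stochastic gradient on `‖LD − D_θ(E_θ(LD))‖²`;
   `LD ← D_θ(E_θ(LD))`
2. `S ← X − LD`; soft-threshold the observed entries of `S` by λ
3. stop when `c1 = ‖X−LD−S‖_F/‖X‖_F < ε` or
   `c2 = ‖LS−LD−S‖_F/‖X‖_F < ε` (LS is the previous `LD+S`)

`LD` is binarised at 0.5 into genotype calls (the sigmoid output makes each
entry a mutation probability). Cells are then embedded in a k-nearest-
neighbour graph (Euclidean distance on calls), edges re-weighted by Jaccard
similarity of neighbour sets, and partitioned by Louvain modularity — the
number of subclones is not specified in advance. Finally each subclone's
consensus (per-site majority) genotype defines pairwise Euclidean
distances, whose minimum spanning tree — rooted at the fewest-mutations
subclone, the most-normal genotype — is the inferred clonal evolution tree.

## Worked example

Simulate a 300-cell × 200-site dataset with 10 subclones at realistic noise
(FPR = FNR = 0.15, MR = 0.3), then run the full pipeline:

```sh
rdaclone simulate --cells 300 --sites 200 --subclones 10 \
    --fpr 0.15 --fnr 0.15 --mr 0.3 --seed 3 --outdir sim/
rdaclone run --input sim/observed.tsv --outdir out/ --seed 1
# -> found 9 subclones; artifacts in out/
rdaclone evaluate --recovered out/recovered.tsv --truth sim/truth.tsv \
    --observed sim/observed.tsv \
    --pred-labels out/labels.tsv --true-labels sim/true_labels.tsv
```

prints (abridged):

```json
{
  "ari": 0.8861414621907862,
  "error": 0.03238333333333333,
  "fpnr_input": 0.30147150891213553,
  "fpnr_recovered": 0.11422626939613265,
  "fpnr_ratio": 0.3788957364771213,
  "missing_accuracy": 0.9683263009845289,
  "precision": 0.9278048780487805,
  "recall": 0.902588438308887
}
```

Reading: the input matrix carried a combined false-positive + false-negative
rate of 0.30; after recovery it is 0.11 (`fpnr_ratio` ≈ 0.38 — more than
half of the noise removed), 97% of the hidden entries were imputed
correctly, only 3.2% of all entries are wrong, and the recovered clustering
closely matches the true 10-subclone structure (ARI 0.89; two small clones
merged). `out/` also contains the rooted clonal tree (`tree.nwk`,
`tree_edges.tsv`), per-subclone consensus genotypes, and the convergence
trace (`convergence.tsv`).

The same analyses are available as a library (`rdaclone.run_pipeline`,
`rdaclone.decompose`, `rdaclone.cluster_cells`, `rdaclone.build_tree`), and
`rdaclone sweep` reruns the pipeline along one noise axis to reproduce
degradation curves.

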