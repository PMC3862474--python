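# coevotree

Mirrortree co-evolution analysis of protein pairs: score ortholog-family
pairs by the correlation of their evolutionary distance matrices,
evaluate the scores as a binary interaction classifier, and validate
the whole pipeline on synthetic benchmarks with known coupling.

## Who this is for

Interacting proteins tend to evolve in a correlated way: a lineage in
which one partner accumulates substitutions quickly is usually a
lineage in which the other does too.  The mirrortree method exploits
this to predict protein-protein interaction from sequence alone.  Given
two ortholog families X and Y aligned over the same n species, each is
summarized by its n(n−1)/2 pairwise evolutionary distances, and the
score is Pearson's correlation of the two distance vectors:

    r_XY = Σ (D_X,ij − D̄_X)(D_Y,ij − D̄_Y)
           / sqrt( Σ (D_X,ij − D̄_X)² · Σ (D_Y,ij − D̄_Y)² )

This package is for computational biologists who want to (a) run that
scoring on their own ortholog sets (pre-aligned multi-FASTA per
protein plus a TSV pair list), (b) evaluate how well the scores
separate interacting from non-interacting pairs — shuffled negative
controls, score densities, ROC/AUC, Matthews correlation coefficient
(MCC) versus threshold, sensitivity/specificity, conservation binning,
evolutionary-span stratification — and (c) test the machinery offline
on simulated families where the degree of co-evolutionary coupling is
known by construction.

Distances can be computed as p-distance, Kimura's corrected distance
−ln(1 − D − 0.2D²), the physico-chemical Categories distance (0.457
between-group cost), or pairwise maximum-likelihood distances under the
JTT or Dayhoff PAM001 replacement models.  See `docs/methods.md` for
the models and the design choices.

## Worked example

Simulate a benchmark of 10 interacting (coupling 0.9) and 10
non-interacting (coupling 0) protein pairs on one 20-species tree,
score every pair with JTT ML distances, and evaluate:

```sh
coevotree run --n-pairs 10 --seed 42 --out-dir demo
cat demo/report/summary.tsv
```

```
metric	value
n_pairs	20
n_status_scored	20
auc	0.89
peak_mcc	0.8
peak_threshold	0.9589770335
density_mode_interacting	0.9686888454
density_mode_noninteracting	0.9491193738
```

All 20 pairs had enough common species to be scored.  The AUC of 0.89
says a randomly chosen interacting pair outscores a randomly chosen
non-interacting one 89% of the time.  The MCC peaks at 0.80 at a score
threshold of ~0.96: predicting "interacting" for r ≥ 0.96 is the
balanced operating point.  Both score densities peak at high r (0.97
vs 0.95) — unrelated families correlate strongly too, because both
distance matrices mirror the same species tree; the classifier lives
off the small excess correlation of coupled pairs.  `demo/` also
contains the per-pair scores (`scores.tsv`), the ROC and MCC curves,
the simulated alignments, and a config echo + manifest that make the
run byte-reproducible.

The same stages are available separately (`coevotree simulate`,
`coevotree score`, `coevotree evaluate`) for user-supplied data, and as
library functions (`coevotree.score_pair`, `coevotree.roc`, ...).

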