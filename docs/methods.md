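# Methods

## The mirrortree score

Two proteins that interact — directly, in a complex, or through a shared
pathway — tend to accumulate substitutions in a correlated fashion: a
lineage in which one partner evolves fast tends to be a lineage in which
the other does too.  The mirrortree method turns this into a score.  For
a protein pair (X, Y) with orthologs in the same n species, each family
is summarized by its condensed vector of pairwise evolutionary
distances, D_X and D_Y, of length n(n−1)/2, both ordered by the same
lexicographic species-pair order.  The score is Pearson's correlation

    r_XY = Σ (D_X,ij − D̄_X)(D_Y,ij − D̄_Y)
           / sqrt( Σ (D_X,ij − D̄_X)² · Σ (D_Y,ij − D̄_Y)² )

and higher r is taken as evidence for interaction.  Note that even
unrelated protein pairs score well above zero: both distance vectors
reflect the same underlying species history, so the discriminative
signal is only the correlation *excess* of interacting pairs.  All
classification here is a threshold on r; a pair is predicted
interacting when r ≥ t.

Pairs are scored only if the two families share at least `min_common`
species (default 15, the conventional dataset filter; configurable).
A family of identical orthologs has a zero-variance distance vector and
r is undefined; such pairs are flagged `degenerate-variance`, excluded
from evaluation, and counted in the run log rather than silently
dropped.  Distance entries that are individually undefined or saturated
are removed from *both* vectors symmetrically, preserving the paired
structure; if fewer than three entries survive the pair is flagged.

## Distance measures

Four pairwise measures over aligned amino-acid sequences, all using
pairwise gap deletion (a column is skipped only for the sequence pair
that has a gap or ambiguity code in it; B/Z/X are treated as missing):

* **p** — observed fraction of differing residues.
* **kimura** — d = −ln(1 − D − 0.2 D²) with D the p-distance; a
  closed-form correction for multiple hits that diverges at
  D ≈ 0.8541, beyond which a saturation error is raised.
* **categories** — residues are lumped into six physico-chemical
  groups (sulfhydryl C; small/neutral STAPG; acidic/amide DENQ; basic
  HRK; hydrophobic VLIM; aromatic FYW); a column costs 0 within a group
  and 0.457 between groups, and the distance is the mean column cost.
  The flat between-group weight is used as published, without a further
  multiple-hit correction.
* **jtt / pam001** — pairwise maximum-likelihood distance under the
  Jones-Taylor-Thornton or Dayhoff PAM empirical replacement model:
  the t ≥ 0 maximizing Σ_columns log(π(a)·[exp(Qt)]_ab).  Q is built
  from the published exchangeabilities and stationary frequencies
  (shipped as plain-text data files), normalized to one expected
  substitution per site per unit time.  P(t) is computed from a cached
  eigendecomposition of the symmetrized rate matrix; the reversible
  spectrum is real, and symmetrizing the pair-count matrix (which
  leaves the likelihood unchanged under reversibility) makes the
  estimate exactly symmetric in its arguments.

Numerical choices for the ML distance: the likelihood is unimodal in
practice; a coarse geometric grid on [1e-9, 10] locates the peak and a
bounded scalar search (tolerance 1e-8) refines it within the bracketing
grid interval.  Identical sequences return exactly 0.  A peak at the
upper bound (10 substitutions/site, far beyond usable signal) is
reported as saturation.  Site-rate heterogeneity is deliberately *not*
modeled in scoring, matching the classical pairwise-distance tools this
mirrors; its absence compresses large distances but barely affects the
correlation structure the score uses.

Conservation of a family is its mean pairwise fraction identity
(mean over pairs of 1 − p-distance); a pair's conservation is the mean
of its two families' values, computed on the common species.

## Evaluation machinery

Negative control pairs are built by drawing protein ids (with
replacement) from the positive set and re-pairing them at random,
discarding self-pairs, pairs present in the positive set in either
orientation, and duplicates, with a retry budget of 100 draws per
requested pair before reporting a capacity error.

ROC curves sweep thresholds over the observed scores with ties grouped
into single steps; AUC is the trapezoidal area, identical to the
Mann-Whitney concordance estimate with ties counted one half.  The
Matthews correlation coefficient

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

is defined as 0 when a denominator factor vanishes; the threshold sweep
records MCC, sensitivity TP/(TP+FN) and specificity TN/(TN+FP), and the
recommended operating threshold is the MCC peak (ties broken toward the
smaller threshold, favoring sensitivity).  Score densities per class
are Gaussian KDEs with Silverman bandwidth, used for reporting only —
classification always uses raw scores.

Conservation binning uses half-open bins [k·w, (k+1)·w), default width
0.02, reporting count, mean and sd of r per bin and label (sd absent
for singleton bins).  Span stratification assigns each pair to the
innermost clade containing all of its common species, given a table of
nested clade memberships per species; the time-based summary instead
defines a pair's span as the largest divergence time (Myr) among its
common species and groups scores by that value.

## The synthetic benchmark generator

Real interaction benchmarks require database snapshots; the generator
replaces them with families whose coupling is known by construction.

* **Species tree** — a Yule (pure-birth) tree: speciations at rate 1
  per lineage until the target species count, the present set one more
  exponential waiting time later, then all branches rescaled so every
  root-to-tip path equals `depth` (substitutions/site).  The tree is
  ultrametric by construction and shared by every family in a
  benchmark, exactly as a real species history would be.
* **Rate coupling** — each branch b carries a pair of lognormal rate
  multipliers (m_A, m_B) with log-sd `rate_sd` and log-scale
  correlation `coupling` (built from shared + idiosyncratic normal
  components, so coupling 1 gives identical multipliers exactly);
  log-mean −rate_sd²/2 makes E[m] = 1, leaving expected branch lengths
  unbiased.  Protein P sees branch length l_b·m_P(b).  Interacting
  pairs get the configured coupling; non-interacting pairs coupling 0.
  This is the minimal generative model that produces correlated
  distance matrices — precisely the signal the score detects.
* **Sequences** — each protein draws its own root sequence from the
  model's stationary frequencies and evolves down the tree under JTT
  (or PAM001); alignments are gap-free, so no aligner is needed.
  Columns evolve at discrete-gamma site rates (shape `site_rate_alpha`,
  default 1.0, four mean-one categories, assigned independently per
  protein).  Without site-rate variation, deep alignments decay
  uniformly toward random (~6% identity) and distance saturation noise
  swamps the coupling signal; with it, a conserved core persists, and
  mean identity runs from ~0.77 at depth 0.2 to ~0.33 at depth 2.0 —
  the range real ortholog sets occupy.
* **Seeding** — one master seed; each pair's random stream is derived
  from (seed, class, pair index) via numpy's SeedSequence, so any pair
  is reproducible in isolation and whole benchmarks are byte-stable.

Defaults (20 species, depth 2.0, coupling 0.9, rate_sd 0.25,
seq_length 300, 30 pairs per class) describe a deep, eukaryote-wide
benchmark.  `rate_sd = 0.25` corresponds to ~25% coefficient of
variation in branch rates — moderate lineage-specific rate variation —
and places the benchmark's AUC around 0.8–0.9: clearly separable but
not trivially so, comparable to the regime reported for real
interaction data rather than a ceiling of 1.0.

### What the generator does and does not emulate

It reproduces correlated lineage-specific rates, shared species
history, controllable depth and conservation, and labeled
positive/negative classes.  It does not simulate indels or alignment
error, paralogy or incomplete ortholog sets, heterogeneous species
counts per pair, label noise in interaction databases, or
compositional drift.  Passing benchmarks therefore demonstrates that
the scoring and evaluation machinery recovers coupling under the
model's assumptions — not that comparable AUCs would be achieved on any
particular real dataset, where label noise and span heterogeneity
demonstrably reduce performance.

### Behavior across depths

AUC rises steeply from shallow trees (depth 0.2: ~0.80) and saturates
by depth ~1 (~0.88), and the sd of interacting-pair scores drops by
more than half over the same range — wider spans give better, steadier
scores, because distance-estimation noise shrinks relative to the
signal.  Between depths 1.0 and 2.0 the model is scale-free: the
multiplicative rate coupling fixes the score distribution once
estimation noise is negligible, so AUC and score spread are
statistically indistinguishable there (paired-replicate difference
−0.01 ± 0.007 in AUC).  Experiments and tests therefore contrast the
narrow-span benchmark against the wider ones rather than asserting an
ordering between the two deepest, which the model cannot resolve.

## Problem sizes

Benchmark experiments use 20 species, 300-column alignments and 30+30
pairs per replicate, with 5–6 replicate seeds per condition; the ML
consistency check uses 50,000-column pairs at branch lengths 0.1, 0.5
and 1.0.  These sizes give Monte-Carlo standard errors on mean AUC of
~0.03, small relative to the effects asserted.

## Known limitations

* The Categories measure implements the published flat between-group
  weighting only; classical implementations layer further corrections.
* ML distances assume site-homogeneous rates at scoring time even
  though the generator (and reality) are heterogeneous; distances
  deeper than ~2 substitutions/site are compressed as a result.
* The negative-pair sampler assumes the positive set is sparse in the
  space of possible pairs; dense positive sets exhaust the retry
  budget and raise a capacity error rather than looping forever.
* Clade stratification requires every species in a user-supplied clade
  table; pairs with unknown species are excluded and logged, not
  guessed.
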