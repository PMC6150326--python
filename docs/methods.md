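# Methods

This note documents the model, the defaults and the design choices behind
`glypre`, in the order the pipeline applies them.

## Windows and datasets

A candidate site is an odd-length peptide window centred on a lysine.
Windows that overhang a terminus are completed with the wildcard residue
`X`, which has a defined, neutral value in every encoder (score 0 in the
position scoring function, zeros in AAindex, its own alphabet letter in
CKSAAP, and exclusion from all frequency denominators).  Annotation
positions are 1-based at the I/O boundary (UniProt convention) and 0-based
internally.

Positives are the annotated glycation lysines.  The negative pool is every
other lysine in the input proteins — including sites explicitly annotated
as label 0 — and is subsampled without replacement to `neg_per_pos` times
the positive count (default 2, giving the 1:2 class ratio typical of this
problem's benchmarks, which counters the heavy natural imbalance).  The
positive set never depends on the subsampling seed.

Redundancy removal is expected to happen upstream with a proper clustering
tool; for users without pre-filtered input a greedy longest-first filter on
global-alignment identity (matches / alignment length) is provided.  It is
quadratic and approximate, and it is off by default.

## Feature groups

Each group extracts its own window around the same centre.  Defaults
(31, 27, 13, 25) are the per-group optima of the predictor this package
implements; the per-group window search that produced such optima is
implemented in `evaluation.optimize_window_sizes`.

**Position scoring function.**  Column conservation
`M(l) = Σ (P_il − p0)² / p0` with background `p0 = 0.05`; the PWM uses the
square-root pseudocount `P_xl = (n_xl + p0·√N) / (N + √N)`, whose columns
sum to exactly 1 because `20·p0 = 1` (the source describing this estimator
prints the formula ambiguously; this standard form is adopted and its two
defining hand values, 0.35 for n=2/N=4 and 1/60 for an absent residue, are
frozen in the tests).  `N` is counted per column over non-`X` residues so
padded columns remain proper distributions.  The per-window score is
`F(l) = ln(P_xl/p0)·[Mp(l) − MN(l)]`, natural log; `X` contributes 0.
Only positive windows shape the PWM; negatives enter through `MN`.

**Secondary structure.**  `.ss2` triples in file column order (C, H, E),
renormalized to sum 1 (the reader accepts row sums in [0.95, 1.05]).
Positions beyond the chain encode (0,0,0) rather than uniform (⅓,⅓,⅓), to
mark absent structure rather than maximal uncertainty.

**AAindex.**  Twenty scales, z-scored per index over the 20 residues so
that the groups are commensurate and `X → 0` equals the post-normalization
mean.  The vector is index-major (all positions of scale 1, then scale 2,
…), with labels naming accession and offset.

**CKSAAP.**  Ordered pairs over the 21-letter alphabet at gaps k = 0..4;
each k-block is divided by its W−k−1 slots so it forms a composition.
The 2205-dimensional vector is reduced to the top 30 pairs by information
gain with zero/nonzero discretization, fitted on training data only.

## Feature selection

Mutual information is estimated in bits on discretized features:
zero/nonzero for the sparse CKSAAP compositions, and the mean ± σ
three-bin scheme for dense features in mRMR (both choices follow common
practice; the source is silent).  mRMR uses the MID criterion — relevance
`I(x;y)` minus mean redundancy with the chosen set — with deterministic
ascending-index tie-breaking (ties compared at 1e-12 to be robust to
float round-off).

Greedy forward selection walks the ranked list.  The first feature always
starts the subset; each later candidate is kept iff mean k-fold CV AUC
exceeds the best so far by more than `eps = 1e-4`.  One fixed stratified
partition is reused for all candidates within a run, so comparisons are
paired and acceptance noise does not accumulate.  The recorded best AUC is
non-decreasing by construction.

Honest vs. global scope: the literature around this predictor family often
selects features once on the full dataset and then cross-validates only the
classifier, which leaks selection information.  The default here refits the
PWM, the CKSAAP top-30 and any wrapper selection inside every training
fold (`selection_scope="fold"`); the global protocol is available and
labelled (`"global"`).  The zero-effect synthetic corpus is the control:
honest evaluation stays at AUC ≈ 0.5 there.

## Classifier

RBF-SVM on per-feature z-scored inputs; standardization parameters are
estimated from training rows only and frozen inside the model.  Posterior
probabilities come from sigmoid (Platt) calibration fitted on internal
cross-validated decision values; class calls threshold the posterior at
0.5.  Grid search over C = 2⁻⁵..2¹⁵ and γ = 2⁻¹⁵..2³ (log2 step 2, the
libsvm practical-guide ranges) by mean 10-fold CV AUC is implemented, with
ties resolved toward smaller C then smaller γ.  AUC (rather than accuracy)
is the grid criterion to match the GFS criterion.  The cross-validation
pipeline defaults to fixed hyperparameters (C = 1, γ = 'scale'), which are
ample for the synthetic corpora; grid search can be switched on per run
where data warrant it.

## Evaluation

Sen, Spe, Acc, MCC from the confusion counts with the conventions: a ratio
with an empty denominator is 0, and MCC is 0 when any factor under the
root vanishes.  AUC is the rank (Mann–Whitney) estimator with midranks for
ties.  Repeated stratified k-fold pools counts and scores over the folds
of each repeat and reports mean and sd (population sd, so a single repeat
reports 0) across repeats; stratification prevents single-class folds at
the 1:2 ratio.  Degenerate partitions are redrawn with a shifted seed and
logged.  Leave-one-out pools all n single-sample predictions and reports
no sd.

## Synthetic data

The generator emulates the two signals this predictor family exploits:
positional residue enrichment (A, E, L boosted at offsets −6 and +4 of
positive sites; `effect_size` is the total probability mass moved onto the
enriched residues, default 0.35, putting each near 17% against a uniform
5% background) and a helix-biased structure context (mean coil→helix shift
of 0.20 within ±6 residues of a positive site, Dirichlet concentration 8).
Defaults produce 70 proteins × 3 positive sites = 210 positives — the
scale of the benchmark this emulates — with a 7-per-protein planted
negative pool supporting the 1:2 split.

Every lysine is planted at a controlled location and the inter-site
background is lysine-free.  This is deliberate: with lysines arising
freely from the background, negatives adjacent to positive sites inherit
boosted flanks, terminal negatives are the only padded windows, and
positives' windows are the only ones without incidental lysine pairs —
three artifacts that let a classifier separate the classes for reasons
unrelated to the planted signal (or, for the null corpus, at all).
Controlled placement with a minimum spacing of 22 residues and a 16-residue
terminal margin guarantees that no window of one site reaches another
site's enriched positions or helix zone, so the classes differ only in the
planted signal and `effect_size = helix_bias = 0` is an exact null.

What the generator does **not** emulate: natural amino-acid composition
(uniform background by default, matching the scoring function's p0; a
Swiss-Prot-like composition is available behind a flag), homologous
proteins, position-dependent residue correlations, PSIPRED's error
structure, or negatives overlapping positive motifs as they do in real
proteomes.  Passing tests on this corpus therefore demonstrate the
machinery — encoders, selection, honest evaluation — not real-data
performance; the headline numbers reported for real glycation benchmarks
require the original external datasets and PSIPRED runs and are out of
scope here.

## Problem sizes

The test suite and the acceptance script run the protocols at the sizes
the synthetic study conditions define: n = 630 (210/420) for the
planted-recovery and no-leakage checks (10 repeats of honest 10-fold for
the null), 20 generator seeds for the stability of the information-gain
top ranks, and smaller corpora (n ≈ 72–210) for protocol unit tests,
leave-one-out, and the effect-size monotonicity check.

## Known limitations

* The greedy identity filter is a stand-in for proper redundancy
  clustering and scales quadratically.
* mRMR computes O(p²) pairwise MI terms; for the 2205-dimensional full
  CKSAAP space use the IG ranking (as the pipeline does) and reserve mRMR
  for the assembled 402-dimensional vector.
* Model files are joblib-serialized Python objects with a schema tag;
  they are versioned but not portable across major library versions.
* Probability calibration needs at least two samples per class in
  training; leave-one-out on very small corpora is the practical floor.
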