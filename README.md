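# glypre

Prediction of lysine glycation sites from protein sequence and predicted
secondary structure.

Glycation is the non-enzymatic attachment of a reducing sugar to a protein
amino group — at lysines, a post-translational modification implicated in
diabetic complications and neurodegeneration.  Experimentally mapping
glycated lysines is slow, so sequence-based classifiers are used to
prioritise candidate sites.  `glypre` is a complete, tested implementation
of such a predictor for computational biologists: four feature encoders, a
two-step feature selection, an RBF-SVM classifier with probability
calibration, the repeated cross-validation protocols used to evaluate this
family of tools, and a synthetic-corpus generator so the entire pipeline
runs and is testable without any external downloads.

## The model

A candidate site is a lysine-centred peptide window (terminal overhangs
padded with `X`).  Four feature groups, each with its own window size, are
concatenated into the default 402-dimensional vector
31 + 27·3 + 13·20 + 30:

**Position scoring function (31 dims).**  Per-column residue conservation
is measured against a uniform background p₀ = 0.05:

    M(l) = Σᵢ (P_il − p₀)² / p₀

(0 for random residue usage, 19 for a perfectly conserved column).  A
position weight matrix with a √N pseudocount is fit on positive windows,

    P_xl = (n_xl + p₀√N) / (N + √N),

and the window is scored per position as

    F(l) = ln(P_x(l),l / p₀) · [M_p(l) − M_N(l)],

the log-likelihood ratio weighted by the positive/negative conservation
difference.

**Secondary structure (81 dims).**  Per-residue coil/helix/strand
probabilities in PSIPRED `.ss2` vertical format, renormalized to sum to 1;
out-of-chain positions encode (0, 0, 0).

**AAindex (260 dims).**  Twenty physicochemical scales (AAindex1 flat-file
accessions, z-scored over the 20 residues) looked up per window position.

**CKSAAP (30 dims).**  Compositions of k-spaced amino-acid pairs over the
21-letter alphabet: 441 ordered pair types per gap k = 0..4 (2205 total),
each k-block normalized by its W−k−1 slots, reduced to the top 30 pairs by
information gain on training data.

Feature selection is mRMR (mutual-information difference scheme, bits, on
discretized features) followed by greedy forward selection: walking the
ranked list, a feature is kept only when 10-fold cross-validated SVM AUC
improves.  The classifier is an RBF-SVM on per-feature z-scored inputs with
sigmoid (Platt) probability calibration; a lysine is called glycated when
its posterior reaches 0.5.  Evaluation reports sensitivity, specificity,
accuracy, MCC and AUC over repeated stratified k-fold CV (counts pooled
over folds per repeat, mean ± sd across repeats) or leave-one-out.

By default every fitted quantity — the PWM, the CKSAAP top-30, any wrapper
selection — is refit inside each training fold ("honest" evaluation); the
leakier select-once-globally protocol common in this literature is
available behind `selection_scope="global"` for comparison.

## Worked example

`examples/04_train_evaluate_predict.py` generates a 630-sample synthetic
corpus (210 planted glycation lysines with A/E/L enrichment at offsets
−6/+4 and a helix-biased structure context, 420 background lysines), runs
honest repeated 10-fold CV, then trains a final model and scores every
lysine of two proteins:

```
honest 10-fold CV over 3 repeats (n = 630, 1:2 class ratio):
  sen  0.9746  (sd 0.0022)
  spe  0.9952  (sd 0.0039)
  acc  0.9884  (sd 0.0033)
  mcc  0.9738  (sd 0.0074)
  auc  0.9996  (sd 0.0002)

per-lysine predictions for 2 proteins (20 lysines, call = score >= 0.5):
protein_id  position  score  call
  SYNP0001        17 1.0000     1
  SYNP0001        42 0.0000     0
  ...
planted sites among these proteins recovered: 6 of 6
```

The synthetic signal is deliberately clean, so near-perfect recovery is the
expected behaviour — the interesting outputs are the per-position
conservation profiles (`examples/01_simulate_and_profile.py`), the feature
layout (`examples/02_encode_features.py`) and the selection behaviour
(`examples/03_feature_selection.py`).  On a zero-effect corpus the same
honest pipeline stays at AUC ≈ 0.5, which is the test that catches
selection leakage.

## Command line

The same workflow is exposed as a thin CLI; every command writes its
resolved configuration next to its outputs for reproducibility:

```bash
glypre simulate --out corpus/ --seed 1
glypre train    --fasta corpus/proteins.fasta --annotations corpus/annotations.tsv \
                --aaindex corpus/aaindex.txt --ss2-dir corpus/ss2 --out run/
glypre predict  --model run/model.joblib --fasta corpus/proteins.fasta \
                --ss2-dir corpus/ss2 --out preds/
glypre evaluate --fasta corpus/proteins.fasta --annotations corpus/annotations.tsv \
                --aaindex corpus/aaindex.txt --ss2-dir corpus/ss2 \
                --k 10 --repeats 50 --out eval/
```

`glypre encode` and `glypre select` expose the feature matrix and the
mRMR/IG + GFS rankings as TSV for inspection.

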