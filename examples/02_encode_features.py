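"""Encode one candidate lysine into the 402-dimensional feature vector.

Fits the position weight matrix and the information-gain CKSAAP selection
on a small corpus, then assembles position-score | secondary-structure |
AAindex | CKSAAP blocks for a single site and prints the layout.
"""

import tempfile
from pathlib import Path

import numpy as np

import glypre as g
from glypre.pipeline import fit_fold
from glypre.synthetic_data import (
    SyntheticConfig,
    generate_corpus,
    write_aaindex_fixture,
)

corpus = generate_corpus(SyntheticConfig(n_proteins=20, seed=2))
dataset = g.build_dataset(corpus.proteins, corpus.annotations, 31, 2.0, seed=2)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "aaindex.txt"
    accessions = write_aaindex_fixture(path, n_indices=20, seed=2)
    table = g.read_aaindex1(path, accessions, zscore=True)

encoded = g.prepare_corpus(corpus.proteins, dataset, corpus.profiles, table,
                           g.EncoderConfig())
fold = fit_fold(encoded, np.arange(len(encoded)), g.PipelineConfig(), seed=2)

print(f"feature matrix: {fold.X.shape[0]} windows x {fold.X.shape[1]} features")
print("blocks (name, start, length):")
for block in fold.layout.blocks:
    print(f"  {block.name:8s} start {block.start:3d} length {block.length:3d}  "
          f"e.g. {block.labels[0]}")

window = dataset.windows[0]
print(f"\nfirst positive window {window.source}: {window.residues}")
vec = fold.X[0]
pssf = fold.layout.slice('pssf')
print(f"position-score block, centre +/-3: "
      f"{np.array2string(vec[pssf][12:19], precision=2)}")
print("Positive values mean the residue at that offset looks more like the "
      "positive-class\nprofile (log-ratio weighted by the class conservation "
      "difference).")
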