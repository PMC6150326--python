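"""Generate a synthetic glycation corpus and inspect positional conservation.

Builds a corpus of proteins with planted glycation lysines (A/E/L enriched
at offsets -6 and +4), assembles the 1:2 labelled window dataset, and prints
the per-position conservation statistic M(l) for both classes.  Positions
-6 and +4 should stand out in the positive class only.
"""

import glypre as g
from glypre.synthetic_data import SyntheticConfig, generate_corpus

corpus = generate_corpus(SyntheticConfig(n_proteins=70, seed=1))
dataset = g.build_dataset(corpus.proteins, corpus.annotations,
                          window_size=31, neg_per_pos=2.0, seed=1)
print(f"{len(corpus.proteins)} proteins, {int(dataset.labels.sum())} positive "
      f"and {int((dataset.labels == 0).sum())} negative lysine windows")

profile = g.positional_profiles(corpus.proteins, dataset,
                                property="conservation_M", window=31)
wide = profile.pivot(index="position", columns="class", values="value")
print("\nconservation M(l) around the lysine (0 = random residue usage):")
for pos in (-8, -6, -4, -2, 2, 4, 6, 8):
    row = wide.loc[pos]
    marker = "  <-- enriched offset" if pos in (-6, 4) else ""
    print(f"  {pos:+3d}  positive {row.positive:6.3f}   "
          f"negative {row.negative:6.3f}{marker}")
print("\nA high positive-class M(l) at -6/+4 reflects the planted A/E/L "
      "enrichment; the\nnegative class stays near the random-usage baseline.")
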