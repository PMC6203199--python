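# pines

Phenotype-informed prioritization of noncoding variants from binary
epigenetic annotations.

Most disease-associated variants from GWAS and family studies fall
outside protein-coding exons, where their functional impact is hard to
read off the sequence.  What *is* informative is the epigenetic context:
whether a position sits in histone-mark peaks (H3K4me1, H3K4me3,
H3K27ac, H3K9ac), DNase hypersensitive sites across cell types,
conserved elements, permissive chromatin states, or chromatin-
interaction anchors.  `pines` scores noncoding SNVs and indels from
such annotations, for users who want to prioritize candidate regulatory
variants at GWAS loci, in fine-mapping output, or in rare-variant
studies — optionally steering the score towards the cell types relevant
to their phenotype.

## The score

Each variant is a binary annotation vector **x** (one entry per
mark × cell type, plus global conservation/chromatin-state/interaction
columns; the canonical layout has 639 entries).  Annotations are
heavily correlated, so raw counting double-counts evidence.  Let μ and
Σ be the mean and covariance of **x** over a large background of common
variants, Σ̂ = Σᵢ₌₁ᵏ λᵢ**u**ᵢ**u**ᵢᵀ the rank-k (default k = 30)
approximation from the spectral decomposition of Σ, and **W** a
diagonal matrix of annotation weights (identity when unweighted).
Variants are projected into the decorrelated space

  zᵢ = λᵢ^(−1/2) **u**ᵢᵀ **W** (**x** − μ),  i = 1…k,

where ‖**z**‖ = √((**x**−μ)ᵀ**W**Σ̂⁺**W**(**x**−μ)) is the reweighted
Mahalanobis distance.  The score is the angle to the whitened image of
the all-1 vector 𝟙 — the direction of maximal annotation load — scaled
by the two projected lengths:

  score(**x**) = acos( cos∠(**z**, **z**_𝟙) ) / ( ‖**z**‖ · ‖**z**_𝟙‖ ).

Smaller scores mean more evidence of regulatory function; 𝟙 attains the
minimum 0.  Significance is an empirical one-sided p-value of the score
against background variants of the same genomic class (intronic and
intergenic variants are modelled separately), re-scored under the same
weights.  Weights come from three sources: identity (unweighted), a
manual constant (default 4) on user-selected annotations, or
−log10(enrichment p) learned from GWAS lead SNPs by 1000
allele-frequency-matched resampling draws.  Comparing weighted and
unweighted significance per variant — the angle each (u, w) =
(−log10 p_unweighted, −log10 p_weighted) pair forms to the main
diagonal — flags variants with cell-type-specific annotation profiles.

## Worked example

Score the cell-type-specificity simulation: 5000 background variants
with 100 independent Bernoulli(0.3) annotations, plus 100 specific
variants whose 10 characteristic annotations fire at rate 0.9 and the
remaining 90 at rate 0.1, with the characteristic annotations
up-weighted by the default constant 4.

```python
import numpy as np
from pines.simulate import SimulationConfig, simulate_celltype_specific
from pines.background import score_with_background
from pines.specificity import diagonal_angle, detect_specific_variants
from pines.weighting import manual_weights

config = SimulationConfig(seed=11)
matrix, labels = simulate_celltype_specific(config)
background = matrix.values[~labels]

W = manual_weights(matrix.schema, config.hot_ids, constant=4.0)
_, p_unweighted, model = score_with_background(matrix.values, background, None)
_, p_weighted, _ = score_with_background(matrix.values, background, W)

angles = diagonal_angle(-np.log10(p_unweighted), -np.log10(p_weighted))
hits = detect_specific_variants(angles[labels], angles[~labels])

print(f"variance explained by 30 eigenvectors: {model.variance_explained:.3f}")
print(f"mean angle, cell-type-specific variants: {angles[labels].mean():+.3f} rad")
print(f"mean angle, background variants:         {angles[~labels].mean():+.3f} rad")
print(f"specific variants flagged at p <= 0.05:  {hits['flagged'].sum()} / {labels.sum()}")
```

Output:

```
variance explained by 30 eigenvectors: 0.353
mean angle, cell-type-specific variants: +0.770 rad
mean angle, background variants:         -0.003 rad
specific variants flagged at p <= 0.05:  99 / 100
```

The specific variants overlap *fewer* annotations on average than the
background (18 vs 30), so unweighted significance alone ranks them
*below* background; up-weighting their characteristic annotations moves
them far above the diagonal (mean angle +0.77 rad vs ≈0), and 99 of 100
are flagged at the 5% angle threshold.

A command-line interface covers the file-based workflow —
`pines build-background`, `pines score`, `pines weights`,
`pines simulate`, `pines specificity`; see `pines --help`.

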