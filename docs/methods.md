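# Methods

## Model

A noncoding variant is represented by a binary vector **x** of
annotation overlaps.  The canonical layout pairs five marks (H3K4me1,
H3K4me3, H3K27ac, H3K9ac, DNase) with 127 reference epigenomes (635
cell-type-specific columns) and appends four global columns: GERP and
SiPhy conserved elements, an aggregated ChromHMM DHS state, and pooled
chromatin-interaction anchors — 639 columns.  Any layout can be
declared through an `AnnotationSchema`; the scoring model is agnostic
to it.

The background distribution of **x** is summarized by its mean μ and
covariance Σ, estimated from a large set of filtered common variants.
Because Σ is a noisy estimate of a heavily correlated structure, only
the top k eigenpairs are retained: Σ̂ = Σᵢ≤k λᵢ**u**ᵢ**u**ᵢᵀ, with
Moore–Penrose pseudo-inverse Σ̂⁺ = Σᵢ≤k λᵢ⁻¹**u**ᵢ**u**ᵢᵀ.  Whitening
is performed directly in the eigenbasis,

  zᵢ = λᵢ^(−1/2) **u**ᵢᵀ **W** (**x** − μ),

which reproduces every quadratic form (**a**−μ)ᵀ**W**Σ̂⁺**W**(**b**−μ)
exactly; a Cholesky factorization of the rank-deficient Σ̂⁺ would not
exist, so the eigen-route is the defined transform.  ‖**z**‖ is the
reweighted Mahalanobis distance of **x** to μ.

The Mahalanobis length alone penalizes variants that merely *deviate*
from correlation patterns, and under strongly positively correlated
annotations it loses significance precisely at near-total annotation
load (an all-or-nothing load is *expected* there) — the saturation
study in `experiments.saturation_study` demonstrates this.  Scoring
therefore uses the angle to the whitened image of the all-1 vector 𝟙,
the maximal-annotation-load direction, scaled by both projected
lengths:

  score(**x**) = acos(cos∠(**z**, **z**₁)) / (‖**z**‖·‖**z**₁‖).

The score is non-negative, equals 0 iff **z** is a positive multiple of
**z**₁ (in particular at **x** = 𝟙), shrinks with annotation load at a
fixed angle, and is exactly invariant to relabeling of annotation
columns.  Rescaling **W** → c**W** multiplies every score by 1/c², so
rankings and empirical p-values are invariant to the overall weight
scale.  acos is taken in radians; any fixed unit would rescale all
scores equally.

## Significance

Raw scores have no absolute unit.  Each variant receives an add-one,
one-sided empirical p-value against background variants of its own
genomic class scored under the same weights:

  p = (1 + #{b ∈ background : b ≤ score}) / (N + 1).

Ties count as ≤ (conservative); p never reaches 0, and the most extreme
attainable value is 1/(N+1).  The background is re-scored whenever the
weights change, so weighted p-values always use a weighted null — this
is what makes the weight-scale invariance exact and the weighted/
unweighted comparison meaningful.  Calibration is verified by
leave-one-out p-values of background draws, which form a uniform grid
and pass a Kolmogorov–Smirnov uniformity test.

Background variants are built by a fixed filter cascade over a
candidate list: drop ClinVar "Pathogenic", "Likely pathogenic" and
"Uncertain significance" entries; drop GWAS-catalog variants; drop
variants overlapping enhancer intervals; drop variants with allele
frequency ≤ 5% in *any* provided continental ancestry column
(candidates with no frequency record are dropped and logged).  Counts
after every step are logged.  The background size is whatever survives
the cascade — it is data, not a constant.

Intronic and intergenic variants have different annotation
architectures, so μ, Σ̂ and the score null are computed per class; both
μ and Σ̂ are class-specific for consistency.  Variants inside exons or
UTRs are excluded rather than scored — the score is defined for
noncoding variants only.

## Annotation and classification conventions

BED inputs are 0-based half-open; variant positions are 1-based (VCF
convention); the conversion (pos − 1) happens exactly once, at the
membership test, so an interval [100, 200) covers 1-based bases
101–200 and a 0-based position equal to an interval's end never
overlaps it.  Chromosome names are normalized to one dialect (default:
strip a leading "chr").  Indels and multi-nucleotide variants are
annotated at their leftmost position; no span rule is applied.
Missing tracks yield *missing* entries (NaN), never zeros; at scoring
time missing entries are imputed to the background column mean, so
they contribute zero deviation — a neutral treatment that is distinct
from "annotation absent".  Conservation columns consume pre-thresholded
element calls (BED), and per-cell-type chromatin-interaction tracks are
pooled into one global column.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 30 | rank of the covariance approximation; override per run, or choose by a variance-explained target |
| weight constant | 4 | manual up-weighting of selected annotations; 1 = unweighted; balances power on selected vs other annotations |
| weight floor | 0.1 | lower bound on every weight, so no annotation is ever excluded from the model |
| n_draws | 1000 | allele-frequency-matched resampling draws for enrichment weights |
| AF bin width | 0.05 | matching granularity on the reference allele-frequency column |
| AF threshold | 0.05 | background cascade: minimum frequency in every continental ancestry |
| angle threshold | 0.05 | empirical angle p-value below which a variant is flagged cell-type-specific |

Eigenvalues below 10⁻¹⁰·λ₁ are dropped (k is reduced) for stability of
λ⁻¹; cosines are clipped to [−1, 1] and values within 10⁻¹² of ±1 are
snapped exactly, since acos otherwise turns O(ε) parallelism error into
O(√ε) angles.  A variant whose whitened projection has zero length (for
example **x** = μ after imputation) has no defined angle; it is
reported with p = 1 and a flag rather than a score.

Enrichment weights use the add-one upper-tail convention over the
matched draws, so the strongest attainable weight at 1000 draws is
−log10(1/1001) ≈ 3.0004; the floor keeps unenriched annotations at a
small positive weight.  Within an allele-frequency bin, matched sets
are drawn without replacement when the universe allows, with
replacement (logged) otherwise; universe rows are ordered by content
before sampling so results are invariant to row order.  The manual
constant is floored at the weight floor, which lets weight sweeps start
at 0 without violating the strictly-positive-weights rule.

## Simulated data

The generators are first-class, tested code and define the study
conditions:

* **Cell-type-specific design** — 5000 background variants, 100
  annotations, independent Bernoulli(0.3); 100 specific variants with
  10 characteristic annotations at Bernoulli(0.9) and 90 at
  Bernoulli(0.1).  Expected loads: 30 (background) vs 18 (specific) —
  the specific variants are *not* high-load outliers, which is exactly
  why phenotype weighting is needed to surface them.
* **Block design** — 10 blocks × 10 binary annotations, exchangeable
  within-block latent correlation 0.7, independent across blocks,
  marginal rate 0.3 (matching the background rate above; the block
  designs state no marginal of their own).  Correlated Bernoulli
  columns are produced by a latent Gaussian copula: one shared factor
  per block, thresholded at the upper-p normal quantile.  The binary
  correlation is attenuated relative to the latent 0.7, as expected
  for dichotomized Gaussians.
* **Saturation design** — 20,000 binary vectors over 100 annotations
  with a random dense positive correlation matrix (single dominant
  positive factor, unit-diagonal noise, normalized to unit diagonal),
  marginal rate 0.5.  The positive-factor choice creates the regime
  where intermediate loads are the surprising ones.
* **Fixture bundle** — deterministic toy BED/VCF/GFF3/BED12/TSV files
  with a brute-force-computed ground-truth overlap matrix and
  hand-countable filter-cascade outcomes, for exercising the I/O and
  CLI paths.

What the simulations do *not* emulate: realistic marginal frequencies
per mark and cell type, linkage disequilibrium between variants,
distance-to-TSS structure, and the empirical correlation structure of
real epigenome compendia.  Passing tests on these designs show the
estimator and its geometry behave as designed, not that any particular
biological prioritization is correct.

## Design notes

* Axes of the specificity comparison are significances
  (−log10 empirical p), not raw scores; the diagonal angle is
  atan2(w, u) − π/4, signed, in [−π/4, +π/4], positive when weighting
  adds significance.  The (0, 0) pair has no defined angle and is
  reported as 0 with a flag.
* Calibration of the angle flag rate requires the background angle
  reference to be treated like the query (out-of-sample with respect to
  the fitted model and null).  With small backgrounds, in-sample
  background angles are biased relative to query angles because the
  rank-k covariance overfits; the test suite holds out background rows
  for this comparison.  At realistic background sizes (10⁵ variants)
  the effect is negligible.
* μ and Σ are estimated from the unweighted background matrix; **W**
  enters only inside the quadratic forms at scoring time, exactly where
  the formulas place it.
* The study-scale runs used throughout (5000 + 100 variants, 10⁴-row
  block designs, 2 × 10⁴-row saturation design, 2000-draw calibration,
  1000 enrichment draws) complete in seconds on one CPU.

## Known limitations

* Binary annotations only; signal-valued tracks are out of scope.
* Indel spans are collapsed to the leftmost base.
* The enrichment matching covariate is allele frequency alone; other
  covariates (e.g. TSS distance) are not matched.
* Per-class backgrounds require enough rows per class (> k); tiny
  backgrounds reduce the usable rank.
* The empirical p-value floor is 1/(N+1): resolution is limited by the
  background size.
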