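# Methods

This note documents the models behind `brainaging`, the synthetic-data
generator that stands in for the study corpus, the numerical choices, and the
limits of what the tests demonstrate.

## 1. The synthetic corpus

The generator (`brainaging.synthetic_data`) emulates a combined
single-cell-WGS / single-nucleus-RNA-seq study of the aging prefrontal cortex
at desk scale. Its defaults *are* the study conditions; everything flows from
one seed through three independent child streams (genome, catalog,
expression), so a seed fully determines the corpus.

### 1.1 Toy genome and annotation

A single 2 Mb chromosome of i.i.d. uniform bases carries 1,000 non-overlapping
genes with log-normal lengths. Gene classes: 30 % housekeeping (median length
~600 bp), 20 % neuron-specific (~1,600 bp — deliberately longer, as
neuron-identity genes are in cortex), 50 % other. Each gene carries per-type
mean expression in "logged CPM" units constructed to satisfy the program
definitions of §4.3 by class (housekeeping: common base 0.25–1.4 with ±0.045
jitter, so spread < 0.1 and every mean > 0.1; neuron-specific: neuron means
0.25–1.2, microglia/endothelial < 0.08). The excitatory-neuron mean is the
gene's expression score for quintile placement. The callable mask defaults to
the whole chromosome.

A real genome differs in ways that matter for absolute numbers but not for the
pipeline's logic: non-uniform trinucleotide composition, overlapping genes,
introns vs exons, and mappability holes are all absent.

### 1.2 Somatic SNV catalogs

Per cell of a donor aged *a*, the two signature components contribute
independent burdens

    N_g ~ Poisson(a · r_g · G_g),  G_g ~ Gamma(α_g, 1/α_g),

with clock rates r_A1 = 13.8 and r_A2 = 1.8 sSNVs/year (the study's fitted
per-signature rates; they sum to 15.6, the printed total clock being 15.5).
The Gamma multipliers (mean 1) model per-cell biological dispersion. Their
shapes α_A1 = 50, α_A2 = 1.4 are back-calculated from the study's fit quality:
with the 13 donor ages (SD 33.4 years) and these rates, pure Poisson noise
would give burden-age R² ≈ 0.99 for every component, while the reported fits
are 0.94 (A1), 0.31 (A2) and 0.92 (total); inverting R² = trend-var /
(trend-var + residual-var) for the residual CV yields those shapes. The
synthetic corpus then lands at R² ≈ 0.94–0.95 (A1) and 0.25–0.40 (A2) across
seeds without further adjustment. `dispersion_*=None` restores pure Poisson.
The dispersion also serves an identifiability role discussed in §2.2.

Each mutation's 96-context channel is drawn from the component's packaged
96-vector; its position is drawn among callable sites carrying that exact
trinucleotide (either strand), re-weighted within the stratum — A1 by
expression-quintile weights (1.0, 1.3, 1.6, 2.0, 2.5), A2 by an intergenic
weight of 2 — so placement preferences never distort the context mixture.
Genic T>C placements put the pyrimidine on the template strand with
probability 0.65 (`strand_asymmetry`), the transcription-coupled-repair
asymmetry the analyses recover. The truth record stores per-cell component
counts and every mutation's component label.

The signature fixtures are synthetic 96-vectors shipped with the package
(`data/signature_*_synthetic.tsv`): an SBS5-like shape (flat-ish, 47 % T>C /
24 % C>T mass) and an SBS30-like shape (87 % C>T), cosine 0.49 apart. They are
constructed, not downloaded; they carry only the qualitative features the
analyses exploit, and users can substitute real COSMIC v3 vectors in the same
TSV layout.

### 1.3 Expression matrices

Counts are negative binomial (size θ = 10) with per-gene rates
λ = expm1(mean logged CPM) scaled to an expected adult library of 5,000
counts per nucleus, for 6 cell types (ExN, InN, Micro, Endo, Oligo, Astro) ×
13 donors × 40 nuclei. In elderly cells, rates are multiplied by 2^lfc with
planted log2 fold changes: housekeeping genes decline on a length gradient
interpolated from −1 (shortest decile) to 0 (longest); neuron-specific genes
are untouched; 30 well-expressed "other" genes are planted down (−1) in ExN,
InN, Oligo and Astro — one excitatory, one inhibitory and two glial types, the
shared-downregulation criterion. The truth record stores the full planted
log2FC table.

Two consequences worth knowing. First, planted values are absolute-rate fold
changes; because ~30 % of genes are planted down, per-cell normalization
necessarily inflates every other gene by ≈ +0.2 log2 (a compositional effect
real aging data share). Second, the Seurat-style estimator
log2((mean expm1 + 1)/(mean expm1 + 1)) compresses fold changes at low
expression; a planted 2-fold change at baseline λ < 0.3 reads as −0.3 to −0.5
and is not callable at the 0.5 threshold at any sample size. Recovery tests
therefore condition on adequately expressed planted genes (λ ≥ 0.5), where
measured sensitivity is 1.0. Doublets, ambient RNA, batch effects and
dropout beyond the NB sampling are not modeled, so passing tests say nothing
about robustness to those artifacts.

## 2. Signature inference

### 2.1 NMF

`nmf_decompose` implements multiplicative-update NMF for the generalized KL
divergence (ε = 1e−10 guards; objective tracked every 10 iterations and
non-increasing up to the 1e−7 relative tolerance; 500 iterations default).
Restarts are seeded via `SeedSequence((seed, k))`; the best objective wins;
signatures are column-normalized with the scale folded into exposures. The
component with the larger T>C mass is labeled A1, the other A2; ties break by
column index.

Rank selection runs the restart ensemble for each k, warm-starting one
restart from the previous rank's solution so the error curve is non-increasing
in k. Stability is the **minimum** cosine of Hungarian-matched signatures
between each random restart and the best one — the worst-reproduced component.
The mean cosine is not discriminating here: two arbitrary flat-ish 96-vectors
already have cosine ≈ 0.9, so the mean stays above 0.93 out to k = 8, while
the minimum drops from ≈ 0.99 (k = 2) to 0.79–0.88 (k ≥ 3). The chosen k is
the largest whose stability exceeds 0.9 *and* whose error improves on k−1 by
more than 5 %; k = 1 is the baseline. The warm-started restart is excluded
from the stability statistic (it can sit in its own basin with a degenerate
padded component).

### 2.2 Exposure attribution

Both components' burdens grow linearly with age, so every cell's *expected*
signature proportion is the same (≈ 88.5 % / 11.5 %); only the per-cell
dispersion makes proportions vary, and with α_A2 = 1.4 they span roughly
0.02–0.4. A factorization of such data identifies each component only up to
the hull of the observed mixtures: the recovered minor component is the most
A2-heavy mixture in the data (cosine ≈ 0.85–0.9 to the true vector), not the
vertex, and refitting exposures against it misattributes mass (the dominant
slope comes out ≈ 8.4/year instead of 13.8). No algorithm can do better from
the spectra alone; the vertex is simply not in the data.

The pipeline therefore follows field practice: the de novo factorization
fixes the *number* and *identity* of the components (rank selection, T>C/C>T
labeling, cosine match), and per-cell exposures are then quantified by NNLS
against the **matched reference vectors** — the role COSMIC signatures play
in real signature analyses. With that route the recovered slopes are
13.15–14.14 (A1) and ~1.3–2.3 (A2) across seeds; the A2 slope's sampling SE
is ≈ 18 % of its value at the study's dispersion, so its 10 % recovery is a
property of the replicate mean, not of single corpora. `attribution:
"de_novo"` switches back to refitting against the de novo signatures, and the
report records which path produced each output.

## 3. Genomic enrichment

Matched controls copy each observed mutation's canonical substitution onto
`multiplier` (default 10) uniform random callable sites sharing its
trinucleotide, making the control spectrum an exact scalar multiple of the
observed one. Enrichment ratios are observed/control class shares with
percentile bootstrap CIs (default 1,000 draws) over resampled observed
mutations.

Per-signature ratios decompose each partition class's aggregate observed and
control spectra by NNLS against the attribution basis and compare each
signature's share of its own exposure between observed and controls. The
per-mutation-responsibility alternative (soft or argmax) is implemented but
not the default: a component with ~12 % mixture weight never exceeds ~1/3
responsibility even in its most characteristic contexts, so
"minor-component-attributed" mass is dominated by the major component and its
placement signal washes out. Region-level decomposition recovers it.

Strand convention: a mutation is on the transcribed strand when the
pyrimidine of its canonical context lies on the gene's template strand. A
mutation overlapping several genes (possible with external annotations; the
toy genome has none) goes to the unique gene for which it is
transcribed-strand, else to the longest, and the count of such resolutions is
logged.

Gene-length deciles and expression quintiles are rank-based with ties broken
by gene identifier, so assignments are total and deterministic. The
stop-codon census enumerates all 64 codons × 9 substitutions, counts events
creating (but not starting from) a stop, and reports the 7/9 A-or-U content
of the three stop codons. Of note, the enumeration puts T>A alongside C>A at
the top (7 events each, C>T at 5): transversions to A create stops as readily
as the cytosine substitutions usually singled out.

## 4. Transcriptome analyses

### 4.1 Differential expression

Log-normalization is ln(1 + count·10⁴/cell-total). DE tests genes detected in
≥ 25 % of elderly *or* adult cells (the alternative preset — ≥ 25 % adult and
≥ 20 % elderly — defines the expressed background for the permutation test,
following the two filters' different roles); the test is a two-sided Wilcoxon
rank-sum (normal approximation with tie correction); log2FC uses the
expm1-mean convention with pseudocount 1 (configurable). Raw p-values mirror
the |log2FC| > 0.5, p < 0.05 calling convention; a BH-FDR column is emitted
for users but never used for calls. Type-I error on null synthetic data
measures 5.1 %.

### 4.2 Shared downregulation

A gene is "shared" when down-called in ≥ 1 excitatory, ≥ 1 inhibitory and
≥ 2 glial cell types. Each of the 1,000 permutations redraws, per cell type,
a uniform subset of that type's expressed genes of the observed down-set
size. The empirical p is (1 + #{perm ≥ obs})/(n_perm + 1), so its floor is
1/1001. On the default corpus the observed count (~69) includes both the 30
planted shared genes and housekeeping genes whose planted decline crosses the
calling threshold in enough cell types — itself a cross-cell-type shared
decline, as in the real tissue.

### 4.3 Gene programs and length gradients

Housekeeping: spread of the four cell-type mean logged CPMs < 0.1 (strict,
with a 1e−9 guard so a spread of exactly 0.1 fails despite floating-point
subtraction) and every mean > 0.1. Neuron-specific: both neuron means > 0.2,
microglia and endothelia < 0.1. These thresholds are absolute values
calibrated to a genome-wide panel; on the 1,000-gene toy panel the CPM scale
is inflated ~25×, so the pipeline classifies from the annotation's logged-CPM
profiles (in threshold units by construction) and falls back to means
recovered from counts for externally supplied data.

Length-decile fold-change tables report per-decile median log2FC with an OLS
trend on the decile index; two classes' trends are contrasted by Fisher's
r-to-z using the signed correlations and the class gene counts. The
composition trend test is an exact two-sided Wilcoxon rank-sum for combined
n ≤ 20 (where the extreme 2-vs-11 split yields exactly 2/C(13,2) = 0.0256),
normal approximation beyond.

## 5. Problem sizes and determinism

Default corpus: 65 single-cell genomes (~47,000 sSNVs), 3,120 nuclei × 1,000
genes; rank selection scans k = 1–8 with 50 restarts for analysis (10 in
tests). The full pipeline runs in well under a minute on one CPU; these sizes
were chosen so every distributional property the tests assert has adequate
power at desk scale. All randomness is `numpy.random.Generator`-based and
seeded; identical configurations reproduce reports byte-for-byte.

## 6. Known limitations

- The minor signature's vertex is unidentifiable from spectra alone under a
  shared linear age trend (§2.2); reference-based quantification is a modeling
  choice, not a measurement.
- The toy genome's uniform base composition makes every trinucleotide
  abundant; genomes with skewed composition could starve rare strata in the
  matched-control sampler (it reports missing strata rather than guessing).
- DE fold-change estimates carry the pseudocount and compositional biases of
  the standard single-cell convention (§1.3); planted-truth comparisons are
  made in the estimator's own units where possible.
- Indels, CNVs, amplification artifacts, doublets and ambient RNA are out of
  scope throughout.
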