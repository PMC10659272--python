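# brainaging

Integrated analysis of somatic mutation signatures and transcriptome change in
the aging human prefrontal cortex, at single-cell resolution — together with a
seeded synthetic-data generator that reproduces the statistical structure of
such a study at desk scale, so that every stage of the pipeline is testable
end-to-end without access to protected sequencing data.

The package is aimed at computational biologists studying somatic mosaicism
and transcriptomic aging: it implements the analysis chain that connects
per-neuron somatic SNV (sSNV) catalogs from single-cell whole-genome
sequencing with single-nucleus RNA-seq expression matrices from the same
donors.

## The analyses

**Mutational clocks and signatures.** Each cell's sSNVs are summarized in the
96 pyrimidine-centered trinucleotide contexts. Per-cell burden is modeled as a
linear clock, `E[burden] = β · age`, fit by OLS across cells. The per-cell
spectra matrix **V** (96 × n) is factorized by non-negative matrix
factorization minimizing the generalized Kullback–Leibler divergence,

    V ≈ W H,  W ≥ 0 column-stochastic, H ≥ 0,

with the rank chosen by restart-to-restart stability of the signatures versus
the drop in reconstruction error. At the study conditions two components
emerge: a flat, T>C-weighted "clock-like" signature (SBS5-like, ~13.8
sSNVs/year) and a C>T-dominant one (SBS30-like, ~1.8/year). Per-cell exposures
are quantified by non-negative least squares against the reference vectors
matched to the de novo components, and each exposure is regressed on age.

**Genomic placement.** Random controls carrying *exactly* the observed
96-context spectrum are drawn uniformly from callable sites with the same
trinucleotide, so enrichment ratios (genic vs intergenic, expression
quintiles; overall and per signature) isolate placement from sequence
composition. Transcriptional strand bias is the fraction of genic mutations
whose canonical pyrimidine lies on the template strand, per substitution class
and expression quantile. Per-bp sSNV rates are tabulated across gene-length
deciles within gene classes, and class spectra are contrasted with exact
binomial tests.

**Transcriptome aging.** Counts are log-normalized per cell
(`ln(1 + c·10⁴/total)`); elderly-vs-adult differential expression uses a
two-sided Wilcoxon rank-sum test with a 25 % percent-expressed filter and
calls significance at |log2FC| > 0.5, p < 0.05. Housekeeping genes (near-equal
logged CPM across excitatory neurons, inhibitory neurons, microglia and
endothelia) and neuron-specific genes are classified by fixed thresholds;
cross-cell-type shared downregulation is tested against 1,000 size-matched
permutations of expressed genes; fold changes are summarized across
gene-length deciles with OLS trends and a Fisher r-to-z contrast between gene
classes.

## Worked example

The numbered drivers under `analysis/` run the full study on the default
synthetic corpus (13 donors aged 0.4–104 years, 5 single-cell genomes per
donor, 6 cell types × 40 nuclei per donor):

```sh
python analysis/01_simulate_corpus.py
python analysis/02_mutation_signatures.py
python analysis/03_genomic_enrichment.py
python analysis/04_transcriptome_aging.py
```

which prints (seed 1):

```
simulated 47387 somatic SNVs over 65 cells and 3120 nuclei across 1000 genes
chosen rank k = 2
aggregate spectrum vs SBS5-like reference: cosine = 0.990
total:  15.18 sSNVs/year  (R^2 = 0.94, p = 7.32e-41, n = 65)
   A1:  13.81 sSNVs/year  (R^2 = 0.95, p = 8.02e-42, n = 65)
   A2:   1.41 sSNVs/year  (R^2 = 0.34, p = 3.62e-07, n = 65)
     genic: ratio 1.179 [1.171, 1.188], A1: 1.24, A2: 0.62
intergenic: ratio 0.795 [0.786, 0.805], A1: 0.72, A2: 1.44
T>C strand bias (fraction on transcribed strand, all quantiles): 0.641
differential expression: 508 significant calls (508 down) across 6 cell types
gene programs: 300 housekeeping, 230 neuron-specific
shared downregulation: 69 genes, permutation p = 0.000999
housekeeping: decile-median log2FC slope +0.103/decile (R^2 = 1.00)
neuron_specific: decile-median log2FC slope -0.000/decile (R^2 = 0.00)
```

Reading this: the total burden clock and its split into a dominant
T>C-weighted component (A1, tight age fit) and a minor C>T-dominant component
(A2, loose fit) recover the configured per-year rates; A1 concentrates in
genic, highly expressed regions while A2 prefers intergenic space; T>C strand
bias recovers the configured asymmetry (0.65); the housekeeping program is
down-regulated in elderly cells with the planted length gradient (shortest
deciles hit hardest) while neuron-identity genes stay flat; and the planted
cross-cell-type shared-downregulation set beats all 1,000 permutations.

Large intermediate artifacts (reference FASTA, per-cell VCFs, count matrix)
are written under `scratch/pipeline/`; summary tables land in `results/`.

The same stages are exposed as a CLI (`brainaging simulate|spectra|signatures|
enrich|transcriptome|all --config cfg.yaml --out DIR --seed N`) and as a
library (`brainaging.pipeline.run_pipeline`).

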