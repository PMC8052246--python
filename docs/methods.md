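# Methods

## Model and assumptions

The package analyzes exon-level microarray data: each gene is tiled by
several probes whose log2 fluorescence measures local (exon- or
junction-level) transcript abundance. Differential splicing between two
groups appears as a probe whose gene-normalized signal shifts while the
gene-level signal does not.

**Splicing index.** For probe *i* of gene *g*, SI contrasts probe/gene
intensity ratios between groups A and B. All computation is done in log2
space: SI = (P_A − G_A) − (P_B − G_B), where P is the group-mean probe log2
signal and G the gene-level log2 intensity. Gene-level intensity is defined
as the mean over the gene's probes of per-probe means — the simplest
estimator that makes the statistic self-contained and invariant to
per-sample scale shifts (adding a constant to all of one sample's log2
values changes nothing, because probe and gene terms shift together).
Significance per probe is a Welch (unequal-variance) two-sample test on
per-sample probe-minus-gene log2 ratios. Array software for this assay
class reports a per-gene "splicing index with a p-value" without
documenting the gene-level test; here the per-gene summary is explicitly
the signed SI of the maximum-|SI| probe together with that probe's p-value,
with ties broken by the lowest probe index for determinism.

**Batch handling.** When a batch (cohort-of-origin) label is supplied, each
probe is mean-centered within every batch that contains samples of both
groups before the contrast is formed. This location-only correction mirrors
a batch covariate in a balanced design; batches containing only one group
are left untouched, since centering them would absorb the group contrast
itself.

**Individual Splicing Index.** ISI = F_selected / geomean(F₁…Fₙ) with F in
log2 units. The quotient of log2 values (rather than of linear
intensities) is deliberate: it is how the statistic is defined for this
assay family, and downstream inference only requires a monotone per-sample
splicing score, not a ratio with physical units. The geometric mean of
log2 values requires strictly positive inputs; values at or below a log2
floor of 1.0 are rejected with instructions to floor the data upstream,
rather than silently clipped. The selected probe is fixed per gene across
samples — per-sample re-selection would break comparability across
genotype groups. Default selection is by largest |SI| in a reference
contrast (`by_si`); `by_max_f` (largest mean signal) implements the
formula's literal maximum. The two rules are not equivalent and both are
exposed. Note that with a fixed selected probe, ISI ≥ 1 is guaranteed only
when that probe is the per-sample maximum.

**sQTL mapping.** The genotype test is a 2-df nested F: full model =
intercept + gestational age + sex indicator (M = 1) + 1[g=1] + 1[g=2];
reduced model = intercept + covariates. This "full genotypic" form allows
heterozygote-specific effects rather than assuming additivity; a separate
OLS of ISI on dosage {0,1,2} (slope, Pearson r) summarizes additivity for
loci of interest, computed on raw ISI without covariates. SNPs must carry
each genotype class in ≥ 2 samples; missing genotypes are deleted pairwise
per (SNP, gene) test, and a pair whose deletion empties a class is skipped
with a reason code rather than imputed. Cis means the SNP lies within 1 Mb
of the gene's probe-spanning interval (boundary inclusive, distance to the
interval rather than to the TSS because the annotation carries intervals);
anything else, including other chromosomes, is trans. BH FDR is computed
within the cis and trans strata separately by default — mirroring
separately reported cis/trans discovery counts — with a joint-FDR option.

**Trans windows and the Monte-Carlo null.** Significant trans couples
(raw p below a configurable α, presets 1e-3 and 1e-4) are grouped by
sorting the distinct significant SNPs along each chromosome and starting a
new window whenever the gap to the previous SNP is ≥ 2000 bp — a distance
on the order of minimal LD-block sizes, so a window approximates one
haplotype-scale locus. Window length is the number of SNP-gene couples (a
SNP significant for k genes contributes k); the distinct-SNP count is
reported alongside, since either convention is defensible. The null
resamples, uniformly without replacement from the full tested panel, as
many loci as there are distinct significant SNPs, carries each real locus's
couple count to a drawn position, rebuilds windows, and records the maximal
window length; this preserves the number of significant loci and the
per-locus couple multiplicity — exactly the quantities window length
measures — while randomizing genomic organization. Resampling is panel-wide
rather than within-chromosome. The empirical p of the observed maximum is
(1 + #{null ≥ observed}) / (n_perm + 1). Bandmaster windows are those
strictly exceeding the null maximum with ≥ 2 distinct target genes.

## Key parameters

| parameter | default | units | role |
|---|---|---|---|
| SI gene filter | p < 0.001 or \|SI\| > 3 | — | disease splicing screen |
| cis window | 1,000,000 | bp | cis/trans boundary (inclusive) |
| min per genotype class | 2 | samples | SNP retention filter |
| window gap | 2000 | bp | new window when consecutive significant SNPs ≥ gap apart |
| trans α | 1e-4 (preset 1e-3) | — | couple significance for windows |
| n_perm | 1000 | — | Monte-Carlo null size (seed mandatory) |
| FDR threshold | 0.05 | — | sQTL retention |

## Synthetic cohorts

`SimConfig` defaults emulate a two-cohort placental study: 17 controls,
7 preeclampsia, 13 growth-restriction samples in two collection batches;
gestational age group means of ~39 vs ~32–33 weeks; 48 genes with 4–8
probes each; MAF in (0.2, 0.5); a quarter of SNPs placed in tight
(< 2000 bp) clusters. Expression is gene baseline (log2 ≈ 11) + probe
offset + effects + N(0, 0.5) noise, floored at log2 = 2 to emulate scanner
background. Disease splicing adds ±5 log2 to one probe of 12 genes per
disease — the "most strongly spliced genes" regime (screen-scale SI of
roughly 4–5 after gene-mean dilution). Genotypes are i.i.d. Hardy-Weinberg
across SNPs: no LD is simulated, because window clustering consumes only
SNP positions. Genotypes at injected-effect loci are drawn conditionally on
passing the genotype-class filter, since real discovered sQTLs exist only
within the filtered panel. Covariate effects add small gestational-age and
sex terms to 10% of probes.

What the generator does *not* emulate: probe cross-hybridization and GC
bias, LD structure, population stratification, batch-specific
intensity distortions beyond additive shifts. Passing tests therefore
demonstrate correctness and calibration of the statistical machinery under
the assumed model, not robustness to those real-data artifacts.

Three focused configurations are canonical for validation:

* `cis_recovery_config` — 15 + 15 samples, MAF 0.3, one additive cis pair
  with beta = 2 × noise SD per allele, moderate (2 log2) disease splicing
  so the ANOVA residual is noise-dominated;
* `master_recovery_config` — a 7-SNP, < 2000 bp cluster driving 7 distinct
  genes at 3 × noise SD per allele;
* `null_config` — all effects zero, for calibration.

The moderate splicing shift in the recovery configurations is deliberate:
disease status is not a model covariate (only gestational age and sex are,
as in the motivating design), so at the study-scale splice effect (±5) the
disease variance enters the ANOVA residual and a 2-noise-SD genotype
effect is undetectable. That is a property of the design worth knowing:
strong disease splicing on the selected probe masks modest genetic effects
unless effects are large relative to total residual variation.

## Numerical choices

* SI and ISI are computed in log2 space throughout; no exponentiation.
* Welch p-values that are undefined (zero variance, equal means) are
  reported as 1; all p-values are clipped into (0, 1].
* The genotypic F uses `numpy.linalg.lstsq` (tens of thousands of small
  fits in simulation studies); residual df = n − rank(full design), so
  collinear covariates degrade df rather than crash. A zero full-model RSS
  reports F = ∞ with the smallest positive p.
* Ties (max |SI| probe, max mean-F probe) break to the lowest probe index.
* BH FDR delegates to `statsmodels.stats.multitest`; tests verify it
  against a hand-written step-up oracle.
* The Monte-Carlo null is bit-reproducible for a fixed seed
  (`numpy.random.default_rng`); permutations are vectorized with
  `lexsort`/`reduceat`.
* Chromosome order is natural (1…22, X, Y, MT, then lexicographic).
* A 2×2 overlap table with a zero margin reports chi² = 0, p = 1.

## Validation problem sizes

Calibration and recovery claims are computed at deliberately modest sizes:
~5,000 probes for p-value uniformity; ~2,500 SNP-gene pairs for sQTL null
calibration; 40 null cohorts for the bandmaster false-positive rate; 100
seeded cohorts each (12 genes × 60 SNPs, 30 samples) for cis and master
recovery. These sizes give binomial standard errors of a few percent on
the reported rates, sufficient for the stated thresholds.

## Known limitations

* The per-gene p-value is the max-|SI| probe's p-value, not an omnibus
  gene-level test; it is flagged as such in outputs.
* No kinship/population-structure correction, no genotype imputation, no
  haplotype phasing.
* The window null randomizes locus positions panel-wide; if significant
  loci concentrate on atypically dense chromosomes, a stratified null
  would be stricter.
* ISI on log2 values compresses dynamic range; the statistic is a
  relative, per-gene score and should not be compared across genes with
  very different baseline intensities.
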