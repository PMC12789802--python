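# Methods

## Scientific setting

Conventional mantle cell lymphoma (cMCL) loses DNA methylation not only at
active enhancers but also at a small set of CpGs that sit in chromatin that
is inactive in the full-blown tumor. Because demethylation at regulatory
elements is largely unidirectional and persists after the element is
decommissioned, such sites can be read as *imprints* of past genome
activation — either in a hidden subpopulation of the cell of origin (naive
B cells, NBC) or during early lymphomagenesis. `imprintscan` implements the
analysis that identifies and characterizes these sites from
methylation-array beta values, ChromHMM-style chromatin-state
segmentations, accessibility peaks, motif matrices, TF ChIP peak sets and
RNA-seq counts.

## Pipeline model

**Stage 1 — selection.** Per-population mean beta values are computed with
missing values excluded; the NBC mean pools blood and tonsil naive B cells
at the sample level (a flag restricts to NBC-B). A CpG is cMCL-specific
when mean(cMCL) < 0.25, mean(NBC) > 0.75, and mean(pop) − mean(cMCL) > 0.25
for *each* of GCBC, MBC and PB/PC. The third rule removes
proliferation-associated epigenetic drift: highly proliferative mature
B-cell subtypes accumulate passive demethylation at the same loci, so a
site that is also low in those populations is not tumor-specific. All
comparisons are strict, so boundary-equal values are rejected.

**Stage 2 — chromatin classification.** Each CpG takes the state of the
200-bp segmentation bin containing it, per sample. Per population the
per-sample state set is reduced by a fixed hierarchy that prioritizes
active annotations: E1 → ActivePromoter, else E7 → ActiveTranscription,
else E2/E6 → ActiveEnhancer, else E3/E4/E9 → Other, else E5 → Primed, else
Inactive (E8, weak transcription, deliberately falls through to Inactive).
The three Active subcategories merge into `Active`. cMCL accessibility
peaks split Active CpGs into accessible/inaccessible; non-Active CpGs keep
the flag for reporting but not the refined category. Genic context is
summarized by a fractionated score: every (transcript, feature) interval
covering the CpG counts one hit over {intergenic, 1–5 kb upstream,
promoter, 5′UTR, first exon, exon, intron, 3′UTR}; if a first-exon hit
exists the plain exon hits are discarded as redundant; weights are
hits/total so each CpG contributes unit mass to the genome-annotation
distribution. Promoter ([TSS−1 kb, TSS)) and upstream ([TSS−5 kb, TSS−1 kb))
windows are strand-aware; UTRs are the exonic sequence outside the CDS
(the gene-model table carries optional CDS bounds for this purpose).

**Stage 3 — NBC-het / NBC-hom.** Inactive selected CpGs are clustered on
their beta profiles across the NBC samples (agglomerative, Euclidean
distance, complete linkage — the documented defaults of the standard
`hclust` tool; both are configurable and recorded in the output metadata),
and the tree is cut into two clusters. The cluster with the lower mean NBC
methylation is NBC-het (consistent with a hidden subpopulation carrying
the demethylated allele), the other NBC-hom (uniform high NBC methylation,
i.e. a tumor-acquired imprint). A diagnostic silhouette is emitted so a
user can notice when two clusters are inappropriate. The best-separating
DNAm threshold is the midpoint between consecutive observed per-CpG NBC
means that minimizes misclassification by the rule `mean < t → NBC-het`;
among ties the tightest bracketing pair wins.

**Permutation enrichment.** All category enrichments share one engine:
`n` random samplings without replacement from the background, size-matched
to the selection; a simulation scores 1 for a class when its simulated
statistic is ≥ the observed one (≤ for depletion, implemented
symmetrically since results report both directions), and
P = (r+1)/(n+1), counting the observed sample as one permutation. The
statistic is the class count for label data, the summed fractionated
weight for genic annotations, and the unique-closest-gene category
fraction for expression categories (recomputing the unique gene set inside
every simulation is what corrects for CpG probe density). Sampling without
replacement followed by aggregation over items with identical class/weight
profiles is performed as a multivariate hypergeometric draw over profile
counts — exactly the same distribution as a per-item shuffle at
O(profiles) cost per simulation, which is what makes 100 000 simulations
cheap. Fold changes are reported against both the permutation mean and the
analytic background proportion.

**Stage 4 — motifs and TF binding.** Each CpG is extended ±50 bp
(plus-strand sequence); windows crossing a contig end are dropped. The
shared background is all array CpGs with NBC mean > 0.75 minus the
selection, which controls for array composition biases: background base
frequencies convert PFM counts to log2-odds PWMs with one pseudocount
distributed by the background frequencies. A sequence's affinity for a
motif is the mean over all windows on both strands of 2^(PWM window sum);
windows with non-ACGT bases are skipped. Per motif a lognormal null
(mu, sigma = mean and SD of log affinity) is fitted on the ~100-bp
background windows, which serve directly as the tiles. Group enrichment of
N target windows tests the mean log affinity, whose null under the fitted
lognormal is exactly Normal(mu, sigma²/N); we measured this against an
empirical null of 10 000 resampled background window sets (N = 50) at
|Δlog10 p| ≤ 0.41 for p ∈ [1e-3, 0.5]. A Fenton–Wilkinson approximation
for the mean *raw* affinity is available (`statistic="arith_mean"`) but is
poorly calibrated because raw affinities are far heavier-tailed than
lognormal; it is kept for sensitivity analysis only. Per sequence, motifs
are ranked by their lognormal tail p; a motif is "top" when its rank is
≤ ceil(0.05·M) (ties share the minimal rank), and selected when its group
p < .05 and its top-motif percentage is ≥ 10%. TF-peak overlap uses the
±50 bp window (inclusive), one Fisher exact test per TF against the same
background, BH-corrected; TFs with fewer than 5 bound background CpGs are
flagged as unreliable.

**Stage 5 — expression.** Each CpG maps to the closest protein-coding
gene: intragenic CpGs to the host gene (overlapping hosts resolved by
nearest TSS, then lexicographic id), intergenic CpGs to the nearest
strand-aware TSS. FPKM = count / (exonic kb) / (library size per million,
taken as column totals). A gene is expressed in a population when its mean
log10(FPKM + 0.01) exceeds 0. Differential expression cMCL vs NBC-B is a
deliberately simple negative-binomial Wald test — median-of-ratios size
factors, pooled method-of-moments dispersion floored at 1e-8, log2 fold
change of normalized means with a 0.5 pseudocount, delta-method standard
error, BH adjustment — and an externally computed (gene, log2FC, padj)
table can be supplied instead; the six-category hierarchy, which is the
analysis' own contribution, is independent of the DE engine. The rules
are applied literally in the printed order, so a gene expressed in only
one population with a non-significant fold change is "stable";
`strict_loss_precedence=True` reorders lost/de-novo before stable for
sensitivity analysis.

## Synthetic data

The generator emulates the study conditions at desk scale: 2 contigs ×
5 Mb, 20 000 CpGs (one per chosen 200-bp bin, ≥ 120 bp apart, each a CG in
the generated genome), and the real cohort's sample structure (6 HPC, 16
early B, 10 NBC-B, 5 NBC-T, 9 GCBC, 10 MBC, 11 PB/PC, 62 cMCL, 20 nnMCL
methylation samples; 2 cMCL + 3 NBC-B segmentations; 3+3+3+3+3 normal and
2 cMCL RNA-seq samples). Planted classes: 600 active (150 of them under
accessibility peaks), 80 inactive NBC-hom, 230 inactive NBC-het, 400
drift, the remainder background (70% methylated / 30% unmethylated
everywhere). Beta values are Beta(mean·ν, (1−mean)·ν) draws with
precision ν = 150, chosen so that population means resolve the 0.25/0.75
thresholds cleanly at the real sample sizes while single samples remain
noisy (SD ≈ 0.03–0.04). Demethylated classes sit at 0.08 in cMCL and 0.92
in normals; NBC-het CpGs use the mixture mean f·0.10 + (1−f)·0.93 ≈ 0.805
with hidden-subpopulation fraction f = 0.15; drift CpGs drop to 0.30 in
GCBC/MBC/PB-PC so the drift rule must exclude them (margin 0.22 vs the
0.25 cutoff — a deliberate near-miss).

Segmentations place planted active CpGs in E2/E6 bins in cMCL (E11 in
NBC-B) and planted inactive/drift CpGs in E8/E10/E11/E12 bins in both
populations; other bins draw a genome-wide state mix dominated by
heterochromatin. Each sample keeps a bin's planted state with probability
0.9; the replacement is drawn within the same category tier at
planted-CpG bins (so per-sample noise cannot flip a planted category
through the any-sample-active rule) and from all other states elsewhere,
which still exercises the hierarchy on background bins. Motif consensus
sequences (10-bp synthetic PFMs, 85:5 counts; two motifs per class for
active, NBC-hom and NBC-het plus four decoys) are inserted at 80% of
planted windows, avoiding the CpG dinucleotide; insertion samples from the
PFM instead of the consensus behind a flag. The ReMap-style BED covers 70%
of planted motif instances with the corresponding TF plus a 2% background
binding rate for every TF. RNA-seq counts are negative binomial
(dispersion 0.05); de novo expression (mean 300 in cMCL, 0.3 elsewhere) is
planted at exactly the genes nearest the NBC-hom CpGs, with lost/up/down
classes planted at 30 random genes each for category coverage.

What the generator does **not** emulate: probe chemistry and array batch
effects, tumor purity, copy-number artifacts, realistic CpG island
clustering (CpGs are spaced ≥ 120 bp, so proximity fractions are near 0),
correlated histone-mark structure along the genome, and overdispersion
heterogeneity across genes. Passing tests therefore demonstrate that the
algorithms recover planted structure under calibrated noise, not that the
thresholds are optimal for real cohorts.

## Numerical choices and degenerate inputs

- Permutation p-values are floored at 1/(n+1); enrichment and depletion
  are computed from the same draws, so p_enrich + p_deplete ≥ 1.
- Weight profiles are grouped after rounding at 1e-9 to keep the
  multivariate hypergeometric reduction exact under floating-point noise.
- sigma of the lognormal null is floored at 1e-6; identical tiles warn.
- All-identical cluster input degenerates to a single NBC-hom cluster with
  a warning; missing NBC values are imputed by the CpG row mean.
- Probes missing in ≥ 50% of any population's samples are dropped with a
  logged count (configurable); population means exclude missing values.
- Beta means of exactly 0 or 1 in the simulator are clamped to
  [1e-3, 1−1e-3] with a warning.
- A master seed spawns independent child streams per component
  (generator) and per stage (pipeline) via `numpy.random.SeedSequence`,
  so re-running one stage in isolation reproduces its output and adding a
  component does not perturb the others; identical config + seed yields
  byte-identical files.

## Problem sizes

The default dataset (20 000 CpGs, 149 methylation samples, 600 genes, 10
motifs) runs the full pipeline, including 100 000 chromatin/annotation
simulations and 10 000 gene-category simulations, in well under a minute
on one CPU; the test suite regenerates it from scratch. These sizes were
chosen as the smallest scale at which every planted signal is
statistically unambiguous (enrichment folds ≥ 2, clustering ARI = 1 in
expectation) while all class proportions echo the real study's structure.

## Known limitations

- The hierarchical classifier treats every uncovered segmentation
  position as an error; real segmentations with gaps need pre-filtering
  (synthetic segmentations are gap-free).
- The NB Wald test is not a substitute analysis for a shrinkage-based DE
  framework at small n; with 2 tumor samples its dispersion estimate is
  crude, which is why an external DE table can be injected.
- The motif stage assumes equal-length windows for targets and background
  (101 bp vs the nominal 100-bp tiles; no length correction is applied).
- Group motif p-values assume independent target windows; overlapping or
  repeat-rich windows would inflate significance.
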