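# Methods

This note documents the models, statistics and design choices behind
`episenet`, in the order the pipeline runs them, together with what the
synthetic cohort does and does not emulate.

## Coordinates and interval algebra

All coordinates are 0-based half-open (`[start, end)`, BED-native); any
1-based input must be converted at the boundary. Overlap is strict
half-open: touching intervals do not overlap. Stitching is non-strict —
two peaks whose inner distance equals the stitch gap (12 500 bp by default)
are merged, following ROSE convention, and merging is transitive per
chromosome. The cross-sample state matrix is built on the finest partition
induced by all segment breakpoints (the `bedtools unionbed` construction);
only regions covered by every sample are retained, and sex chromosomes are
excluded by default.

## Super-enhancer calling

Peaks fully contained in a promoter window `[TSS − 2500, TSS + 2500)` are
removed before stitching; the window is strand-agnostic because annotation
conventions differ and the asymmetry is negligible at 2.5 kb. Stitched
regions are ranked by corrected signal `max(IP − input, 0)` summed over
constituent peaks, ties broken by genomic position so ranking is a
deterministic permutation. Two SE definitions coexist:

* the **inflection rule** (`rose_cutoff`): with both axes min–max scaled
  and rank ascending in signal, the cutoff is the first point whose
  discrete central-difference slope exceeds 1 (tolerance 1e-9 against
  float noise on exactly linear curves). Flat or linear curves have no
  inflection and return 0. Tests pin this against an exhaustive
  diagonal-tangent search (the point deepest below the unit diagonal),
  which agrees within ±2 ranks on hockey-stick curves;
* the **top-N override** (`call_superenhancers`): the top 1000 ranked
  regions per sample, which is what all downstream stages consume. A focal
  amplification inflates the signal scale, compresses the scaled curve and
  collapses the inflection count; the fixed top-N count is invariant to it.

Consensus regions are overlap-merges (gap 0) of sample-level SEs, kept when
occupied by ≥ 2 samples (`min_samples`). Activity is
`log2(1 + corrected signal per kb)` of each sample's stitched enhancers in
the region — a library-free RPKM-like scale; the constant is simply per-kb
density, documented here rather than configurable.

**Differential SE activity** is a per-region Welch t-test on log2 activity
(difference of group means is the log2 fold change), with BH-adjusted
q-values reported alongside and significance taken at raw p < 0.05. A
count-model (negative-binomial GLM) test could be slotted behind the same
contract; the Welch test was chosen because the calibration and power
acceptance runs bound its behaviour directly: on null cohorts its
false-positive rate sits inside the binomial 99% interval of 0.05, and it
recalls ≥ 80% of planted 2× effects at 5 vs 5 samples.

## Chromatin-state landscape

The fixed signed transform encodes activation: E2 (active enhancer or
promoter) +3, E3 (bivalent) +2, E1 (quiescent/no mark) +1, E5 (weakly
repressed) −1, E6 (heterochromatin) −2, E4 (Polycomb-repressed) −3.

**Feature selection.** Regions that are E1 in *all* samples are dropped
(regions partially E1 are kept — the intent is to enrich for active
chromatin, not to discard mixed regions). Then two count-based cutoffs,
both relative to the post-exclusion region count: top 1% by Shannon
entropy of the empirical state distribution across samples, then within
those the top 1% by variance of the signed score. Ties at either boundary
are kept, and entropy/variance are accumulated in sorted order so the
selection is exactly invariant to sample and region order. Treating both
fractions as fractions of the total (rather than compounding them) is the
only reading consistent with a final feature set of ≈ 1% of the genome-wide
segments.

**MCA.** Multiple correspondence analysis with samples as observations and
regions as categorical variables, computed as correspondence analysis of
the complete indicator matrix (SVD of the standardised residuals of
`indicator / total`). Sample principal coordinates are `D_r^{-1/2} U Σ`;
total inertia obeys `J/Q − 1` for `J` total levels over `Q` regions, which
the tests verify. Per region and dimension we report a **signed loading**:
the correlation ratio η (between-category share of the dimension's
variance) oriented by the Pearson correlation between the region's signed
scores and the dimension coordinate — a sign convention is required for
gene ranking and the basal/non-basal direction, and η itself is unsigned.
The loading p-value is the one-way ANOVA of the dimension coordinate on
the region's categories, the standard dimension-description test.

**MDS + MNN.** Classical (Torgerson) MDS on Euclidean distances between
samples in signed-score space. Batch correction operates in the embedding:
for each sample of the smaller batch, mutual nearest neighbours (k = 3)
in the other batch are found, and the displacement to them — pair
displacements weighted by inverse squared distance, so a coincident
partner implies no correction — is subtracted; samples without mutual
pairs receive the mean displacement of corrected ones. This is an
embedding-space simplification of gene-space MNN (fastMNN): the acceptance
checks are behavioural (batch silhouette collapses, planted cluster
silhouette is preserved at ≥ 0.9× and the Dim-2 two-cluster cut matches
the planted basal/non-basal labels with ARI ≥ 0.8), not numerical
equivalence to fastMNN.

**Gene ranking and eQTL.** Regions passing the loading p < 0.05 filter map
to genes; a gene under several regions takes the loading of largest
magnitude (a mean-aggregation alternative would damp strong regions; max
preserves the extreme ranks GSEA consumes). Segment–gene eQTL pairs keep
Pearson p < 0.05 across shared samples; pairs with constant score or
expression are skipped and counted. The per-gene TSS state uses frequency
dominance over a gene's annotated TSSs, ties resolved toward the more
active state.

## SE→gene assignment

Candidates per SE: genes whose body overlaps the SE (`overlap`), the gene
with the TSS nearest the SE midpoint (`proximal`), and genes whose
GREAT-style regulatory domain intersects the SE (`basal_extension`) — the
basal region is strand-oriented 5 kb upstream / 1 kb downstream of the
TSS, extended on both sides up to 1 Mb but stopping at the neighbouring
gene's basal region. The GREAT defaults are adopted because the mode is
named but the numbers are not fixed by the analysis description. The best
link is the candidate with the highest Spearman correlation between SE
activity and expression — by default over all shared samples; the pipeline
restricts to tumours (`tumour_samples=`), since cultured samples carry a
strong in-vitro expression component that is noise for cis-regulation.
Ties break toward the nearer TSS. SEs with constant activity are flagged
unassigned, never dropped silently. `top_pairs` ranks all SE × gene
Spearman pairs (guarded at 2 × 10⁶ pairs; a candidate-restricted mode
covers larger problems) and returns the top 1%.

## Regulons and the TF network

`aracne_lite` estimates TF–gene mutual information on equal-frequency bins
(`floor(sqrt(n))` bins, capped at 10). Because equal-frequency binning
gives every gene identical marginals, a single permutation null serves all
pairs. During bootstrap consensus the null must carry the same
duplicate-pair structure as the resampled data, so the permuted gene
vector is permuted *before* the bootstrap index is applied — permuting
after resampling makes every null MI too small and the edge rate collapses
to ~100% (this failure mode is covered by a calibration test).
`n_bootstraps = 1` means no resampling (a pure significance gate); with
more bootstraps, edges present in > 50% of rounds are kept with the
support fraction as weight. DPI removes the weakest edge of each
TF–TF–target triangle when it is below the minimum of the other two minus
a tolerance (default 0). Edge sign (mode) is the sign of the TF–target
Spearman correlation, since MI is unsigned. The published MI p-value
threshold of 1e-8 is kept as the default; tests and the synthetic pipeline
use relaxed thresholds (1e-2 with hundreds of permutations) because a
permutation null cannot resolve 1e-8 at tractable cost.

**Regulon activity** is `Σ_t mode_t w_t z(t, s) / sqrt(Σ_t w_t²)` over the
regulon's targets, with genes z-scored across samples — a deliberately
simple stand-in for three-tailed enrichment scoring (aREA/VIPER) that is
zero-mean per TF, comparable across regulon sizes, and on a scale where
the driver-TF gate |group-mean activity| > 2 behaves as intended (planted
drivers score ≈ ±3–5, bystanders ≈ 0). The driver gate intersects four
conditions: best-linked target of a differential SE, annotated TF,
differentially expressed between the two subtypes (same Welch test at
p < 0.05), and the activity threshold; the subtype is the group of largest
absolute mean activity. The final TF–TF graph keeps Pearson r ≥ 0.5 edges
over all samples (within-subtype correlation would shrink toward noise at
these sample sizes); connected components are the reported modules.

## Subtype transfer

Reference and query are normalised per sample by rank-based inverse-normal
transform before the gene-intersection merge — any monotone per-platform
scale (TPM, RLE, RMA) maps to identical scores, which the tests verify by
exponentiating the query. Feature selection is one-way ANOVA F on the
reference classes, top 2000 genes, ties by gene id; single-sample classes
are dropped with a warning. Classification embeds reference + query
*jointly* (the embeddings are non-parametric) into 2-D once per ensemble
member, seeded `base_seed + e`, and votes the k = 6 nearest reference
neighbours (Euclidean; vote ties break toward the smaller summed
neighbour distance). The default embedding is scikit-learn's tSNE with
per-member random initialisation; a PCA + random-orthogonal-rotation
embedding is available as a fast fallback for tests. The tSNE default was
selected after measuring that the rotation embedding dilutes local class
structure (a duplicated reference sample self-votes in only ~76% of
rotation embeddings versus ~100% of tSNE embeddings). Class vote
frequencies sum to 1 by construction and are the reported probabilities.

## Signatures

Single-cell QC applies the gene filter (expressed in < 3 cells) and then
the cell filter (< 200 detected genes) in one fixed pass — the sequence is
not iterated to a fixed point. Markers per cluster are two-sided Wilcoxon
rank-sum versus all other cells with BH correction; markers require
adjusted p < 0.05 and positive log fold change of means and are ranked by
logFC. Preranked GSEA follows the weighted running-sum: hit increments
`|score|^w / Σ|score|^w` (w = 1 by default), miss decrements
`1/(N − n_set)`; ES is the signed extremum, the leading edge the hits at
or before (positive ES) / after (negative ES) it. p is the signed
one-sided gene-label permutation fraction with add-one correction (floor
`1/(n_perm+1)`); NES divides ES by the mean |permuted ES| of matching
sign. The plasticity-signature adaptation requires the luminal set to be
enriched among perturbation-down-regulated genes and the basal set among
up-regulated genes (both p < 0.05, configurable) and returns the two
leading edges. Signature-space projection fits PCA on reference samples
restricted to the signature genes, centring and scaling with *reference*
statistics only, so queries project into the reference's coordinate frame;
zero-variance signature genes are dropped with a count.

## The synthetic cohort

The generator emulates a 24-sample design — 9 Luminal, 9 Ba/Sq, 4
Stroma-rich, 2 normal urothelium, of which 15 are tumours and 9 cultured —
on a toy diploid genome (2 × 10 Mb, 360 genes). Its structural choices:

* **Peaks and signal.** One shared background peak set (consensus peak
  geometry is common across samples of a tissue) at 30 peaks/Mb, 1 kb
  wide; IP counts are negative binomial (dispersion r = 10) with mean 60
  versus input mean 15 (~4× enrichment, as called H3K27ac peaks are).
  Planted SEs are 20 kb windows of four constituent peaks with in-group
  mean 120 versus out-of-group 60 — the 2× effect size is a calibration
  choice, as no quantitative subtype effect size is established.
* **Programme sharing.** A planted Luminal SE is active in Luminal and
  Stroma-rich samples (the differentiation programme); a Basal SE in Ba/Sq
  and normal urothelium (whose cultured, proliferative state is
  basal-like). All planted state differences therefore align on one
  basal-versus-non-basal axis — the dominant chromatin split in bladder
  cohorts, and the two-cluster structure the landscape stage must recover.
  `SyntheticCohort.state_clusters` records this planted labelling.
* **States.** 2 kb bins with a shared background state per bin, E2 at
  active planted SEs and E4 elsewhere, the target gene's promoter bin
  following its SE's programme, a culture stripe (20% of bins flip to the
  opposite-signed extreme state in cultured samples — the strong in-vitro
  effect that dominates Dim 1), and per-sample randomisation at
  `state_noise_rate` = 0.1.
* **Expression.** Gene baselines N(8, 1) log2 units; +0.4 × signed state
  score of the promoter bin (TSS-state coupling); +2 log2 units at planted
  targets where their SE is active; TF programmes with driver activities
  +3 in the driver's subtype and −1 elsewhere, regulon targets at
  0.8 × mode × activity; residual noise sd 0.5.
* **Geometry for identifiability.** SEs sit 5–10 kb downstream of their
  target with clearance to the next gene's basal region, planted SEs
  cannot stitch into one another, and genes bordering an anchor carry no
  regulon programme — so each planted link is expressed by exactly one
  candidate and the truth table promises only links the geometry creates.
* **Determinism.** All randomness flows from one seed through
  `numpy.random.SeedSequence` spawning; identical configs give
  bit-identical cohorts, and the cohort writer/readers round-trip exactly.

What the generator does **not** emulate: read-level noise and mappability,
copy-number beyond the single 100× amplification flag, continuous
enhancer-strength gradients (effects are two-level), correlated noise
between samples, sex chromosomes, and realistic gene density or SE sizes
(everything is scaled down ~300-fold). Passing recovery tests therefore
demonstrates the *logic* of each stage under its stated assumptions, not
performance on real ChIP-seq.

Planted links whose programme is active in fewer than 4 tumour samples
(the normal-urothelium-only programme: 2 of 24 samples) are below what a
rank correlation on this design can identify (null Spearman sd ≈ 0.21
against an attainable ≈ 0.4); the link-recovery acceptance check is
therefore assessed on links with ≥ 4 active tumour samples, and the
unrestricted figure is reported alongside by `scripts/acceptance.py`.

## Problem sizes

The shipped test and acceptance runs use: the default 24-sample cohort
(2 × 10 Mb, 10 000 state bins, ~400 consensus SEs), 5 vs 5 cohorts for
differential power/calibration, 10 TFs × 30 targets × 100 samples for
regulon recovery, 10 planted chains for DPI, a 60-reference/12-query
3-class transfer problem at 50 embeddings (down from the 1000 used for
production calls), and 400-cell two-population single-cell matrices.
These sizes keep the full suite under two minutes while leaving every
recovery margin wide.

## Known limitations

* The Welch differential test treats log activity as approximately normal;
  heavy zero-inflation (sparse occupancy) would make it conservative.
* MCA loading p-values are not multiplicity-corrected (the selection they
  feed is a ranking, not an inference).
* `aracne_lite`'s permutation p cannot reach the 1e-8 production threshold;
  at that setting the gate effectively becomes "MI above every permuted
  value".
* Embedding-space MNN corrects only the embedded dimensions; residual
  batch structure orthogonal to the embedding is untouched.
* The ensemble classifier's joint embedding makes predictions depend
  (weakly) on the query batch composition; this is inherent to
  non-parametric embeddings and documented in the classifier docstring.
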