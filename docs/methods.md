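# Methods

## The data and the model

msGBS produces, per individual, read counts at restriction cut-site loci of
a methylation-sensitive enzyme (HpaII). Methylation blocks digestion, so the
expected count at a locus decreases with its methylation level; the package
treats methylation entirely on this observed count scale and never infers a
methylation fraction. The unit of observation is the cut-site locus
(scaffold, 1-based position, strand); samples belong to one of three groups
(`parent1`, `parent2`, `hybrid`) and carry a sampling site and a total
library size. Counts are modelled as negative binomial: for sample *j* in
group *g*, Y<sub>lj</sub> ~ NB(mean = μ<sub>lg</sub>·L<sub>j</sub>/10⁶,
dispersion φ), where μ<sub>lg</sub> is the group's expected CPM at locus *l*
and L<sub>j</sub> the library size.

Coordinates are kept 1-based inclusive throughout, matching GFF3; library
sizes come from the sample sheet rather than column sums because
normalization should reflect the full sequencing depth of each sample, not
just the loci that survive filtering (a fallback to column sums exists for
sheets without depth information).

## Normalization and locus filtering

CPM = count × 10⁶ / library size, with no additional between-sample scaling
(no TMM-style factors): the normalization is depth-only by design, and a
trimmed-mean variant was deliberately left out rather than hidden behind a
default. For a two-group comparison, a locus is kept when strictly more than
`cpm_threshold` (default 1) CPM is seen in at least *n* individuals of
*each* group, with *n* defaulting to the smaller group's size;
`FilterSpec(inclusive=True)` switches to ≥ for sensitivity analysis, and an
explicit `n` override exists because published analyses sometimes use an
*n* below the smaller group's size. Filtering is applied per comparison;
the joint three-group variant is used only for the all-sample ordination.

## The differential test

The test is the exact conditional NB construction for two groups of count
libraries:

1. counts are rescaled to the mean library size and summed within groups
   (sums rounded to integers; the rescaling error this introduces is second
   order when depth variation is moderate, and vanishes at equal depths);
2. conditional on the total t = S₁ + S₂, the split S₁ follows a
   distribution with log-mass ∝ lnΓ(s + r₁) − lnΓ(s + 1) + lnΓ(t − s + r₂)
   − lnΓ(t − s + 1), r<sub>g</sub> = n<sub>g</sub>/φ — the NB analogue of the
   binomial split, to which it reduces exactly as φ → 0 (φ < 10⁻⁸ is
   dispatched to the binomial branch, and a closed-form binomial oracle pins
   this limit in the tests);
3. the two-sided p-value is the minimum-likelihood convention: the sum of
   probabilities of all splits whose probability does not exceed the
   observed one, ties included via a 10⁻⁹ log-tolerance.

log₂ fold change is computed on group mean CPMs with a 0.5-CPM pseudo-count
(configurable) to avoid infinities at zero means; with hybrids as the focal
group, positive logFC means more reads, hence *less* methylation
(hypomethylation) in hybrids. Direction is assigned by sign (threshold 0);
a magnitude threshold is exposed but not default, since hypo/hyper fractions
should partition the DMC set.

Dispersion is estimated from the conditional NB likelihood given group
totals (the quantile-adjusted conditional ML idea): the common value
maximizes the likelihood pooled over loci and both groups (bounded scalar
optimization on log φ over [10⁻⁶, 5]); per-locus values are the argmax over
a fixed 80-point log-spaced grid — deterministic and fast — shrunk toward
the common value with weight 0.8 (few samples per group make per-locus
estimates noisy; the weight is configurable). Estimates at the lower bound
snap to 0. Multiple testing uses Benjamini–Hochberg; a DMC satisfies
q < `fdr_threshold` (strict, default 0.01). Common DMCs are the loci
significant in both hybrid-vs-parent comparisons, ordered by scaffold and
position.

## Inheritance classification

Per locus, group mean CPMs are compared: hybrid mean within the closed
parental interval ⇒ additive; above ⇒ overdominant; below ⇒ underdominant.
Boundary equality counts as additive because transgression is defined
strictly, and ties have measure zero on continuous CPMs. Means (not
medians) keep the geometry consistent with the logFC machinery. The caller
chooses the locus set: the parental DMC set for the "intermediate in
hybrids" table, the common set for the transgressive table. Profile
clustering z-scores each locus across samples (sample SD, ddof = 1;
zero-variance loci map to zero rows) and applies average-linkage (UPGMA)
agglomeration on Euclidean distances; the linkage method is configurable in
spirit but UPGMA is the default since no particular linkage is canonical
here. Dendrograms serialize to Newick.

## Genomic context

A locus is a *promoter* hit when it lies within `promoter_window` (default
2000 bp) upstream of a gene's strand-aware start (upstream of `start` for +
genes, of `end` for − genes), exclusive of the gene body; a *gene body* hit
when inside the gene's coordinates; *intergenic* otherwise; *unannotated*
when its scaffold carries no gene annotation at all (one defensible
operationalization of "unannotated region"; an explicit scaffold set can
override it). Precedence promoter > gene_body > intergenic makes the four
categories a partition; `dual_labels=True` reports promoter and gene-body
membership independently. Gene ties break by distance to the gene start,
then gene id.

## Distances, ordination, association

* Euclidean distances feed the classical (Torgerson) MDS: eigendecomposition
  of the double-centred Gram matrix, axes ordered by descending eigenvalue,
  each axis sign-fixed so its largest-magnitude loading is positive (a
  deterministic convention; argmax ties break by sample order), axes beyond
  the positive-eigenvalue rank zero-padded and flagged.
* Bray–Curtis d(u,v) = Σ|uᵢ−vᵢ| / Σ(uᵢ+vᵢ), over features observed in both
  samples when `pairwise_deletion=True` (used for SNP dosages; missing
  genotypes are never imputed); two all-zero vectors are at distance 0.
* The Mantel test correlates off-diagonal entries (Pearson) and permutes the
  second matrix's samples jointly on rows and columns;
  p = (1 + #{r<sub>perm</sub> ≥ r<sub>obs</sub>}) / (1 + n<sub>perm</sub>),
  one-tailed for positive association by default (the scientific hypothesis
  is genome–methylome coupling), two-sided by flag.
* The pairwise mixed model regresses epigenetic distance of each unordered
  pair on genetic distance plus the sites and species of the two pair
  members, with crossed random intercepts for the two individuals (MLPE).
  Slots 1/2 of a pair follow the fixed sample-list order, a convention that
  must be stated because the model formula alone does not define it.
  Fitting is maximum likelihood (not REML) so the AIC comparison against
  the fixed-effects-only OLS fit is valid; single-level categorical terms
  are dropped as unidentifiable; a constant genetic-distance matrix is a
  hard error.

## The synthetic generator

Defaults describe a natural-hybrid msGBS design: 22 + 17 parental samples
and 5 F1 hybrids split over two sites; 5% of loci species-divergent with a
3-log₂ parental difference; inheritance mix 0.9/0.06/0.04
additive/over/under among divergent loci; transgressive shift 2 log₂ units
beyond the nearer parent; NB dispersion 0.3 (a biological CV near 0.55,
plausible for wild outbred samples); log-normal library sizes with mean 10⁶
and CV 0.3; per-locus baseline CPM log-normal with median 30 and log-SD 1.
Additivity is defined on the log₂ scale (hybrid at the parental geometric
mean), which always lies inside the parental CPM interval, so simulated
truth and the classifier's mean-CPM geometry agree. Genotypes contain 80%
species-diagnostic markers (dosages 0 vs 2, hybrids 1, in both orientations
relative to the reference so no species is an all-zero vector) plus
background markers and 2% missingness; gene models tile 70% of scaffolds so
all four context categories occur. One seed drives independent sub-streams
for counts, library sizes, genotypes and genes.

What it does *not* emulate: read-level artefacts (alignment, PCR
duplicates), per-cytosine bisulfite-style states, linkage between loci,
shared polymorphism between species, or environment-driven methylation.
Passing tests therefore demonstrate statistical correctness and pipeline
integrity under the NB count model, not robustness to those real-data
complications.

## Calibration and known limitations

Under the NB null the exact test's p < 0.05 rate is nominal to within
Monte-Carlo error and the q < 0.01 rate is far below 0.01 (exact tests are
discrete, hence conservative at small totals). A structural property of the
design — not of the implementation — is detection bias in the common-DMC
set: with very few hybrid samples, an additive locus differs from each
parent by only half the parental difference, while a transgressive locus
differs from both parents by at least the full transgressive shift, so at
stringent FDR the detected common set over-represents transgressive loci
even though classification of detected loci matches the simulated truth
essentially perfectly. The acceptance script quantifies both effects
(`additive_fraction_common_dmcs` vs `inheritance_call_truth_agreement`);
the realized mode proportions approach the simulated mix only in the
large-effect / low-dispersion limit. Consequently, estimated
transgressive percentages from small hybrid cohorts should be read as upper
bounds.

Problem sizes used by the test suite and acceptance script — 2,000-locus
null replicates, a 5,000-locus recovery experiment, 500-locus pipeline runs,
200 Mantel replicates at 8 samples, 30-individual mixed-model fits — are the
package's chosen desk-scale study conditions; all are seeded and
reproducible.
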