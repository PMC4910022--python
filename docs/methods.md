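# Methods

## Measurement model

A tumour section is represented as a lattice of 1 mm² squares. Each square
carries a status (tumour / mixed / non-tumour), the cancerous fraction of
its area, and a positivity value: % positive nuclei (PNC markers: HIF-1α,
HIF-2α, Ki-67) or % positive pixels (PPC markers: phospho-mTOR,
phospho-S6RP). Two conventions matter throughout:

- **Corrected area.** A mixed square's PPC denominator is its cancerous
  pixel count, not the square size, so positivity is invariant to how much
  non-cancerous tissue was excluded. PNC counts only nuclei whose centroid
  lies in the cancerous area; centroid assignment is used because a
  boundary-straddling nucleus must belong to exactly one square for counts
  to add up.
- **Flagged squares.** A quantifiable square with zero nuclei has no
  defined % PN; it keeps a null value and is excluded from statistics
  rather than scored 0.

Squares with cancerous fraction below 0.05 are treated as non-tumour: a
3-pixel denominator would make percentages meaningless. The cut-off is a
package decision, not derived from the source workflow, and is
configurable.

## Heterogeneity scores

Per tumour/marker sample (n squares, values x): sample s.d. (n−1
denominator); MAX-μ = max(x) − mean(x) with the mean over *all* analysed
squares (whether "average positive value" means all squares or only
positive ones is ambiguous in the source description; all-squares is
implemented and the alternative is a one-line change); Shannon
H = −Σ pᵢ ln pᵢ and inverse Simpson D = 1/Σ pᵢ² over binned data
categories. Natural log is used for H (the conventional ecological form;
the base is configurable). D uses the plug-in form by default with the
bias-corrected small-sample form `1/[Σ nᵢ(nᵢ−1)/(N(N−1))]` behind a flag.

Binning uses half-open intervals `[k·w, (k+1)·w)` with the last bin closed.
Full-range markers (0–100%) use 5% bins → s = 20 categories.
Restricted-range markers (≈0–25%) use 2% bins over a 40% span, which keeps
s = 20; 2% over 0–25 would give 13 categories, and the two stated goals
("2% intervals" and "s = 20") cannot both hold over a 25% range, so the
span is configurable and 40% is the default that preserves the category
count.

A sample is classified **heterogeneous** when the D'Agostino–Pearson
omnibus test (K² = Z(√b₁)² + Z(b₂)², χ²(2) tail; `scipy.stats.normaltest`)
rejects normality at p < 0.05. Samples passing normality are simply
"not heterogeneous" — no third class. The test is refused below n = 8
(hard floor); its transforms are unreliable below n ≈ 20.

## Zonal analysis

Peripheral zone = outermost tumour squares: squares 8-adjacent to the
exterior background or the lattice edge, where the exterior is the flood
fill of non-tumour squares from the border. Background flood fill uses the
dual (4-) connectivity, the standard pairing that keeps a closed tumour
contour watertight. Internal holes (vessels, necrosis) therefore create no
periphery. 4-connectivity for adjacency is available by flag.

Erosion depth is the number of successive peels until the tumour is
exhausted. A lesion needs depth ≥ 3 to be analysable — the direct reading
of the exclusion rule for two-layer lesions with no usable central zone.

Peak localization: the zone of the square(s) attaining the sample maximum.
Ties spanning both zones are reported as tied and counted as
central-peaked for enrichment — conservative toward the peripheral
hypothesis. Enrichment is tested with the one-sided binomial tail
P[X ≥ k | n, p=0.51]; one-sided because the question is specifically
whether peaks localize peripherally. Whether the original trial was one-
or two-sided is unstated; one-sided is implemented and flagged here.

## Marker correlation

Aligned sections share lattice dimensions and statuses (enforced). Each
tumour square contributes one row of five marker values; rows with any
null are dropped listwise. Spearman ρ (average-rank ties) is computed over
all squares pooled within a subgroup — whether the original analysis
pooled squares or averaged per-tumour coefficients is unstated; pooling is
the default and a per-tumour average is provided. Degree labels use |ρ|
(the scheme is applied to negative coefficients in the source usage) with
boundary values assigned to the upper class; the sign is a separate field.
No multiple-testing correction is applied across the 10 pairs × 3
subgroups, matching the source analysis; Benjamini–Hochberg is available
behind a flag.

## Variant pipeline

Order of operations (asserted by test): cohort-wide recurrence filter
(identity = chrom/pos/ref/alt; present in ≥ 6 of 8 patients, counting both
regions of one patient as one occurrence — the per-patient-counting
alternative is unstated in the source) and dbSNP filter (known flag set,
clinical flag unset); per-patient stratification into central-only /
peripheral-only / shared; functional filter (nonsynonymous, splice-site,
stop gain/loss SNVs; indels carried with their own labels but excluded
from spectra, which are SNV-defined); 96-category classification;
strand-bias filter; background-corrected spectra.

**Strand bias.** The removal rule is verbatim from the source (< 2
supporting reads on the strand opposite the bias), but how bias was
*declared* per category is not stated. The package declares a category
biased when a two-sided binomial test of its pooled forward vs reverse
read counts rejects balance at α = 0.01 — a decision documented as such.
Pooling is cohort-wide for power at desk-scale counts.

**Classification.** Substitutions with purine reference are
reverse-complemented onto the pyrimidine strand: 6 substitutions × 16
flanking contexts = 96 categories, labels like `A[C>T]G`, ordered
substitution-major with ACGT flanks.

**Background.** Every 3-mer whose centre lies in a target interval is
counted; a triplet and its reverse complement pool into one
pyrimidine-centred class, stored in a 64-slot table with mirrored slots
equal, so each category divides by its context unambiguously. Both-strand
counting is required for correct denominators: a G-centred site is a
potential (reverse-complement-mapped) mutation site for a C-centred
category. Category rates countᵢ/backgroundᵢ are rescaled to sum to 1;
comparison is by cosine similarity u·v/(‖u‖‖v‖).

## Synthetic-data generators

**Grids.** A tumour mask is drawn as a thresholded smoothed Gaussian field
(largest 8-connected component; an ellipse option exists), on a 12×12
lattice with 45% non-tumour — giving ~75 analysable squares per section
and ~7% of lesions excluded as two-layer, both at the scale of the
motivating study (which averaged ~75 squares/section and excluded 3 of 30
lesions), with an empirical peripheral-square fraction near the 0.51 used
in the Bernoulli trial. Tumour squares take value
`baseline + delta·[outermost layer]` plus Gaussian noise truncated to the
marker's range — a single-step periphery enrichment, the minimal structure
that makes the zonal finding recoverable (deeper gradients are a config
extension, off by default). Noise is Gaussian-with-clipping rather than
beta: the simplest model consistent with percent scales; clipping is
truncation and is documented as such. Panels share one mask and correlate
noise across markers through a shared latent field. Slide images construct
counts first (disjoint nucleus disks, stained pixels) and draw second, so
image→grid quantification is an exact round trip by design. Seeds are
explicit arguments everywhere; no global state.

**Variants.** A single synthetic contig (60 kb by default) with a
whole-contig target BED keeps the "exome background" well defined without
a genome download. Default cohort: 8 patients × (4 shared truncal + 8
central-private + 3 peripheral-private) SNVs — the central-rich,
periphery-poor balance of the motivating study — plus one private indel
per patient, ~10% synonymous decoys, strand-bias artifacts (10% of true
privates; forward-skewed reads with < 2 reverse reads) planted in a
designated low-signature category, 2 recurrent artifacts planted in ≥ 6
patients, and 2 dbSNP decoys. Trinucleotide contexts are planted into the
reference at the variant positions (≥ 3 bp apart so contexts never
overlap) so the aggregate expected spectrum equals the configured
signature exactly; the default signature is mildly C>T-enriched.

**What the generators do not emulate.** Real stain chemistry, nuclei
segmentation and registration error; spatial autocorrelation of marker
expression beyond the shared latent noise; subclonal structure, allele
frequencies, coverage variation and caller error profiles; realistic
signature mixtures. Passing tests therefore validate the *analysis
machinery* (scores, partitions, filters, classification, normalization and
their calibration), not the biology of any real cohort, and the headline
numbers of the motivating study (which depend on 30 clinical tumours and
controlled-access exomes) are not reproduced at desk scale.

## Validation experiments and problem sizes

Chosen once as desk-scale study conditions:

- **Zonal calibration/power:** 200 cohorts × 12 tumours per arm; the
  enriched arm uses delta = 2 noise s.d. Measured over 1 000 null
  cohorts, the no-enrichment rejection rate is ≈ 4% (the binomial test at
  p = 0.51 with ~11 analysable tumours is slightly conservative by
  discreteness; single 200-cohort estimates scatter ±3 points around it).
- **Normality classifier:** 2 000 standard-normal samples of n = 150
  (measured type-I rate of the omnibus test at this n is ≈ 5.4%) and
  2 000 well-separated bimodal samples.
- **Spectrum recovery:** 20 seeds × three 8-patient cohorts (default
  signature for goodness of fit and artifact accounting; a
  disjoint-support C>T-only / T>G-only pair for the similarity-ordering
  check, since the ordering claim concerns *distinct* mutational
  processes — with one shared signature, sparse-count noise dominates and
  no ordering is implied).
- **Spearman recovery:** Gaussian-copula pairs with true rank correlation
  0.5 (Pearson r = 2 sin(π/12) on the latent scale), n = 2 000 squares
  per pair, averaged over five pairs: a single pair's estimate has
  sampling s.e. ≈ 0.022, so averaging measures estimator accuracy rather
  than draw noise.

## Known limitations

- The RGB "brown" stain detector is a crude exploratory aid; the validated
  path consumes label images or precomputed grids.
- Grids are assumed pre-aligned; no registration is implemented.
- Bias declaration (α, pooling scope) is a package decision; with the
  original per-sample rule unknown, filtered sets on real data may differ.
- The inverse Simpson plug-in form is biased upward for very small n; use
  the bias-corrected flag when n is small relative to s.
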