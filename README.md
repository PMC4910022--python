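# ith-niche

Spatial intratumoural heterogeneity (ITH) analysis for tile-gridded
immunohistochemistry and region-stratified exome variants.

Clear cell renal cell carcinoma and other solid tumours show marked
variation in marker expression and mutation content between regions of one
tumour. This package implements the analysis chain used to ask two
questions about that variation: *does functional ITH scale with malignant
progression?* and *is it spatially organized into niches — a proliferative,
signalling-active tumour periphery versus a quieter centre?* It is aimed at
computational pathology and cancer-genomics analysts who have per-square
marker positivity (or label images to quantify) and per-region variant
calls, and want the complete scoring, zonal and spectrum analysis with a
tested synthetic ground-truth path.

## What it computes

**Tile-grid quantification** (`grid_quant`). A section is overlaid with a
virtual lattice of 1 mm² squares. Per square, positivity is the percentage
of positive nuclei (PNC; HIF-1α, HIF-2α, Ki-67) or positive pixels (PPC;
phospho-mTOR, phospho-S6RP), with mixed squares normalized to their
cancerous ("corrected") area.

**Heterogeneity scores** (`heterogeneity`). For the per-square values *x₁…xₙ*
of one tumour/marker:

- sample s.d. and the MAX-μ score `max(x) − mean(x)` (outlier highlighter);
- after binning into *s* ≤ 20 data categories (5% bins for 0–100% markers,
  2% bins for restricted-range markers), the Shannon index
  `H = −Σ pᵢ ln pᵢ` and inverse Simpson index `D = 1/Σ pᵢ²`;
- the D'Agostino–Pearson omnibus normality test; a sample rejecting
  normality (p < 0.05) is classified *heterogeneous*;
- Kruskal–Wallis / Mann–Whitney comparisons of any score across prognostic
  subgroups.

**Spatial niches** (`zones`). The peripheral zone is the outermost tumour
squares (8-adjacent to the exterior background, found by border flood
fill so internal holes create no periphery); everything else is central.
Lesions with fewer than three erosion layers are excluded. Peak-expression
localization is tested with a one-sided Bernoulli trial at success
probability 0.51 (near-balanced zone sizes).

**Marker correlation** (`correlation`). Spearman ρ between markers over
directly corresponding aligned squares, pooled per subgroup, with the
conventional degree labels (|ρ| 0–0.2 none, 0.2–0.4 weak, 0.4–0.7
moderate-to-good, 0.7–1.0 good-to-very-good).

**Mutational spectra** (`spectra`). Centre/periphery variant sets per
patient are stratified into region-specific and shared; variants recurrent
in ≥ 6 of 8 patients or dbSNP-known without clinical context are removed;
functional SNVs (nonsynonymous, splice-site, stop gain/loss) are kept;
per-category sequencing strand bias is filtered (< 2 reads opposite the
bias); SNVs are classified into the 96 pyrimidine-referenced trinucleotide
categories, corrected for the target's triplet composition, and compared
with cosine similarity per patient and for the merged strata.

**Synthetic data** (`simulate_grids`, `simulate_variants`). Generators with
known ground truth for every stage: irregular ~75-square tumour sections
with configurable outermost-layer enrichment and inter-marker correlation,
rasterized slide-like label images whose per-square fractions are exact by
construction, and 8-patient variant cohorts with planted signatures,
strand-bias artifacts, recurrent artifacts and dbSNP decoys.

## Worked example

The numbered scripts under `analysis/` run the full study-style analysis on
the synthetic cohort (30 tumours in three subgroups, five aligned markers;
8 patients' centre/periphery variant sets) and write tables under
`results/`:

```
$ python analysis/01_simulate_cohort.py
wrote 30 tumours x 5 markers to .../results/cohort
total data points (squares x markers): 11300

$ python analysis/03_zonal_niches.py
1 lesion(s) excluded (fewer than three square layers)
1129 peripheral vs 1068 central squares evaluated (empirical peripheral fraction 0.514)
peak expression peripherally enriched in 15/15 marker x subgroup cells (p<0.05)

$ python analysis/05_mutational_spectra.py
105 region-specific variants across 8 patients after recurrence/dbSNP filtering
strand-biased categories: ['T[T>A]T']; 9 SNV(s) removed
cross-patient cosine similarities span 0.000-0.433 (mean 0.110); merged central-vs-peripheral similarity 0.162
```

Reading the output: the simulated cohort reproduces the intended study
conditions — near-balanced zone sizes (peripheral fraction 0.514 ≈ the 0.51
Bernoulli success probability), peak marker expression recovered in the
periphery in every marker × subgroup cell because the generator plants
outermost-layer enrichment, and all planted strand-bias artifacts removed
by the per-category filter. Cosine similarities are small because each
spectrum is a sparse draw (tens of SNVs over 96 categories); see
`docs/methods.md` for what the synthetic cohort does and does not emulate.

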