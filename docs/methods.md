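# Methods

## Peptide registry and mass model

The registry (`src/histoquant/data/peptides.tsv`) contains the standard
propionylation-workflow backbone peptides, in 1-based mature-protein
numbering (initiator Met removed), with closed residue spans:

| id | sequence | mod sites (allowed states) |
|---|---|---|
| H3_18-26 | KQLATKAAR | K18, K23 (un/ac) |
| H3_9-17 | KSTGGKAPR | K9, K14 (un/ac) |
| H3_73-83 | EIAQDFKTDLR | K79 (un/me1/me2/me3) |
| H3.3_27-40 | KSAPSTGGVKKPHR | K27 (un/ac/me1–me3), K36 (un/me1–me3) |
| H3_27-40 | KSAPATGGVKKPHR | as H3.3 (A31 distinguishes the variants) |
| H4_4-17 | GKGGKGLGKGGAKR | K5, K8, K12, K16 (un/ac) |
| H2A_12-17_T/_S | AKAKTR / AKAKSR | none (variant-pair QC control) |

Only acetyl and methyl states are modeled; phosphorylation and other PTM
classes are out of scope for this workflow.  The H2A T16/S16 pair is two
backbones sharing one normalization *family*, so their recovery ratio is
well defined; every other family is a single backbone.

Derivatization is modeled as complete: a propionyl group on each peptide
N-terminus and on every lysine in state un or me1 (including lysines that
are not declared mod sites, e.g. H3 K37).  Monoisotopic masses use the
pyteomics residue/element tables; PTM deltas are computed from elemental
formulas (`ptm_deltas.tsv`): ac +42.010565, me1 +14.015650, me2 +28.031300,
me3 +42.046950, propionyl +56.026215 Da.  Fragment ladders are b/y with
m/z = (neutral + z·proton)/z; charge 1+ is the default throughout because
the annotated histone MS/MS in this workflow are dominated by singly charged
b/y ions; higher charges are supported in the ladder math.

Two forms are isobaric iff their PTM-type multisets agree (ac = un − CH2
makes this exact, not approximate).  Discriminating ions are found by
pooling both series' ladders across isoforms and single-pass clustering by
m/z (tolerance 0.4 Da by default, matching ion-trap MS/MS accuracy;
configurable, with a ppm mode in the matcher): clusters not produced by all
isoforms are discriminating, and their 0/1 production pattern forms the
indicator matrix.  For H3 18–26 K18ac/K23ac the discriminating ions are
b1–b5 and y4–y8 (the K18-containing prefixes and K23-containing suffixes);
y1–y3 contain neither lysine and are shared.

## Isomer deconvolution

The averaged spectrum across a chromatographic peak is the
precursor-intensity-weighted mean of the MS2 spectra (plain mean available),
binned by m/z within tolerance; a spectrum lacking a peak in a bin
contributes zero at its weight, so averaging identical spectra is the
identity.  Observed peaks are matched to theoretical ions greedily by m/z
distance, one peak per ion, ties broken toward the lower theoretical m/z.

Mixing fractions solve a least-squares problem on the probability simplex:
`argmin ‖obs − s·Zθ‖²` with `Z` the indicator matrix over discriminating-ion
clusters and `s` the shared-ion intensity scale (median observed intensity of
clusters produced by all isoforms — robust to single outliers; if no shared
ion is observed, `s` is calibrated from the discriminating ions and the fit
flagged).  The solver enumerates supports and solves each
equality-constrained KKT system exactly (`numpy.linalg.solve`); with at most
a handful of isomers this is exact and fast.  The system is solved in
scale-normalized units (`obs/s` against the 0/1 matrix) because carrying raw
intensity scales (~1e6) into the KKT matrix makes it numerically
ill-conditioned against the unit-scale constraint row.  For two isomers the
closed form θ₁ = I₁/(I₁+I₂) over per-isomer unique-ion sums is used; it
coincides with the simplex solution whenever shared and unique ions are
consistent (exactly, on noise-free mixtures).  The reported residual is the
L1 fraction of discriminating-ion intensity the fit leaves unexplained; a
spectrum with no discriminating signal yields a flagged, undefined estimate
rather than a guess.

## Quantification

Peak areas are trapezoidal over an RT window after subtracting a flat
baseline (median intensity outside the window, floored at 0) and clipping
negatives.  Relative abundances divide each unit's area by the family total;
units below the limit of quantification — by default an area under 0.001 of
the family total — are flagged and zeroed *before* normalization, and a
family with no signal at all is flagged wholesale.  `integrate_peak` also
returns the baseline so callers can additionally impose a signal-to-baseline
floor; that check is not wired into the normalization because the baseline
is a property of the trace, not of the area table.  Missing forms contribute
zero area to the denominator, keeping fractions comparable across samples.
Splitting a class fraction by θ conserves the class total exactly.

Whether raw areas should be baseline-subtracted at all is a judgment call in
this workflow; the flat-median baseline was chosen as the most testable
robust default, and is exactly zero on the synthetic traces.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes —
and only that structure:

* **Elution**: Gaussian peaks (σ = 0.1 min default), one XIC per form;
  isobaric co-eluters share a single trace with identical elution profile —
  the worst case for chromatographic separation, which is exactly when
  MS/MS deconvolution is needed.  Peaks are laid out on a fixed RT grid
  (2 min spacing), so no retention-time alignment is exercised.
* **MS2**: 7 spectra (configurable) on a fixed grid across ±2σ of each
  multi-isomer peak; fragment intensities are θ-weighted sums of the
  isoform ladders scaled by the precursor height at that RT, with
  multiplicative log-normal noise (CV configurable, 0 by default) and an
  optional additive uniform floor.
* **Replicates**: per condition and family, expected fractions are the
  input simplex times per-form fold-change effects, renormalized; each
  replicate draw multiplies every unit by mean-one log-normal noise
  (default CV 0.20, the level indicated by the variant-pair recovery
  control) and renormalizes.  Default design: input n=4, a bromodomain
  pulldown n=4 with multi-fold acetylation enrichment, a fusion-protein
  pulldown n=2 with stronger combinatorial enrichment (n=2 groups are never
  t-tested; they get range-based descriptive output).

All randomness flows from one `numpy` Generator seeded by a single integer.
What passing tests on these data do *not* show: robustness to isotope
envelopes, charge-state mixtures, chimeric MS2, retention-time drift,
incomplete derivatization, or missing-value structure of real LC-MS runs —
none of which the generator produces.

## Statistics

* **Welch's t** is implemented directly (means, ddof-1 variances,
  Welch–Satterthwaite df, two-sided p from the t distribution) and checked
  against scipy's unequal-variance t-test to 1e-9 in the test suite.  The
  input group is passed first, so pulldown enrichment yields negative t.
  Zero variance in both groups with equal means returns t=0, p=1 flagged
  degenerate; with unequal means it raises rather than fabricating a
  statistic.
* **Normality gate**: Shapiro–Wilk per group (3 ≤ n ≤ 5000); the gate marks
  `gate_passed` but does not suppress the Welch result, since the sensible
  fallback for non-normal small samples is a judgment left to the analyst.
  n=2 groups are reported with ranges only.
* **Technical threshold**: per-sample T16/S16 ratio; spread = max
  |deviation from the mean|/mean (primary) or SD/mean (`mode="sd"`);
  threshold = 2 × spread, falling back to the fixed 0.4 with a warning when
  the control peptides are absent.  `exceeds_technical` marks
  |log2 fold| > log2(1 + threshold).
* **Calibration note**: with n=4 log-normal CV-0.2 replicates the Welch
  test is mildly conservative (empirical type-I ≈ 0.04 at nominal 0.05
  across thousands of null simulations) because such small samples retain
  skewness ≈ 0.6 that the Shapiro gate rarely detects.  This is a property
  of the test under multiplicative noise, not of the implementation.
* **Pearson matrix**: pairwise over forms quantified in both samples
  (below-limit excluded pairwise; ≥3 shared forms required, otherwise the
  pair is flagged not-computable), p from the t transform, 95% CI by Fisher
  z (needs n > 3).  Compositional (log-ratio) treatment of the simplex data
  is deliberately not applied; plain fractions are the convention this
  workflow reports.
* **Multiple testing**: raw p-values are primary; Benjamini–Hochberg
  q-values are an optional, clearly secondary column.
* **Timepoint comparison**: per-form −log2(t1/t0) of mean levels, so
  decreases map to positive values; zero or below-limit levels are excluded.

## Problem sizes and tolerances

Monte-Carlo checks use 200 simulations for recovery/power analyses and 1000
for null calibration (±2 Monte-Carlo SE acceptance band); isomer recovery is
checked at MS2 CV ∈ {0, 0.02, 0.05}.  Mass assertions are at 1e-6 Da;
simplex sums at 1e-9 in construction and 1e-6 after file round-trips;
solver equivalences at 1e-9.  These sizes keep the full suite under a
minute on a laptop while leaving every Monte-Carlo margin comfortably wide.

## Known limitations

* Complete propionylation is assumed; under-derivatization would bias
  fractions and is not modeled.
* No peptide-spectrum matching, retention-time prediction, isotope-envelope
  deconvolution, or cross-run alignment — inputs are already form-assigned
  XICs/MS2 (or the synthetic equivalents).
* The deconvolution assumes discriminating ions of a class have equal
  theoretical response within an isoform (unit ladder intensities); real
  fragment-ion yields vary, which would fold into the per-ion residual.
* mzML ingestion is not implemented; the exchange formats are the
  documented TSV/CSV (plus read-only XLSX for abundance tables).
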