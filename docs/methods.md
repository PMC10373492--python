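# Methods

## Scope and data model

The package analyses positive-mode full-MS/DIA acquisitions of enzymatically
digested DNA. A run is modelled as RT-ordered centroided spectra: MS1 full
scans (110–650 m/z) interleaved with one MS2 scan per DIA isolation window
per cycle. The DIA geometry is a set of contiguous, non-overlapping windows
of equal width; the two supported acquisitions are 16 × 10 m/z over 195–355
(low-mass 2′-deoxyribonucleoside adducts) and 26 × 10 m/z over 347–607
(high-mass adducts). Window membership uses the half-open convention
[lo, hi): a boundary m/z belongs to the upper window, so every precursor
maps to exactly one window. Retention times are minutes throughout.

mzML reading and writing are implemented directly on the XML (lxml),
covering plain and indexed mzML, 32/64-bit float arrays, zlib or no
compression, and profile-to-centroid conversion by local-maximum picking
(intensity-weighted m/z of the apex and its two neighbours). The writer
emits uncompressed 64-bit arrays deterministically, so a fixed simulator
seed yields a byte-identical file.

## Peak detection

Extracted-ion chromatograms sum all centroids within the target m/z ±
tolerance per spectrum; spectra without a match contribute zero (no
interpolation). Detection is a matched-filter design:

1. Gaussian smoothing, σ = 0.075 min.
2. Two zero-area filters — negated second derivatives of Gaussians with
   widths 0.085 and 0.165 min, offset to sum exactly to zero — both of
   whose responses must be positive at a candidate apex (a smoothed local
   maximum). Candidates closer than the wide filter width keep only the
   higher apex.
3. Baseline and noise from the raw trace in an 8.0-min window centred on
   the apex, excluding the peak region: baseline = median, noise = half the
   16th–84th percentile spread. This quantile estimator equals the
   MAD-based σ for symmetric noise but, unlike the plain MAD, does not
   collapse to zero on the one-sided, sparse intensity distributions of
   centroid EICs.
4. S/N = (smoothed apex − baseline) / noise, cutoff 5 by default; an
   otherwise empty trace gives infinite S/N.
5. Peak bounds are the zero crossings of the narrow filter response around
   the apex; area is the trapezoidal integral of the raw trace between
   them. For a Gaussian peak of σ ≈ 0.05 min this interval covers ≈ 99% of
   the true area, which is why spike-recovery tests hold a 5% tolerance.
6. A persistence criterion (`min_points`, default 4 non-zero scans within
   the bounds) rejects single-scan spikes, which in sparse EICs would
   otherwise pass with infinite S/N.

All filter widths are in minutes and exposed as parameters; the published
descriptions of the original screening software name these parameters but
not their algorithmic semantics, so the implementations here are declared,
configurable choices rather than reconstructions.

## Neutral-loss screening and the master list

MS1 centroids inside the acquisition's scan range are clustered by sorting
all m/z values and splitting at gaps larger than the ppm tolerance;
clusters with at least `min_points` centroids become candidate EIC bins.
For each detected precursor peak the expected fragment is
`precursor − 116.0473`; the MS2 EIC in the window containing the precursor
must contain a peak whose apex co-elutes within 0.1 min. The loss
tolerance (default 5 ppm) is referenced to the **precursor** m/z: referencing
it to the 116 Da loss itself would reject catalogued adducts whose pairs
deviate by ~2 mDa, while at precursor reference all pass; the suite pins
this convention. Observed precursor and fragment m/z are intensity-weighted
means across the peak, so the reported loss error reflects the whole
elution profile rather than one scan. ESI adducts and isotopologues are
deliberately not removed.

Master-list merging is single-linkage over hits within 5 ppm (m/z) and
0.5 min (RT), with median consensus coordinates, and is idempotent. IDs are
`L#`/`H#` by ascending m/z within the mass class given by the low-mass scan
range.

## Confirmation, dG normalization, RSD filter

Each master entry is re-integrated per run at its consensus m/z (± 5 ppm)
accepting the detected peak closest to the consensus RT within ± 0.2 min
("comparable retention time" is not standardized; the tolerance is
configurable). Absence is data, not an error. Normalized abundance is
`area × 100 / area(dG)` per sample, with dG integrated at the [M+H]+ m/z of
C10H13N5O4 (268.1040, computed, not hard-coded) and a run-specific RT from
configuration; this cancels DNA amount, digestion losses, and response
drift, and is exactly invariant to a common instrument-response factor.
Replicate repeatability: RSD = 100 × sd/mean of normalized areas across an
animal's replicate digestions, aggregated across animals by the maximum
(conservative; mean available). Retention requires RSD strictly below 20%;
an adduct at exactly 20.0% is dropped. Zero replicate means exclude the
adduct with a logged reason.

## Composition annotation

Monoisotopic masses use most-abundant-isotope IUPAC values (≥ 6 decimals);
the proton is 1.0072765 Da. Annotation standardizes on neutral composition
plus protonation. Enumeration solves the hydrogen count directly from the
residual mass for every (C, N, O) triple within bounds (defaults C ≤ 40,
H ≤ 80, N ≤ 12, O ≤ 20; minima C 9, O 3, N 2), keeps candidates within the
ppm tolerance with RDB ≥ 0, and by default discards half-integer-RDB
candidates, which for even-electron protonated CHNO ions violate
nitrogen-rule parity (the filter can be disabled; catalogued ion-convention
formulas with half-integer RDB are then recovered). Results are ranked by
|Δppm|. The search equals exhaustive enumeration (tested against a
brute-force oracle) at a fraction of the cost.

## Statistics

* **Transforms.** Adducts: natural log of dG-normalized areas (zeros
  replaced by half the column minimum positive value), then Pareto scaling
  (centre, divide by √sd) — variance of a scaled column equals the
  pre-scaling sd. Contaminants: log then z-score. Invariant columns are
  dropped with a warning.
* **Correlations.** Pearson r between every adduct and contaminant column;
  two-tailed p from the exact t transform. A Welch t-test compares the mean
  PAH correlations of high- vs low-mass adducts.
* **PERMANOVA.** Euclidean distances on the transformed matrix (Bray–Curtis
  is undefined on negative values; the metric is configurable). Gower
  centring, sum-to-zero factor coding, Type III marginal SS via hat-matrix
  traces; pseudo-F per term; p from free permutation of observations,
  p = (exceedances + 1)/(n_perm + 1) with 999 permutations by default, or
  exhaustive enumeration for small n. PERMDISP embeds samples by principal
  coordinates, measures distance to the group centroid, and permutes labels
  around a one-way ANOVA F.
* **SIMPER** runs on the non-negative dG-normalized areas with the
  classical pairwise Bray–Curtis decomposition; contributions conserve
  100%, and selection takes the smallest descending prefix reaching the 80%
  cumulative cutoff.
* **OPLS-DA.** Orthogonal signal correction (one predictive component plus
  k orthogonal, default 1): w ∝ X'y; per orthogonal component the loading
  part orthogonal to w is deflated from X. R²Y on the full fit; Q² =
  1 − PRESS/TSS from seeded stratified 10-fold cross-validation refitting
  the entire model per fold. VIP on the predictive component satisfies
  mean(VIP²) = 1. With zero orthogonal components the predictive scores
  equal the first PLS1 component.
* **ROC.** AUC by the rank statistic (ties 0.5) — identical to the
  normalized Mann–Whitney U; 95% CI by stratified bootstrap (2000
  resamples, seeded); misclassification at the Youden-optimal threshold.
* **Volcano.** log2 of the contaminated/reference ratio of group means on
  the dG-normalized scale, Welch t-test on logged values. The fold-change
  cutoff is on the ratio scale, the usual volcano convention: the default
  threshold 2 flags |log2 FC| ≥ 1 at p ≤ 0.1. Zero group means trigger
  half-minimum substitution and are flagged.
* Raw two-tailed p-values are reported (α = 0.05); t-tests are Welch's
  throughout.

## Synthetic data

`simulate_run` mirrors the acquisition loop: one MS1 scan followed by the
full DIA sweep at a fixed cycle time (1 s). Planted adducts elute as
Gaussians (σ = 0.05 min, consistent with ~0.2 min base widths at
micro-flow LC); fragments appear in the correct window at
`efficiency × precursor` intensity; m/z values receive Gaussian ppm jitter
(σ = 1 ppm); baseline noise is Poisson-counted uniform-m/z centroids with
exponential intensities. Isotope envelopes are off by default (the
screening chain does not deisotope). A manifest records ground truth.

`simulate_study` reproduces the field design: 19 stations in two basins
(10 contaminated / 9 reference, 47 animals with the per-station counts of
the study), 53 low- + 66 high-mass adducts, lognormal abundances
(between-animal log2 sd 0.6 by default), six effect adducts at
|log2 FC| = 2, triplicate digestions for six animals (replicate log2 sd
0.08, giving RSDs well below the 20% gate), per-sample dG areas so
normalization is genuinely exercised, eleven PAH congeners with LmPAH/HmPAH
sums, ten trace metals with a pollution-load index (geometric mean of
median-normalized metals), a contaminated-site elevation of untargeted
contaminants, and Gaussian-copula correlation targets between chosen
adduct/contaminant pairs on the log scale (infeasible target sets, Σρ² > 1,
are rejected).

What the simulator does **not** emulate: isotope envelopes and ESI adduct
clusters, retention drift between runs, matrix-dependent ionization
suppression, heteroscedastic detector noise, and missingness mechanisms
other than below-threshold signal. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated generative
model, not field-data performance; the field-scale headline numbers of any
real campaign (counts of detected adducts, Q², AUC) are expected to differ.

## Numerical choices and degenerate inputs

Chromatograms shorter than 5 points yield no peaks. EICs are never
interpolated. Ties between candidate apexes keep the higher one. Zero dG
areas, single-class labels, singleton factor levels, all-zero SIMPER
samples, and infeasible copula targets raise errors naming the offender.
Permutation p-values can never be below 1/(n_perm + 1). All stochastic
stages take explicit seeds; pipeline re-runs with the same configuration
are bit-reproducible.

## Problem sizes used in the shipped analyses

The bundled drivers and test suite use a 20-min, 1-Hz-cycle high-mass run
(≈ 32 000 spectra) for spike-in recovery with 36 planted adducts; 200
seeded null studies of 20 samples × 20 adducts for type-I calibration of
PERMANOVA (999 permutations each) and the volcano t-test; and a 48-sample
(24 + 24) study for planted-effect recovery. These sizes give stable Monte
Carlo estimates while keeping the full suite under a minute of statistics
compute; all are parameters, not constants.

## Known limitations

Co-eluting isomers within the ppm tolerance merge into one feature (no
deconvolution); baseline drift is handled only through the windowed robust
baseline; overlapping DIA window schemes are not supported; annotation
enumerates CHNO only (S/P masses are available for user-supplied formulas
but not searched); and OPLS-DA assumes two classes.
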