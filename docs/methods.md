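# Methods

This note documents the models, defaults and numerical choices behind the
package, what the synthetic generators do and do not emulate, and the known
limitations.

## Synthetic fluorescence fields

A field is three registered channels (DAPI, CK, CD45) on a 16-bit camera
scale: baseline 500 counts, cell amplitudes ~5,000–30,000, additive
Gaussian read noise (default sd 30). Each cell is an isotropic Gaussian
blob with σ = r/2 truncated at 3σ, where r is the class's nominal radius.
Class templates: tumor-like cells are DAPI⁺/CK⁺/CD45⁻ (radius 6.5 ± 0.5 µm),
leukocyte-like cells DAPI⁺/CK⁻/CD45⁺ (5.5 ± 0.4 µm), debris DAPI-absent
sub-cellular specks (1.2 ± 0.3 µm) with faint marker bleed. An Otsu mask of
such a blob cuts at roughly a third of peak amplitude, i.e. at ~0.7 r, so
the nominal radii are chosen to put *measured* areas in the physiological
range (leukocytes ~40–60 µm², tumor cells ~70–130 µm²) rather than the
nominal ones.

Illumination is modelled as a multiplicative linear tilt along x (default
amplitude 0.15) applied to the stain signal; the baseline and read noise
are added afterwards, which makes the value at a cell center an exact
closed form (`baseline + A·illum(x, y)` ± noise) used as a test oracle.
Singleton cells are placed by rejection sampling with a hard non-overlap
constraint (100 retries per cell, loud failure when the field is too
crowded), so the segmentation count oracle is exact; cluster members are
deliberately placed adjacent/overlapping around an anchor to create tumor
microemboli.

Not emulated: optics (PSF, chromatic shift), autofluorescence spectra,
staining heterogeneity within a cell, focal drift, 3-D structure. Passing
tests therefore demonstrate the pipeline's correctness on well-behaved
blob-like cells with known ground truth, not its accuracy on real stained
blood smears.

## Image pipeline

Illumination correction divides by a background field: the channel is
morphologically opened (structuring element ~25 px, i.e. about one cell
diameter, so cells are erased), heavily blurred (Gaussian σ = min
dimension / 8), and the quotient is rescaled to preserve the global
median. For large fields the background is estimated on a block-averaged
copy (factor `min_dim // 256`) and resized back; the blur scale dwarfs the
block size, so the estimate is unchanged to well under a percent. The
correction is positively homogeneous — it rescales, never reorders,
pixels — and idempotent to ~1%.

Otsu thresholding is implemented directly on a 256-bin histogram with the
smallest-threshold tie-break, and is tested for exact agreement with an
exhaustive between-class-variance search and with scikit-image's
implementation. Segmentation runs on DAPI only (cells are defined as
nucleated; marker channels are measured, not segmented), uses
8-connectivity with hole filling, keeps border objects flagged, and does
no watershed declumping: touching nuclei stay one object whose
`nuclei_count` (smoothed-DAPI local maxima) records its multiplicity, so
microemboli evidence is preserved for enumeration.

Features are ~25 per object: six morphology features plus six intensity
features per channel. The local background for corrected means and folds
is the median of a 2–5 px dilation ring around the object, excluding
pixels of any object (Chebyshev bands, with ring pixels near two objects
owned by the higher label — immaterial for a median over a smooth
background). The debris filter bounds (area 30–700 µm², solidity ≥ 0.7,
DAPI fold ≥ 2) are deliberate, config-exposed placeholders: real platforms
tune these on their own optics.

## Identification

The marker gate (DAPI fold ≥ 2, CK fold ≥ 2, CD45 fold ≤ 1.5, intactness
as solidity ≥ 0.7 and area within the debris bounds) is definitional and
acts as a hard veto on the classifier score; the classifier (threshold
0.5 by default) only narrows candidates. Hyperparameter grids are small
and fixed — GBM trees 100 / depth {2,3}; AdaBoost estimators {100,200};
RBF-SVM C {0.1,1,10} with standardization and fold-held-out Platt
calibration; RF trees {100,300}; XGB trees {100,300} / depth {2,4} —
because the protocol compares families, not exhaustive tuning. Class
imbalance is handled by stratification only. Models serialize to a
self-describing joblib archive with a feature-schema hash checked on load.

The end-to-end detector (the model `detect_sample` deploys) is trained on
image-derived features from rendered truth-labeled fields, restricted to
morphology plus the fold-over-background intensities. Folds are invariant
to illumination and exposure scale, so a cell rendered at the dim edge of
a field scores like one at the bright edge; raw intensity features would
place such a cell outside the training hull, where tree ensembles cannot
extrapolate and silently assign it the majority class. CK positivity and
CD45 negativity remain enforced by the gate veto regardless of the
classifier's feature set.

The default labeled-population generator draws class-conditional Gaussians
on log scales for intensity folds and areas and logit scales for shape
parameters, so positivity constraints hold by construction. Its fold
distributions are centered on what the image pipeline actually measures on
rendered fields (single-digit folds — the annulus sits on the blob tail).
At the default separation the marker channels are ≥ 6 within-class sd
apart on the log scale, putting the Bayes error far below 10⁻⁶; a
separation scale of 0 collapses the classes to exchangeability.

## Enumeration

`ctc_count` sums nuclei over final-label CTC objects (a k-nucleated
cluster contributes k cells); an object counts toward `ctm_count` when it
is multi-nucleated or its centroid lies within one mean cell equivalent
diameter of another CTC in the same field (both the radius factor and the
rule are config-exposed — the microembolus definition is a package choice,
and reports flag it). Counts are reported per 5 mL of blood and not
rescaled to other draw volumes' conventions.

## Cohort simulation

Per-group CTC counts follow zero-inflated negative binomials whose
defaults are calibrated so the closed-form positivity
`1 − (π + (1−π)(k/(k+µ))^k)` and the mean match the clinical summaries the
generator emulates (e.g. the hepatocellular group: positivity 59.3%, mean
1.37 — solved by π = 0, µ = 1.37, k = 1.138; healthy donors are effectively
Poisson with µ = 0.008). Matching those two moments caps the achievable
count sd at ~1.74 for the hepatocellular group (the clinical tables print
~2.0); positivity and mean are the quantities the downstream statistics
consume, so they take priority. Recurrence uses exponential event times —
baseline hazard 0.0089/month for count-zero subjects and a hazard ratio of
3.36 for count-positive subjects (median time-to-recurrence ≈ 23 months) —
with independent uniform censoring on 6–33 months; the Kaplan–Meier
estimand is closed-form under this model. A single per-group hazard cannot
produce the count-stratified recurrence contrast, hence the two-level
hazard.

Spike-in experiments are i.i.d. Binomial(n_spiked, recovery probability)
per replicate, with the default recovery probability 0.756.

## Single-cell CNA

Input is a BED-like bin-count table (0-based half-open; the simulator's
toy genome is 3 chromosomes of 60/45/30 Mb in 500 kb bins with
Beta-distributed GC). Counts are divided by their mean, corrected by a
robust lowess fit of ratio vs GC (quadratic fit available), and
renormalized to mean 1; zero-count bins are retained. The simulator draws
NegBin(mean = depth · CN/ploidy · g(GC), size k) with a quadratic GC
response normalized to mean 1; "dispersion" is the NB size parameter
(default k = 10, i.e. overdispersion α = 0.1 at the reference depth of 100
reads/bin).

Segmentation is penalized least-squares changepoint detection on log2
ratios (floored at −4), per chromosome. Each recursion evaluates the best
single split (one penalty) and the best *interior carve-out* — a
circular-style two-changepoint test whose flanks share one mean — at twice
the penalty, and applies whichever clears its penalty by more. The
carve-out is essential: the greedy single split through a short interior
plateau (say 30 of 120 bins) captures only a fraction of the step and
falls below any penalty that still rejects null splits. The default
penalty is `3 · σ² · log n` with σ from median absolute first differences;
that multiplier sits just above the expected maximal spurious gain on a
constant profile (≈ 2σ² log n), so mild over-segmentation is possible and
harmless (adjacent segments receive the same integer CN). Minimum segment
length is 3 bins; the O(n²) carve-out search is skipped above 2000 bins
per chromosome.

Integer calls are `round(ploidy × segment mean ratio)` clamped at 0
(round-half-up, to avoid banker's rounding artifacts at `.5` boundaries).
This assumes the genome-wide mean CN is close to the ploidy; the default
simulated truth balances gains and losses accordingly, and an optional
ploidy-scale grid search (1.5–4.0 in steps of 0.05, minimizing distance of
scaled segment means to integers) is provided for strongly aneuploid
genomes but off by default for determinism. Concordance between profiles
is Pearson r on per-bin integer CN (ratios optional). Driver annotation
assigns each gene its maximal-overlap segment (ties to the higher CN),
reports only genes touching a non-neutral segment, and flags
boundary-spanning genes.

## Problem sizes and determinism

Every generator and every training routine is bit-reproducible under a
fixed seed; the acceptance script derives all its seeds from `--seed` via
`numpy.random.SeedSequence`. The package's standard experiment sizes are:
classifier protocol n = 4000 cells; limit-of-detection runs of 20
replicates × 20 fields × 500 leukocyte-like cells (850×850 px at
0.8 µm/px, one tumor-like cell per replicate); CNA recovery at 270 bins
over 20 seeds. These sizes make each experiment a few minutes on one CPU
while leaving the statistical conclusions (perfect separation, exact
single-cell detection, ≥95% bin recovery) comfortably away from their
thresholds.

## Known limitations

- The image model is blob-based; no PSF, spectral overlap or focus model.
  Real-data performance claims cannot be made from these tests.
- The debris filter and gate folds are placeholders tuned to the synthetic
  populations' scales, not to any instrument.
- The CNA caller targets near-diploid genomes by default; whole-genome
  duplications need the ploidy grid search and an informative prior the
  package does not provide.
- The combined count + serum-marker logistic score is a reconstruction:
  its coefficients are refit per cohort and its discrimination is
  cohort-dependent.
- Binary segmentation with the carve-out test is not an exact optimal
  partitioning; equivalence to established callers is asserted only
  through simulation recovery, never against their outputs.
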