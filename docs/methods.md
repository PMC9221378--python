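# Methods

`octraman` implements a multimodal classification pipeline for benign
versus malignant skin/subcutaneous tumors, combining texture statistics
from OCT B-scans with band-integrated features from Raman spectra, and
evaluating the combination by linear discriminant analysis under
leave-one-out cross-validation. Because the ex vivo datasets this kind
of study rests on are not publicly deposited, the package ships a
synthetic generator that emulates the relevant statistical structure of
the four tissue classes (skin, lipoma, mast cell tumor, soft tissue
sarcoma); every stage of the pipeline is exercised and tested end to
end against that generator.

## OCT processing

**Mask construction.** A B-scan (row 0 = top/background side, 8-bit
grayscale) is reduced to a binary tissue-inclusion mask in three fixed
stages:

1. *Threshold.* Default is Otsu's method on the image histogram, with a
   fixed-level override (`MaskConfig(method="fixed", level=...)`). The
   mask rule is `pixel >= level`; Otsu's `pixel > t` convention is
   converted by taking the smallest stored intensity above `t`. The
   threshold source (Otsu) is a design choice: it is automated,
   reproducible and robust to overall gain differences.
2. *Void filling.* Zero regions not 4-connected to the border
   background are set to 1, so low-reflectance voids inside tissue
   (e.g. adipocyte lumina in lipomas) are analyzed as part of the
   tissue structure. 4-connectivity prevents the background from
   leaking diagonally through one-pixel tissue walls. The operation is
   monotone (never removes mask pixels) and idempotent.
3. *Saturation-line removal.* The top `n_top_rows` rows (default 15)
   image only background; summing them per column (S = J·B with J a
   row of ones) flags every column touched by a saturation artifact,
   and those columns are zeroed over the full mask height. Saturation
   lines appear as broken, patchy bright columns, which is why the
   detection integrates 15 rows instead of inspecting one.

The stage order is normative: filling before line removal matters,
because removing a column first can open an interior void to the
background so it would never be filled (this is tested on a crafted
case). Manual mask inspection is replaced by an automated QC record
per image (masked fraction, number of removed columns).

**Scanning-window features.** A 15 × 15 px window (≈53 × 53 µm² at the
nominal 3.5 µm pixel pitch) slides with stride 1. A position is
admitted only if *all* 225 pixels are masked — a deliberate resolution
of an ambiguity (full coverage vs. center coverage): mixed
tissue/background windows would contaminate the statistics. Each
admitted window yields mean µ, population standard deviation σ
(divisor n, fixed by convention), intensity range max−min, and
CV = σ/µ (defined 0 when µ = 0, which otherwise has no defined value).
The four per-image distributions are summarized by mean, standard
deviation and median (numpy's midpoint convention for even lengths),
giving 12 features per image (`m_mu … md_cv`), which are averaged over
a sample's images. Features are computed on raw stored intensities; no
rescaling or cross-device normalization is attempted.

The implementation computes all windows via moving-average filters
(intensities centered on the global mean first, to avoid cancellation
in E[x²]−E[x]²) and is verified against a naive per-position oracle to
1e-8.

## Raman processing

Spectra are linearly resampled onto the canonical grid
920–2070 cm⁻¹ at 1 cm⁻¹ spacing before any feature computation.

**Baseline.** Autofluorescence is removed by iterative modified
polynomial fitting, default order 7 (orders 7–9 supported): fit a
Chebyshev-parameterized polynomial, clamp intensities exceeding
`fit + std(residual)` down to that envelope, refit, stop when the fit
moves less than `tol = 1e-6 · max(intensity)` or after 100 iterations.
The noise-aware clamp (I-ModPoly) is essential: clamping to the bare
fit ratchets the baseline into the noise floor and biases recovered
peak areas by several percent, while the noise-aware rule recovers
synthetic peak areas to <1% with noise at 1% of peak height. The
output is clipped at zero. The procedure is positively homogeneous, so
a global intensity gain passes through the baseline step unchanged in
relative terms.

**Normalization.** Spectra are divided by the maximum intensity within
1425–1460 cm⁻¹. This window covers both the ~1437 cm⁻¹ CH₂ lipid band
(lipid-dominated tissue) and the ~1446–1448 cm⁻¹ protein CH₂/CH₃ band
(protein-dominated tissue), so the anchor selects itself and no class
label is needed at prediction time — a deliberate deviation from
normalizing by a class-specific peak, which would leak the label the
classifier is supposed to predict.

**Band parameters.** p1–p7 are arithmetic means of the normalized
intensity over seven fixed bands (endpoints inclusive): 925–970,
1060–1160, 1180–1280, 1310–1380, 1451–1509, 1845–1880 and
2050–2080 cm⁻¹. p8 is the mean *unnormalized* intensity over the full
grid, computed on the baseline-subtracted spectrum so it reflects
Raman signal strength rather than fluorescence. p1–p7 are invariant to
a global gain; p8 scales with it. Per-sample feature vectors are the
average over a sample's spectra, matching the per-sample
cross-validation unit.

## Classification and statistics

Per-sample feature matrices (12 OCT, 8 Raman, or the combined 20) are
z-scored per feature and classified by LDA with equal class priors
(class frequencies in such studies reflect collection, not
prevalence), projecting onto n_classes − 1 discriminant axes.
Standardization is computed inside each training fold. If the
within-class scatter is singular the degenerate features are named in
a warning and a small shrinkage ridge (1e-3) is applied.
Label-to-integer encoding follows the fixed canonical order (skin,
lipoma, MCT, STS), which also makes prediction tie-breaks
deterministic.

Performance is measured by leave-one-out cross-validation over
samples: each sample is predicted by a model fit on all others
(held-out prediction — the only statistically defensible reading).
Reported LD coordinates come from the full-data fit and are for
plotting only; they are never used for the cross-validated metrics.
Besides one-vs-rest sensitivity/specificity per class, MCT and STS are
pooled into a "malignant" class in both truth and prediction before
re-scoring: confusing the two malignant types with each other is not a
clinically relevant error. Coarsening can only convert errors into
hits, so merged accuracy ≥ 4-class accuracy (tested as a property).

Feature significance between class pairs uses the unpaired two-sided
Mann–Whitney U test: exact null distribution when both groups have ≤8
tie-free observations, tie-corrected normal approximation otherwise
(verified against exhaustive permutation enumeration for all group
sizes ≤7). Stars follow *** p<0.001, ** p<0.01, * p<0.05, NS. No
multiple-testing correction is applied, deliberately mirroring common
practice in this literature; the family-wise error across 7 band
comparisons is therefore ≈25–30% under the null, which matters when
interpreting a single seed's NS pattern.

## Synthetic data generator

The generator is first-class, tested code. Defaults define the study
conditions used by the test suite and the acceptance script:
10 samples/class, 4 B-scans (128 × 192 px, 8-bit) and 8 spectra per
sample (real studies acquire up to 14 images and 8–12 spectra).

**Images.** Background rows at intensity ≈5 (σ 2); a tissue block from
a random surface row (16–28, always below the 15-row saturation
scan) to the bottom; per-class Gaussian texture. Lipomas get dark
disks (radius 4 px, ~70 per 10⁴ tissue px) stamped at background
level — the honeycomb; skin gets a 3-row bright surface line (~230),
the stratum corneum; MCT/STS are bright and homogeneous (means
160/152, σ 16/19) and deliberately close, so the 4-class LDA partially
confuses exactly the pair that is hardest in practice. With
probability 0.15 a saturation artifact is stamped: a 1–3 px wide
column at 255 with random vertical gaps, guaranteed to touch the top
15 rows. The generator keeps a ground-truth tissue mask (tissue block
minus saturated columns, voids included) used to validate the mask
pipeline (≥95% pixel agreement required on artifact-free images).
8-bit depth is a convention choice; intensities are stationary within
the tissue block (no depth attenuation, no speckle physics).

**Spectra.** Sum of class-specific Gaussian bands (σ 6 cm⁻¹) scaled by
a class gain, plus a smooth quadratic fluorescence baseline
(~300 counts, not gain-scaled) and additive Gaussian noise (σ 3
counts). Lipoma is lipid-dominated (1076, 1300, 1437, 1656 cm⁻¹);
skin carries the protein/collagen fingerprint (935, 1000, 1031, 1127,
1241, 1343, 1448, 1544, 1586, 1656, plus 1885 and 2067); MCT and STS
share one spectral model — the skin set with elevated 1241
(nucleic acids) and 1480 bands and a reduced 1437 lipid shoulder — so
their band parameters are exchangeable by construction and the
expected Mann–Whitney outcome between them is NS on p1–p8. Making the
two malignant classes differ in gain instead was rejected: residual
baseline after polynomial fitting, divided by a gain-dependent
normalization anchor, produces a systematic band offset between the
classes that real within-class variability would swamp but a clean
generator does not.

**Variability.** Between-sample random effects: tissue mean jitter
(σ 8 counts), relative gain jitter (σ 0.12), relative band-height
jitter (σ 0.10), and 8 sample-specific weak "nuisance" Raman bands
(exponential heights, mean 10 counts; widths 15–40 cm⁻¹) modelling
biochemical heterogeneity — these set the within-class band variance
that makes true contrasts significant and null contrasts insignificant
at n = 10/class. Per-spectrum gain jitter (σ 0.08) adds within-sample
variation. Everything is a pure function of the configuration
including its seed; two runs with the same seed produce byte-identical
manifests and arrays.

**What the generator does not model**, hence what passing tests do not
show about real data: OCT speckle statistics and depth-dependent
attenuation, instrument response and wavelength calibration, cosmic
rays, formalin-fixation effects, and any systematic site/device batch
structure. Synthetic class separations are cleaner than real ones:
LOOCV metrics near 1.0 here say the pipeline works, not that real
tissue is this easy.

A `scale_separation(cfg, factor)` helper interpolates class parameters
toward their cross-class means; downstream LOOCV accuracy increases
monotonically in the factor (tested at two settings × 20 repetitions),
confirming the pipeline transduces class contrast rather than noise.

## Problem sizes and numerics

Default images are 128 × 192 px (≈20k windows/image); the full study is
160 images + 320 spectra and runs in a few seconds. The multimodal-
advantage property is evaluated over 25 seeded repetitions. Window
statistics use float64 with mean-centering before the variance filter;
variances are clipped at 0 before the square root; CV uses a 1e-12
guard on the mean. Chebyshev bases are used for all polynomial fits.
Degenerate inputs are handled explicitly: empty windows reject,
oversized windows yield an empty (not fatal) distribution, unmaskable
images raise a labeled featurization error, spectra with a non-positive
anchor maximum raise a labeled normalization error, and samples whose
files fail to read or process are dropped with a warning (the run
aborts if more than 20% drop).

## Known limitations

- Acceptance of the NS pattern between MCT and STS on a single seed is
  a 7-test family without correction; ~1 in 4 seeds will show one
  spurious rejection even though the null is exact.
- The label-free normalization anchor assumes the 1425–1460 cm⁻¹
  region contains the tallest local band of either lipid or protein
  type; exotic spectra violating this would be mis-scaled, not
  rejected.
- p8 depends on acquisition gain; it is only meaningful when
  acquisition settings are constant across samples, as they are in the
  generator.
- LDA assumes shared within-class covariance; with 20 features and few
  samples per class the shrinkage fallback activates on small studies
  (it is logged when it does).
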