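# Methods

This note documents the models implemented by `hypoxiaquant`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical decisions a maintainer would want written down.

## PET hypoxia scoring

SUV is computed as activity concentration divided by injected dose per body
weight, with tissue density taken as 1 g/mL so kBq/mL over kBq/g is
dimensionless. The injected dose must be decay-corrected to scan time by
the caller; acquisition metadata handling is deliberately outside the
library. TBR divides every voxel SUV by the arithmetic mean SUV over the
aorta VOI (arithmetic, not median — the blood-pool background is a plain
average).

TBRpeak averages the TBRmax voxel with its 26-connected 3D neighbors
restricted to the tumor VOI: at a VOI border only in-VOI members enter the
mean, and the center voxel is always a member, so a single-voxel VOI has
TBRpeak = TBRmax. When several voxels tie for TBRmax the neighborhood mean
is evaluated at every argmax voxel and the largest is reported — a
deterministic, traversal-order-independent rule. Neighborhood means use
exact (`fsum`) summation so equality checks against enumeration are
well-defined. By construction TBRpeak ≤ TBRmax (a mean of a set containing
the maximum).

Hypoxic volume counts tumor voxels with TBR strictly above the threshold
(default 1.4) times the voxel volume (product of the three spacings;
anisotropic grids supported); tumors are classified hypoxic when HV is
strictly above 1.0 mL. Both inequalities are strict, so a tumor at exactly
1.000 mL is *not* hypoxic. All TBR-derived metrics are invariant to a
global rescaling of SUV.

## IHC densitometry

Optical density is OD_c = −log₁₀((I_c + ε)/I₀) with ε = 10⁻⁶ guarding the
logarithm at zero intensity and I₀ = 255 by default. Stain unmixing solves
OD = concentrations · M for the 3×3 unit-row stain matrix M; the default is
the standard published hematoxylin/DAB optical-density triplet with the
residual row closing the basis, and negative concentrations are clipped to
zero (physical non-negativity). Measured stain vectors can be substituted.

The DAB threshold is Kapur's maximum-entropy criterion: a 256-bin histogram
over the observed ROI range (not a fixed OD domain — the observed range
adapts to stain strength), and the bin edge maximizing the sum of Shannon
entropies of the two renormalized sub-histograms. Candidates leaving either
side empty are skipped; ties resolve to the lowest threshold, making the
two-spike case deterministic. Constant input has no threshold and raises.

Counting is connected-component labeling (8-connectivity) of supra-threshold
ROI pixels with physical area gating, defaults 10–500 µm² — wide enough for
nuclei of 2.5–4.5 µm semi-axes, tight enough to drop single-pixel noise and
fused clumps. No watershed or instance segmentation is attempted: the
procedure is thresholding followed by object counting, and the phantom
generator enforces non-overlapping nuclei precisely so that component count
equals nucleus count and the counting logic is tested in isolation. Density
is count over ROI area, ROI area being pixel count × (pixel edge)².

## Assay normalization

Cytokine-array spots normalize as (spot − mean neg ctrl) / (mean pos ctrl −
mean neg ctrl), clipped below at zero; this cancels any common affine
gain/offset of the densitometry. A membrane whose positive control does not
exceed its negative control is rejected as unusable. Fold induction is the
ratio of normalized HPS to NPS means with a one-tailed pooled-variance
(classic unpaired Student) t-test, alternative HPS > NPS. The candidate
filter retains analytes with p < α (0.05), fold > 1, molecular weight in
the inclusive 30–100 kDa window established by size exclusion, and
confirmation in an independent mRNA (qPCR) comparison; it is monotone in α
and in the window.

ΔΔCt: ΔCt = Ct_target − Ct_reference per sample, ΔΔCt = mean ΔCt(treated) −
mean ΔCt(control), fold = 2^−ΔΔCt. Flow summary is delta gMFI =
exp(mean log) of the stained tube minus the isotype tube; subtraction (not
ratio) was chosen to match the "delta" naming convention — genuinely
ambiguous, and configurable in principle by composing the gMFI calls.
Migration correction subtracts the no-attractant curve pointwise on an
aligned time grid.

## Expression scores

Geneset Z-score: each gene standardized across samples with population SD
(divisor n, the cohort-standardization convention of genomics
visualization platforms; `ddof` is exposed), score = mean standardized
value over set members present in the matrix. Constant genes are dropped
with a warning rather than imputed. The score is invariant to per-gene
affine transforms, and the cohort mean score is 0 when all genes are
present in all samples. Median dichotomization labels value > median as
high, with ties at the median assigned low — deterministic and conservative
for "high-expression" claims.

## Survival statistics

Kaplan–Meier wraps the standard product-limit estimator; median survival is
the smallest time with S(t) ≤ 0.5, reported as "not reached" (None) when
the curve stays above 0.5. The two-group log-rank statistic is
(ΣO − ΣE)²/ΣV with hypergeometric variance at each distinct event time,
referred to χ²(1); it is implemented vectorized in numpy because the
cut-point scan evaluates it at every candidate split, and is cross-checked
against an independent survival library in the test suite.

The maximally selected cut-point scan takes candidates at midpoints between
consecutive sorted unique biomarker values, keeps only splits leaving both
groups at least `min_group_fraction` (default 10%) of the cohort, and
minimizes the log-rank p. Because a threshold anywhere in the gap between
two adjacent data values induces the same partition, the scan reports the
*interval* of thresholds attaining the minimal p (the union of those gaps
over tied candidates) together with a representative cut-off — the natural
counterpart of reporting a best cut-off with a bracketing range. No
multiple-testing correction is applied to the scanned p, which is flagged
exploratory; correcting or validating it on an independent cohort is out of
scope.

Mann–Whitney uses exact enumeration p-values for untied samples with
n₁+n₂ ≤ 12 and the normal approximation with tie correction otherwise;
Spearman is Pearson on average ranks with the t-approximation p.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of their specs (same seed → bit-identical
output) and store ground truth sufficient to predict every downstream
metric without running the pipeline.

**PET phantom** — spheres on a 64³ grid at 2 mm isotropic spacing: tumor
(radius 20 mm, SUV 1.2), concentric hypoxic core (radius 9 mm, SUV 2.0),
disjoint aorta (radius 8 mm, SUV 1.0) over background SUV 0.5, additive
Gaussian noise (default SD 0.05 SUV). The SUV levels put the bulk tumor at
TBR 1.2 (below the 1.4 threshold) and the core at TBR 2.0 (above), the
configuration the hypoxic-volume logic must resolve. Voxel membership is by
voxel-center-inside-sphere, which makes the voxelized ground-truth volume
exact bookkeeping; the analytic 4/3·πr³ volume differs from it by at most
the surface-voxel discretization. Not emulated: scanner point-spread and
partial-volume effects, Poisson count noise, reconstruction artifacts — so
recovery results bound discretization behavior, not scanner physics.

**IHC phantom** — 600×600 px at 0.5 µm/px (0.09 mm²), elliptical nuclei
with semi-axes 2.5–4.5 µm and random orientation, placed by rejection
sampling with a 2 px margin so rasterized nuclei never touch (8-connected
components = nuclei). DAB-positive nuclei carry DAB OD 0.8 plus 40% of the
hematoxylin counterstain (OD 0.6); negatives carry hematoxylin only.
Intensities follow I = I₀·10^−OD per channel with optional Gaussian noise
before 8-bit quantization. The hematoxylin crosstalk leaking into the
deconvolved DAB channel (quantization-limited, ~0.02 OD) is exactly the
nuisance the maximum-entropy threshold must clear. Not emulated: chromatin
texture, overlapping/fused nuclei, stain gradients, tissue folds — passing
tests demonstrate correct thresholding and counting, not robustness to
segmentation-grade confluence.

**Survival cohort** — exponential event times with hazard switching at the
true biomarker cut-off (closed-form group medians ln2/λ); defaults mirror
a hypoxia-imaging cohort with medians 21 vs 9 months, cut-off 1.6 on a
TBRmax-like N(1.6, 0.3) biomarker, 20% censoring, 60-month administrative
follow-up. "Fraction censored" is implemented as independent Bernoulli
dropout with censor time uniform on (0, event time) plus truncation at end
of follow-up, so the realized censored fraction tracks the parameter
regardless of hazards. A `("levels", …)` biomarker option yields a
noise-free ordinal biomarker (each subject exactly on a reading-grid
level); the cut-point recovery study uses 6 levels (1.1–2.1, step 0.2)
with the cut-off mid-gap. With a *continuous* biomarker the minimal-p
partition typically sits 1–3 subjects off the true boundary, so the exact
minimal-p interval misses the true cut-off in most runs — the well-known
imprecision of maximally selected cut-points, and the reason validation
cohorts are required; the recovery guarantee tested here applies to
separated or ordinal biomarkers only.

**Array membranes** — replicate spots per analyte, shared positive/negative
controls across the NPS/HPS pair, HPS spot mean = programmed fold × NPS
spot mean before noise. The default negative-control level of zero makes
control normalization preserve programmed folds exactly, so round-trip
tests isolate the quantification arithmetic.

## Validation problem sizes

The acceptance script and end-to-end tests use: 100 random 5×5×5 TBR
grids (TBRpeak enumeration), 5 hypoxic radii (HV recovery), 200 random
histograms (Kapur brute force), 4 slides per noise level spanning
100–2000 nuclei/mm², 1000 null cohorts of n=100 (log-rank calibration),
200 cohorts of n=150 at hazard ratio 3 with 20% censoring (cut-point
coverage), uncensored n=500 cohorts (KM median vs ln2/λ), and full
enumeration of all Mann–Whitney splits with n₁+n₂ ≤ 10. These sizes give
each Monte-Carlo estimate a standard error comfortably inside its test
tolerance while keeping the whole validation run under a minute.

## Known limitations

- No partial-volume or point-spread modeling: clinical TBRpeak on small
  lesions will behave differently than on phantoms.
- The nuclei counter is not an instance segmenter; confluent staining
  undercounts (components above the area gate are discarded, not split).
- The scan-minimized log-rank p is biased low by construction; the package
  reports it as exploratory and implements no correction.
- The exact Mann–Whitney path requires untied data; ties always route to
  the corrected normal approximation, which is approximate for tiny n.
- Geneset scoring assumes a single cohort matrix; no cross-cohort batch
  handling is provided.
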