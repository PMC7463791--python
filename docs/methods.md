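# Methods

This note documents the statistical procedures, the synthetic-data model
the package is validated on, the default parameter choices and their
rationale, and the known limitations. All empirical statements below are
properties the test suite or the acceptance script computes.

## Data model

A dataset is a collection of per-pixel spectra (`Spectrum`: strictly
increasing m/z axis in Da, non-negative intensities, 1-based (x, y) grid
coordinate). Both continuous-mode imzML (one shared axis) and
processed-mode (per-pixel axes) map onto this model; any resampling to a
common axis happens downstream, in the mean-spectrum step. Regions of
interest (`ROISet`) partition pixels into named tissue cores with patient
and outcome-group labels (`+RD`, `-RD`) plus off-tissue `control` areas;
a pixel belongs to at most one ROI.

## Preprocessing

**Baseline removal** (default width 20 samples) is a moving minimum
followed by a moving average, both with the same window; the estimate is
subtracted and negative residuals are clipped to zero. This is a standard
morphological ("top-hat"-like) realization of convolution baseline removal:
the minimum filter tracks the slowly varying floor, the averaging removes
its staircase artefacts. Two consequences are worth knowing: peaks much
narrower than the window pass essentially unchanged (height preserved
within ~5 % in the tests), and on a sloped background a small constant
offset of about *slope × window/2* survives — local peak areas are
unaffected, but whole-axis integrals are not. Window widths are counted in
samples and any width ≥ 3 is accepted (the default, 20, is even; the
filters use the standard centering convention for even windows).

**TIC normalization** divides each spectrum by its total ion count, so
intensities sum to one. It is idempotent and scale-invariant; all-zero
spectra are rejected (or, inside `preprocess_dataset`, left unnormalized so
off-tissue control pixels survive).

## Mean spectrum and OMP peak picking

The mean spectrum is the arithmetic mean of the selected (tissue) spectra
after linear interpolation onto a uniform axis. The default axis step for
real data is 0.05 Da; the synthetic pipeline uses the acquisition's native
spacing (0.1 Da) because resampling a discrete axis onto a finer grid
broadens peaks slightly and the residual shape error shows up as spurious
low-amplitude "shoulder" atoms in the sparse fit.

Peak picking is orthogonal matching pursuit against a dictionary of
unit-norm Gaussian templates centred at every axis point (template σ
configurable; default two axis steps, and the simulated peak width in the
synthetic pipeline). Per iteration: the template most correlated with the
residual is selected (one Gaussian-filter pass, O(n)), the coefficients of
all selected templates are re-fit by least squares via an incrementally
grown Gram system, and the residual is updated — so the residual norm is
non-increasing by construction, which the code asserts. Selection stops at
`max_peaks` (default 300) or when the best residual correlation falls below
the threshold. The threshold is in residual-correlation units and, when not
given, is estimated as five times the MAD-based robust scale of the
correlation signal. For noiseless inputs of k ≤ max_peaks separated
Gaussians the picker returns exactly k centers, each within one axis step
of truth (tested for k ≤ 5).

The feature matrix assigns each spectrum the mean intensity over the closed
interval ±0.156 Da (default) around each picked centroid. Centroids whose
bins would overlap are merged (with a warning) to the cluster mean; empty
intervals yield 0 and a logged warning; control ROIs are excluded.

## pLSA

The non-negative feature matrix (TIC-normalized intensities × 10⁴, used
directly as continuous EM weights — no rounding to integer counts) is
decomposed with the aspect model P(spot, bin) = Σ_z P(z) P(spot|z) P(bin|z),
default K = 5. Initialization is deterministic: component profiles are
seeded from the K mutually most dissimilar spectra, chosen by greedy
max-min cosine distance starting from the highest-total spectrum; P(spot|z)
and P(z) start uniform. Repeated fits of the same matrix are therefore
bit-identical. The EM log-likelihood is non-decreasing (asserted per fit in
the tests) and every probability table row-normalizes to 1 within 1e-8.
Spot scores are the posteriors P(z|spot).

The outlier-patient screen flags any patient whose spots' dominant
component differs from the majority component of *both* outcome groups —
an automatic, conservative reading of "this patient's spectra look like
neither group", intended to prompt histological review, never to diagnose.

Spatial segmentation uses bisecting k-means (largest-inertia cluster split
first) on rows scaled to unit length, i.e. cosine geometry; the splitting
is delegated to scikit-learn's `BisectingKMeans` with a fixed seed.

## Marker screen

Groups are first balanced by random subsampling (default 1500 spectra per
group, seeded; a smaller group is kept whole). Per bin:

- **AUC** — the probability, with half-credit for ties, that a random +RD
  intensity exceeds a random −RD one; computed from rank sums
  (Mann-Whitney U / n₁n₂), exactly equal to the brute-force pair count.
  AUC > 0.5 always means higher in +RD.
- **Wilcoxon rank-sum p** (two-sided) for bins beyond the AUC cutoffs.
  Small tie-free samples (both n < 20) use exact enumeration. The
  large-sample path uses a continuity-corrected normal refined with a
  one-term Edgeworth correction: the rank sum is the total of a simple
  random sample drawn without replacement from the pooled ranks, so its
  exact variance and fourth central moment follow from population power
  sums (its skewness is exactly zero by the symmetry of midranks), and the
  kurtosis term sharpens mid-range p-values by roughly an order of
  magnitude (agreement with exact enumeration ~3e-4 at n = 15, vs ~1e-2
  for the plain normal). Tied samples fall back to the tie-corrected
  normal approximation.
- **Delta intensity** — mean(+RD) / (mean(+RD) + mean(−RD)), a symmetric
  0–1 share with 0.5 = no difference, so cutoffs > 0.7 / < 0.3 correspond
  to a > 2.33-fold change. Undefined (NaN, marker fails) when both means
  are zero.

A bin passes only the full chain; every bin is reported with its statistics
and flag, sorted by |AUC − 0.5|. Default cutoffs are AUC > 0.65 / < 0.35,
p < 0.001, delta > 0.7 / < 0.3 (`PRESETS["methods"]`). A second preset,
`PRESETS["results2020"]` (AUC > 0.6 / < 0.4, p < 0.01, no delta filter),
reflects looser summary cutoffs that circulate for the same workflow; the
two chains genuinely disagree and are both exposed rather than reconciled.
No multiple-testing correction is applied by default — the screen is a
candidate generator, not a confirmatory test — but a Benjamini-Hochberg
option (`fdr=True`) exists.

## Annotation

Observed centroids are treated as singly-protonated: Mr = m/z − carrier.
The carrier defaults to **1.0079 Da** (the atomic mass of hydrogen) because
that value reproduces the published worked example's printed centroid/Mr
pairs exactly; the physically stricter proton mass (1.00728 Da) is one
config field away. Each Mr is matched to the reference peptide of minimal
|Δ|, ties broken by higher search-engine score then lower mass (so results
are independent of reference-list order), and accepted iff Δ < 0.9 Da, the
conventional bound for identifying MALDI-imaging peptides against an
LC-MS/MS list. Reference peptides matched by several imaging m/z values are
flagged `shared`.

The multi-peptide rule (`min_peptides_per_protein=2`) demotes accepted
annotations whose protein has only one accepted peptide. The default is 1:
the published signature table itself retains nine single-peptide proteins,
and reproducing that table takes precedence over the stricter prose rule;
the strict mode is available for users who want it.

## Ordination

Samples (patients by default, cores via `by="roi"`) are summarized by mean
spot intensity per passed marker bin. PCA is computed by SVD of the
centered (and by default unit-scaled, i.e. correlation-mode) table —
marker intensities span scales, so correlation PCA is the default; both
flags are exposed. Component signs follow a fixed convention (the
largest-magnitude loading of each component is positive), making scores
reproducible up to that convention under sample permutation. Explained
variances are non-negative, non-increasing and sum to the analyzed table's
total variance.

Marker correlation groups use single-linkage on |r| ≥ threshold; each
member carries the sign of its correlation path to the group seed, so
markers tracking the opposite trend of their group are reported negative.
`spatial_cv` exposes a per-marker coefficient of variation across all
tissue spots, the quantity relevant to the contamination argument
(contaminants spread evenly over a slide; biology tracks tissue).

## Synthetic data

The generator emulates the tissue-microarray study design the workflow
targets: two groups of 4 patients, 2 cores per patient, 12 × 12 spots per
core at a 50 µm raster (~2300 tissue spectra), one off-tissue control core,
m/z 800–3200 sampled at 0.1 Da, 200 Gaussian peaks (σ 0.25 Da) of which 20
are discriminative. Peaks sit in evenly spaced slots with random jitter
(guaranteeing separation); per-peak base abundances are log-normal
(σ_log = 0.8) to mimic the heavy-tailed dynamic range of MALDI intensities.
Per spot, abundances are multiplied by unit-mean log-normal factors with
coefficient of variation `abundance_cv` (0.4), the whole spectrum by a
unit-mean log-normal TIC factor with CV `tic_cv` (0.25); a smooth sinusoid
baseline (amplitude 2, random phase per spot) and truncated Gaussian noise
(σ 0.5) are added. Discriminative peaks are multiplied in +RD spots by the
effect size (4.0) for "up" peaks and its reciprocal for "down" peaks,
alternating. All randomness flows from one seed; identical configs give
bit-identical datasets.

The simulated LC-MS/MS reference list contains one entry per true peak at
neutral mass peak − carrier + N(0, jitter²) (default jitter 0.05 Da,
roughly the mass accuracy gap between a TOF imaging measurement and an
LC-MS/MS identification), with two peptides assigned per simulated protein
and a configurable number of decoy entries (default 50) at uniform random
masses with `DECOY` accessions.

What the generator deliberately does **not** model: isotope envelopes and
charge states, matrix-cluster chemistry, detector saturation, spatial
intratumor gradients (spots are i.i.d. within a core), and patient-level
random effects beyond the group effect. Passing tests therefore demonstrate
the correctness and statistical calibration of the pipeline under this
model — type-I control, power, decoy discrimination — not performance on
real tissue, where between-patient heterogeneity and correlated spatial
structure will reduce effective sample sizes.

## Validation summary (what the tests compute)

- Rank-based AUC equals exhaustive pair counting on all small samples;
  AUC(a,b) + AUC(b,a) = 1 exactly; invariance under monotone transforms.
- Wilcoxon large-sample p within 0.01 of exact enumeration at n = 15.
- OMP residual monotonicity and exact recovery of ≤ 5 noiseless peaks.
- pLSA log-likelihood monotonicity and row normalization over 50 random
  matrices; on the default simulated study at least one component separates
  the outcome groups with AUC ≥ 0.9.
- Marker screen on the default study: ≤ 0.5 % of bins pass when the group
  effect is absent; ≥ 90 % of the 20 spiked markers are recovered at
  effect size 4; the end-to-end run accepts no decoy annotation at 0.05 Da
  reference jitter.
- The published 18-row annotation example reproduces exactly (neutral
  masses to the printed four decimals, mass differences within 1.5e-4 Da).

Problem sizes used by the test suite (full run ~25 s on one CPU): the
default simulated study (~2450 spectra including controls) once as a shared
fixture, one additional no-effect study for the type-I check, and small
constructed matrices everywhere else.

## Known limitations

- The OMP threshold's score scale is implementation-specific (residual
  correlation of unit-norm templates); thresholds from other software do
  not transfer.
- The baseline estimator's offset on sloped backgrounds (above) makes
  whole-spectrum integrals after correction slightly conservative.
- pLSA's EM converges to a local optimum; the deterministic seeding makes
  results reproducible, not globally optimal.
- With heavily tied small samples the Wilcoxon p falls back to the normal
  approximation, whose error can reach a few percent there.
- `balanced_subsample` draws one subsample per screen; repeating the screen
  with different seeds and intersecting the passed sets is recommended
  practice on real data.
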