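# Methods

## Scope and model

`fcdev` implements an edge-level growth analysis of functional
connectivity (FC) for accelerated-longitudinal designs: a cohort spans
the age range cross-sectionally (here 14–26 y) while each subject
contributes 1–3 scans, so age-related change is identified jointly from
between- and within-subject contrasts. The repeated-measures structure is
absorbed by a subject random intercept; random slopes, nonlinear age
terms and heteroscedastic residuals are deliberately out of scope (the
target design rarely identifies them per edge).

Per outcome series y (an edge's FC, a region's strength, or the global
mean) the model is

    y_is = β0 + β_age (age_is − b) + β_sex sex_i + β_site site_i + u_i + ε_is,
    u_i ~ N(0, σ²_u),  ε_is ~ N(0, σ²_e)

with baseline age b = 14 (configurable). Reported summaries: FC14 = the
prediction at age b with sex and site at their sample-frequency-weighted
means (a population-average baseline; the reference coding is otherwise
arbitrary) and ΔFC14−26 = 12 · β_age, the total change over the 12-year
window. The maturational index is scale-invariant, so using the annual
slope instead of the 12-year change leaves it unchanged (tested).

## REML estimation

Estimation is restricted maximum likelihood, profiled to one dimension.
For a fixed variance ratio λ = σ²_u/σ²_e the marginal covariance is
σ²_e(I + λZZ') with Z the subject-indicator matrix; the per-subject
Woodbury identity reduces every GLS quantity to per-subject sums, so one
REML evaluation costs O(n_subjects · p²) and fitting tens of thousands of
edges is cheap. λ is found by golden-section search on [0, 10³] with
tolerance 1e-8. When the optimum hits the λ = 0 boundary, or no subject
has repeated scans, the fit reduces exactly to OLS and is flagged
`method = "ols"`. Slope inference uses the normal approximation
z = β̂_age/SE; degrees-of-freedom conventions for mixed models are not
standardised and the per-edge n here is large relative to p. A λ at which
the GLS normal matrix is numerically singular (between-subject contrasts
vanishing) is treated as infeasible (+∞ criterion), not as an error.

Fixed effects at the fitted variance components are verified against a
direct matrix-inversion GLS oracle to 1e-6, and against
`statsmodels.MixedLM` (REML) in tests; statsmodels is the cross-check,
never the implementation.

## Motion QC

FD follows the translation-plus-rotation convention: absolute
volume-to-volume parameter differences, rotations converted to arc length
on a 50 mm sphere (the head-radius is a parameter). Exclusion thresholds
default to mean FD > 0.3 mm or max FD > 1.3 mm; the low-motion subset
rule looks for 100 consecutive volumes with FD < 0.2 mm. Low-signal
regions are flagged by a z-score of mean intensity across regions within
scan below −1.96 in at least one scan; the z uses the population (ddof=0)
standard deviation — with a sample sd, |z| is bounded by
(n−1)/√n and small region counts could never cross the threshold. A
zero-variance scan contributes no exclusions (identical intensities carry
no evidence of regionally low signal).

QC-FC is the per-edge Pearson correlation of FC with mean FD across
scans; its distance dependence is the Spearman correlation of QC-FC with
inter-centroid distance across edges (rank-based for robustness to QC-FC
outliers). FD regression removes, per edge, the OLS component of FC on
mean FD, keeping the zero-motion intercept so baseline levels remain
interpretable; the operation is idempotent and leaves in-sample QC-FC at
exactly zero. Post-correction correlations are floating-point cancellation
dust with systematically structured signs, so correlations below 1e-8 are
reported as exactly 0 and an all-zero QC-FC vector has distance
dependence 0 by definition. Global signal regression (per-region
residualisation on the across-region mean series) is provided as the
alternative correction.

## Connectivity

Regional series are bandpassed with a shift-invariant (stationary)
Daubechies-4 wavelet decomposition, reflection-padded to the required
dyadic length; the retained detail levels are chosen so the union of
nominal dyadic bands [f_s/2^(j+1), f_s/2^j] covers 0.025–0.111 Hz — at
TR = 2.42 s that selects levels 2–3 (nominal 0.026–0.103 Hz; the printed
band does not fall exactly on dyadic boundaries, so the closest union is
used). FC is plain Pearson correlation; node strength is the mean raw
correlation (no Fisher transform) to each partner set, with
cortico-/subcortico- blocks (cc, cs, sc, ss) and the exact identity that
whole-brain strength is the partner-count-weighted average of the block
strengths. Edge datasets are stored edge-major over the canonical
upper-triangle ordering (i < j, row-major), with a lossless round trip to
per-scan matrices.

## Maturational index and spin inference

MI_i is the Spearman correlation of (FC14, ΔFC14−26) over region i's
incident edges (all 345 of them at study scale; `min_edges = 10` guards
toy inputs, and regions below it are marked indeterminate). Subsets
restrict to cortico-cortical or subcortico-subcortical edges for
sensitivity analyses. Modes: conservative (MI > 0) vs disruptive
(MI < 0); significance flags come from BH-FDR at α = 0.05 within each
inference family — cortical regions on spin p-values, subcortical on
parametric p-values (spins are a cortical-surface construct; subcortical
regions have no spherical coordinate and are flagged parametric-only).

Spin permutations: each spin draws a uniform random rotation (Gaussian
quaternion), applies it to the left hemisphere's spherical coordinates
and the x-mirrored rotation to the right, and reassigns regions to
rotated centroids by optimal bijective matching (Hungarian algorithm,
minimum total distance) within hemisphere. Optimal matching replaced a
greedy duplicate-resolution rule during development: greedy assignment
leaves a heavy tail of long reassignments that roughens spun maps, makes
the permutation null underdispersed, and inflates the empirical size of
the test well above nominal. Two-sided empirical p-values use the +1
correction, p = (1 + #{|null| ≥ |obs|}) / (n_spins + 1), so the floor is
1/(n_spins+1). For per-region MI the null spins the ΔFC14−26 partner map
against fixed FC14 (one of several defensible constructions; recorded in
output metadata); a spin that maps a partner onto the index region drops
that partner for that draw, since the self-edge has no Δ.

Half-split stability splits *subjects* (not scans) into disjoint halves,
reruns fit + MI per half, and records the Spearman correlation of the two
MI maps per split.

## Colocation

Continuous annotation maps are compared to the MI map by Spearman ρ on
the shared cortical mask, with the spin p from spinning the MI map, and
BH-FDR computed over exactly the comparisons retained in the battery
(default battery size 12; maps with < 10 shared regions are skipped and
the recorded battery size shrinks). Categorical profiles are descriptive
(per-class n, mean, median, quartiles, ordered by mean MI) with the
subcortex as an optional extra class; no per-class inferential test is
attached.

## Synthetic cohorts

The generator defines the study conditions; defaults were fixed once:

- **Design**: 150 subjects; scans-per-subject probabilities
  (0.45, 0.35, 0.20), giving a mean of 1.75 scans/subject — the emulated
  study's ratio of scans to subjects; baseline ages uniform over six
  strata spanning 14–26 y; follow-up gaps uniform on 0.5–2.5 y (the real
  inter-scan interval distribution is not published; the window is a
  stand-in exposed in config), truncated at 26.
- **Trajectories**: edge baselines B_e ~ N(0.25, 0.15²) (empirical FC is
  generally positive); slopes S_e = s₀(½(a_i + a_j)·z(B_e) + η_e) with
  coupling targets a_i (default ±0.6, alternating by bilateral pair so
  the planted map is hemispherically symmetric), z() edgewise
  standardisation, s₀ = 0.01 FC/y and η ~ N(0, 0.5²) in coupling units.
  Each edge averages its two endpoint couplings; the stored ground truth
  is the *realized* per-region Spearman of (B_e, S_e), recomputed exactly,
  not the target.
- **Noise**: subject random intercepts σ_u = 0.08 FC units; scan-level
  residual σ_e = 0.07 (≈ the Pearson sampling sd of FC estimated from
  ~260 volumes); sex and site effects 0.02.
- **Motion**: mean FD lognormal (median 0.12 mm, σ = 0.4), independent of
  age by default (a config switch adds an age slope for stress tests);
  FC contamination γ_e = γ₀ + γ_d·distance with γ₀ = 0.1 FC/mm and
  γ_d = 0.001 per mm, reproducing both the positive QC-FC and its
  distance dependence. Simulated FC is clipped to ±0.999.
- **Geometry**: per-hemisphere spherical coordinates are a quasi-uniform
  (Fibonacci) lattice covering the *full* sphere, mirrored to the right
  hemisphere — as in real spherical surface registration, which is what
  makes rotation-based nulls act on their own domain; volumetric
  centroids compress the azimuth onto a hemispheric half-shell of radius
  70 mm (subcortical nuclei sit in mirrored pairs in a central ball).
- **Annotation maps**: bilaterally symmetric Gaussian fields on the
  spherical sheet, kernel-smoothed white noise with length 25 mm and
  kernel rows normalised to unit variance (irregular centroid density
  otherwise imposes a variance profile shared across independent maps,
  which would invalidate spatial-null inference). A requested coupling c
  is a Spearman target: mixing uses the Gaussian-scale Pearson value
  2·sin(πc/6). One categorical map (k-means on centroids, k = 7) stands
  in for a cytoarchitectonic/functional atlas.

What the generator does *not* emulate: hemodynamics, physiological noise
spectra, multi-echo acquisition, scanner drift, non-linear trajectories,
spatially structured residual correlations between edges beyond the
shared subject intercept, and real atlases' irregular parcel sizes.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated generative model, not performance on real
data.

## Problem sizes

Test and acceptance runs use desk-scale cohorts chosen to keep full runs
fast while leaving the statistics well-identified: 40 regions (~780
edges) and ~260 scans for parameter recovery; 80 regions for the
motion-correction contrast (after exact FD regression the
distance-dependence statistic is computed on an exactly-zero QC-FC vector,
see above); 150 cortical parcels, 200 spins and 500 repetitions for spin
calibration; 60 parcels, 999 spins and 50 seeds for battery recovery. The
study-scale dimensionality (330 cortical + 16 subcortical regions, 59,685
edges) is exercised for construction and bookkeeping, not for repeated
simulation.

## Known limitations

- The spin test is exactly calibrated only in the infinite-resolution
  limit; at parcel level a small residual size inflation (<~1% absolute
  at the tested scales) remains because value reassignment on a finite
  lattice slightly roughens spun maps. This is intrinsic to
  rotation-permutation nulls on parcellated data.
- REML assumes a single scalar variance ratio per edge; edges whose fit
  fails are dropped from MI with a warning rather than imputed.
- The low-signal filter's z-score direction (across regions within scan)
  is one of two defensible readings of the rule it implements.
- Spin inference for subcortical regions is unsupported by construction;
  their MI significance is parametric only.
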