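# Methods

`neurocouple` implements a voxelwise analysis of the relationship between
cerebral blood flow (CBF), functional connectivity strength (FCS), and their
per-subject coupling across groups of differing white-matter-hyperintensity
(WMH) load, together with a synthetic cohort generator that drives every
analysis end to end.

## Data model

All spatial data live on one shared voxel grid. `MaskedVolume` couples a 3-D
array with a boolean gray-matter (GM) mask and a voxel size in mm (default
3 mm isotropic); values outside the mask are ignored everywhere. `BoldSeries`
is a time-first 4-D array with a repetition time (TR, seconds) and per-frame
rigid-body motion parameters (3 translations in mm, 3 rotations in degrees).
`AslSeries` holds interleaved label/control frames plus a proton-density (PD)
reference volume. Subjects carry a total Fazekas score (0–6); the group is a
pure function of it — mild 1–2, moderate 3–4, severe 5–6 — and any
table row violating that mapping is rejected at load time.

## ASL quantification

CBF follows the single-compartment model for pseudo-continuous labeling:

    CBF = 6000 · λ · ΔM · exp(PLD/T1b)
          / (2 · α · T1b · PD · (1 − exp(−τ/T1b)))   [ml/100 g/min]

with ΔM the mean control−label difference over pairs. Defaults: partition
coefficient λ = 0.9 ml/g, labeling efficiency α = 0.85, arterial blood
T1b = 1.65 s, labeling duration τ = 1.45 s, post-label delay PLD = 2.025 s.
Voxels with non-positive PD are removed from the output mask; negative
quantified values (noise) are clamped to zero and counted in the log.

## BOLD preprocessing

Fixed temporal order: discard the first 10 frames → ordinary-least-squares
nuisance regression (intercept, linear trend, mean white-matter and CSF
signals, 3 or 6 motion regressors) → zero-phase ideal band-pass 0.01–0.08 Hz
(rectangular transfer function on the real FFT after reflection padding).
Spatial steps (realignment, normalization) are out of scope; inputs are
assumed co-registered. Framewise displacement uses the Power formulation
(sum of absolute derivatives, rotations converted to arc length on a 50-mm
sphere). The motion-exclusion rule fails any subject exceeding 3 mm
translation or 3° rotation on any axis; the boundary itself passes.

## FCS

FCS is weighted degree centrality: for voxel i,
FCS_i = (1/(N−1)) · Σ_{j≠i} r_ij · [r_ij ≥ 0.2], with r the Pearson
correlation between preprocessed time series. A correlation exactly at the
threshold is kept. Zero-variance voxels are dropped from the mask (logged).
The correlation matrix is computed as one triangle of a symmetric rank-k
update (BLAS `dsyrk`) on standardized series, thresholded in place — this
is algebraically identical to the brute-force double loop the tests compare
against (max abs diff < 1e−10) but runs ~1 s for 5832 voxels.

## Coupling

Per subject, both maps are smoothed with a 6-mm-FWHM Gaussian
(σ = FWHM/(2√(2 ln 2)), truncation at 6σ) renormalized at the mask boundary
so out-of-mask voxels carry zero weight, z-scored over the GM mask (sample
SD), and correlated — globally across all GM voxels and within each atlas
region (regions with < 3 voxels report NaN). A group-level mode (across-
subject correlation per voxel, averaged within regions) exists but is not
part of the default pipeline.

## Group statistics

Demographics: chi-square (no continuity correction) for categorical
variables, Kruskal–Wallis or one-way ANOVA for continuous ones; an ANOVA
from per-group n/mean/SD summaries reproduces the raw-data F exactly.
Region-wise inference is a permutation ANCOVA: the observed statistic is the
partial F of the group factor over the covariates (age, sex; mean-centered);
the null distribution comes from Freedman–Lane permutation of reduced-model
residuals; p = (1 + #{F_π ≥ F_obs})/(1 + 1000) is never zero. Post-hoc
pairwise contrasts run only when the omnibus p < α = 0.01. No multiple-
comparison correction is applied by default; Benjamini–Hochberg FDR is
available behind a flag. Partial correlations residualize both variables on
the covariates and use a t distribution with df = n − 2 − k.

## Mediation

Simple covariate-adjusted mediation (X → M → Y): a from M ~ X + C; b and the
direct effect c′ from Y ~ X + M + C; total effect c from Y ~ X + C. The OLS
identity c = c′ + a·b holds exactly and is asserted at 1e−10. Inference on
the indirect effect a·b is a 95% percentile bootstrap over whole subject
rows (default 5000 resamples; bias-corrected interval behind a flag);
degenerate resamples are redrawn and counted. Bootstrap refits are batched
(vectorized normal equations) for speed.

## Synthetic cohort generator

The generator's defaults are the study conditions: 86 subjects (32 mild /
24 moderate / 30 severe), an 18³ grid fully inside the GM mask, 24 regions
tiled as equal blocks with the 25% most central flagged as hubs, BOLD with
130 frames at TR 2 s (10 discarded), 40 ASL pairs. Region sizes, frame
counts and grid are package choices sized so the full pipeline runs on one
CPU in minutes; nothing in the statistics depends on them qualitatively.

Mechanisms: BOLD voxel series mix a community latent signal (weight 0.35,
communities partition the regions) with voxel noise and a leak of the
nuisance series; motion is a bounded random walk. FCS spatial fields are
region-level means plus voxel noise, z-scored. CBF maps are built to have a
chosen Pearson correlation ρ with the FCS z-map
(cbf_z = ρ·fcs_z + √(1−ρ²)·ε, re-standardized, scaled to mean 50 / SD 10
ml/100 g/min), with a hub-region reduction of d standardized units
(d = 0 / 0.6 / 1.2 for mild/moderate/severe). Group coupling strengths
default to ρ = 0.225 / 0.209 / 0.156. ASL frames invert the quantification
equation exactly, then add Gaussian noise (SD 2 signal units per frame).
Demographics/cognition tables draw from the reference summaries in
`neurocouple/reference.py`; raw cognitive scores (MMSE, TMT-A/B, AVLT
delayed recall, verbal fluency) use invented per-group means/SDs chosen so
the severe group is worst in every domain — the reference tables print only
domain z-scores, so these raw parameterizations are package choices.

All randomness flows from `numpy.random.SeedSequence` spawning, so every
product is bit-reproducible given one seed and independent across subjects.

## What passing tests do and do not show

The test suite establishes: the estimators agree with independent oracles
(brute-force FCS, closed-form CBF, scipy correlations); the generator/
estimator pair is self-consistent (ASL round trip exact at zero noise,
coupling ρ recovered within ±0.03 with the group ordering preserved); and
the inferential procedures are calibrated (permutation-ANCOVA type-I rate
within [0.003, 0.025] at α = 0.01, power > 80% at d = 1.2; mediation
bootstrap type-I ≈ 5%, CI coverage 90–98%). They do not show anything about
real MRI data: the generator encodes its own assumptions (Gaussian noise,
block atlas, linear coupling), and recovering parameters from data built to
contain them is a consistency check, not an empirical validation.

## Limitations

- Subject-level coupling values are tight around the group ρ; the generator
  does not emulate the across-subject coupling spread (~0.1 SD) a real
  cohort would show, because the recovery tests require a tight target.
- The ideal band-pass has an exactly rectangular transfer function;
  reflection padding suppresses but does not eliminate edge effects, so the
  cropped output of a DC-offset series retains a small (≪1 unit) sample mean.
- The block atlas and full-grid GM mask are geometric idealizations; no
  partial-volume or registration error is modeled.
- Mediation here is associational; no causal identification is claimed.
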