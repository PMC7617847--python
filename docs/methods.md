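# Methods

## The analysis in one paragraph

`painconnectome` implements a developmental functional-connectivity
analysis of the neonatal *pain connectome*: the network of 12 bilateral
pain-processing regions (thalamus, SI, SII, anterior/posterior insula,
ACC, MCC, amygdala, basal ganglia, OFC, vlPFC, dlPFC). Per subject, the
gray-matter-restricted mean BOLD signal of each region is reduced to a
vector of 66 absolute, hemisphere-averaged Pearson partial correlations
(one per unordered ROI-type pair). After per-cohort outlier screens, each
infant value r_C is normalised by the adult mean for that connection,
r-norm_C = r_C / r̂_CA, so that 1 means adult-like strength. A global
presence threshold — the mean thalamus–SI r-norm of infants younger than
32 weeks postmenstrual age (PMA), a connection known to be functional at
that age — sets sub-threshold values to 0 (absent). Maturation is then
characterised by per-subject summary metrics (proportion of present
connections; mean log10 r-norm of present connections), PMA regressions,
Dunnett comparisons of each PMA bin against adults, an age × subnetwork
ANOVA with Tukey follow-ups, and per-connection term-vs-adult Welch
t-tests with Benjamini–Hochberg FDR control within each subnetwork's
connection family.

## Partial correlation and conditioning set

The partial correlation between regions i and j is the correlation of the
residuals of each after regressing on all other regions of the
conditioning set; it is computed from the inverse of the column
correlation matrix R as −R⁻¹_ij/√(R⁻¹_ii R⁻¹_jj). Two conditioning modes
are provided:

- `per_hemisphere` (default): a 12×12 matrix per hemisphere, absolute
  values taken first, then the homologous left/right entries averaged.
  This matches a 66-connection analysis at the correlation stage and
  keeps the conditioning set small relative to the series length.
- `joint`: one 24×24 matrix conditioning each pair on all 22 other
  regions, followed by the same homologous averaging.

No Fisher z-transform is applied anywhere; the analysis operates on raw
|r|. A correlation matrix with condition number above 1e12 is an error —
there is no silent ridge regularisation.

## Outlier screens and their boundary conventions

- Infants: per connection, OLS of value on intercept + PMA; Cook's
  distance D_i = (e_i²/(p s²))·(h_ii/(1−h_ii)²) with p = 2; values with
  D_i strictly above 3 × mean(D) are discarded. With fewer than 4 usable
  points the screen is skipped with a warning.
- Adults: per connection, values deviating strictly more than 3 sample
  standard deviations from the mean are discarded (single pass, no
  iteration); zero variance keeps everything.

Both cuts use strict inequalities ("exceeding"), so ties survive.
Discarded values become *missing* (NaN) and are excluded from every
downstream mean and denominator; they are never imputed or zeroed.
Missingness is distinct from *absence* (presence-thresholded to 0).

The stage order is fixed and guarded by tests: QC screens → adult
reference means (post-screen) → normalisation → presence threshold. The
presence threshold is applied globally, to adults as well as infants;
values exactly at the threshold stay present (strict "below").

## Statistical battery

- PMA regressions: ordinary least squares, R² = 1 − SS_res/SS_tot; a
  constant metric returns slope 0 and R² 0.
- Group-vs-adult: Dunnett many-to-one comparisons via the multivariate-t
  formulation (scipy), seeded for reproducible numerical integration;
  groups with n < 2 are excluded with a warning.
- Age × subnetwork ANOVA: two-way fixed effects with interaction, Type II
  sums of squares on the unbalanced layout. Each subject contributes one
  row per subnetwork and rows are treated as independent — with the
  emulated cohort sizes (470 subjects × 3 subnetworks, 7 age groups) the
  residual df is 1410 − 21 = 1389. The interaction's explained-variance
  share is SS_interaction/SS_total. Tukey-corrected pairwise comparisons
  run for subnetworks within age group and age groups within subnetwork.
- Connection-level tests: Welch (unequal-variance) t-tests of r-norm
  between late-term infants (40–42 wk) and adults; BH-FDR at 0.05 within
  each subnetwork's connection family (sensory 10, affective 10,
  cognitive 15) by default, with a single global family as a config
  switch. Strength averages use log10 of present connections only,
  keeping the log finite. A connection with zero variance on both sides
  is flagged untestable rather than tested.

Subnetworks: sensory {SI, SII, thalamus, BG, pI}, affective {aI, ACC,
thalamus, amygdala, BG}, cognitive {dlPFC, vlPFC, OFC, MCC, BG, aI};
shared pairs (e.g. thalamus–BG) legitimately belong to several families.

## Synthetic cohort generator

The generator exists so every downstream stage is testable without
external imaging data. Each subject is a stationary zero-mean Gaussian
process on 24 channels (12 ROIs × 2 hemispheres, left block then right
block). The two hemispheric blocks are independent (block-diagonal
precision); within a block the precision matrix is built so the absolute
partial correlation of each pair equals a target given by that
connection's logistic growth curve

    target(PMA) = floor + (adult_target − floor) · logistic(rate · (PMA − onset))

evaluated at the subject's PMA, with independent N(0, 0.02) hemispheric
jitter (clipped to [0, 0.9]). Adults sit at the asymptotic targets.

Key design choices and why:

- **Sparse two-tier targets with mixed signs.** A dense equal-sign
  partial-correlation pattern on 12 nodes is positive definite only below
  1/11 ≈ 0.09, far under useful effect sizes. Defaults therefore give
  within-subnetwork connections an adult target of 0.18 and background
  connections 0.03, with a fixed balanced sign pattern chosen once by the
  eigenvalue margin of the implied precision matrices (the analysis takes
  absolute values, so signs are otherwise inconsequential). The default
  design never triggers the diagonal-loading repair; if a custom design
  does, loading shrinks all targets uniformly by 1/(1+λ) and the achieved
  targets are recorded as ground truth.
- **Growth timing.** Onset midpoints sensory 31, affective 35, cognitive
  39 weeks (background 36), rate 0.45/week, floor 0.02. The 4-week
  spacing keeps the three curves separated through the 40–42-week bin;
  curves that saturate by term would make the designed
  sensory ≥ affective ≥ cognitive ordering of presence proportions a coin
  flip in late bins regardless of sample size. A connection in several
  subnetworks inherits the earliest onset.
- **Cohort structure.** Group bins and sizes mirror the emulated infant
  and adult cohorts: <32 (8), 32–34 (8), 34–36 (34), 36–38 (40), 38–40
  (100), 40–42 (182) plus 98 adults; infant series of 2300 time points,
  adult series of 1200. PMA is uniform within each bin. Scaled-down
  cohorts for desk-scale runs keep the bins and series-length structure
  but floor each group at min(printed size, 6) subjects — with fewer, the
  presence-threshold reference group and the Cook screen's age regression
  become degenerate rather than merely noisy.
- **Overshoot designs.** `infant_target_scale` multiplies infant-group
  targets per connection without touching adults; inflating 7 of the 10
  sensory connections by 1.5 produces a cohort whose term-vs-adult tally
  should report ≈70% of sensory connections significantly stronger.
- **Determinism.** Per-subject RNG streams derive from the cohort seed as
  SeedSequence(entropy=seed, spawn_key=(subject_index,)); identical spec
  and seed give bit-identical cohorts.

What the generator deliberately does *not* emulate: hemodynamic
convolution, temporal autocorrelation (an AR(1) knob exists, default 0 —
it only reduces effective sample size), motion or physiological
artifacts, scanner drift, cross-hemisphere dependence, or denoising
residuals. Passing tests therefore demonstrate correctness of the
estimation and inference chain under the stated Gaussian model, not
robustness to real fMRI artifact structure, and the growth-curve defaults
are designed for testability rather than calibrated to real infant data.

## Numerical conventions and degenerate inputs

- Gray-matter threshold for probabilistic masks: > 0.5; binary masks keep
  all nonzero voxels. ROI means are unweighted; an ROI with fewer than
  `min_voxels` (default 1) eligible voxels is an error naming the ROI.
  Voxel grids must match exactly; no resampling.
- Zero-variance time-series columns and singular correlation matrices are
  errors naming the offender.
- A perfect regression fit (zero residual variance) yields all-zero
  Cook's distances and no discards.
- Age bins are half-open on the left (<32, [32,34), …) with the last bin
  closed at 42; adults form their own group.
- Tiny pipelines can leave an ANOVA cell empty (e.g. an all-absent
  youngest bin for the strength metric); the library raises, while the
  end-to-end pipeline skips that metric's ANOVA with a warning.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script runs use scaled cohorts chosen as
sensible desk-scale sizes: cohort scale 0.1 (≈61 subjects) at 1200 time
points per subject for trajectory checks over 20 seeds; n = 100 per group
at 600 time points for the overshoot tally; 500–1000 replicates for the
Dunnett null calibration (7 groups × 50); single subjects at 50,000 time
points for convergence checks. The full-scale defaults (470 + 98
subjects, 2300/1200 time points) run through the identical code path.

## Known limitations

- The Dunnett and Tukey procedures assume homoscedastic groups; the
  connection-level tests use Welch t-tests, so the two families make
  different variance assumptions (both stated, neither configurable).
- Per-hemisphere conditioning is an interpretation; the joint 24-region
  mode is provided but carries a larger conditioning set per sample.
- The Cook screen fits a *linear* age trend to what the generator makes a
  logistic curve; at sparse age extremes this model mismatch inflates
  influence and can discard legitimate young-end values — visible at
  aggressive cohort down-scaling, which is why scaled groups are floored.
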