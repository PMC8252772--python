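# Methods

This note records the models, conventions, default parameters and numerical
choices behind `srica`, and what the synthetic validation does and does not
establish about real data.

## The analysis model

The pipeline estimates, for a small anatomical ROI (a bilateral hippocampus
stand-in), which clusters of ROI voxels act as coherent sources, which
canonical resting-state network each cluster participates in, and which ROI
subfields carry each cluster.

**Spatially restricted group ICA.** Runs are confined to the ROI voxels
(template-space mask; a fixed C-order voxel linearization is used
everywhere), each voxel is scaled to unit variance per run, and runs are
temporally concatenated into a T_total × V matrix. Spatial ICA treats
voxels as samples and timepoints as features: the data are PCA-whitened to
dimension d and unmixed with a fixed-point iteration (logcosh contrast,
symmetric decorrelation). Five random restarts are run; the solution with
the largest total negentropy among the converged restarts is kept, and a
fit with no converged restart is an error that carries the diagnostics.

*Whitening convention.* The PCA operates on the raw spatial second moment
(voxel Gram matrix), **without** subtracting the per-timepoint spatial mean.
Voxel time series are already demeaned by preprocessing, so no temporal DC
survives; what the choice affects is the spatial geometry. In a small ROI,
two nonnegative source maps occupying different sections are strongly
*negatively* correlated once spatially centered (measured r ≈ −0.41 for the
default generator), and whitening's forced orthogonality would then make
them unrecoverable by any rotation. On the raw second moment the same maps
are near-orthogonal and the noiseless two-source oracle recovers both
exactly. Exported maps are afterwards z-scored over ROI voxels, the
peak-magnitude voxel is made positive, and components are ordered by
descending back-projection variance, so downstream results do not depend on
ICA's arbitrary permutation and signs.

**Dual regression.** Stage 1 regresses all d component maps jointly (with a
spatial intercept) against each volume of the participant's ROI data —
because the component maps exist only on ROI voxels, the ROI-restricted
data are the regression target — giving a T × d time-course matrix per
participant (runs concatenated). Stage 2 regresses the variance-normalized
courses jointly (with an intercept) on every brain voxel's series. Each
coefficient is mapped to its partial correlation, r = t/√(t²+dof), and
Fisher-transformed. Raw regression coefficients are unbounded, so a Fisher
transform of the coefficient itself is ill-defined; the partial-correlation
conversion makes atanh well-posed while preserving the sign and ordering of
effects. A `coefficient_scale="raw"` mode retains the literal coefficient
path for comparison (used by the noiseless proportionality oracle, where
the coefficient *is* the planted weight).

**Group maps.** `parametric` (default): voxelwise one-sample t over
participants, mapped through the t CDF to a normal quantile. `signflip`:
voxelwise one-sided sign-flipping permutation p (default 1000 flips,
identity included so p ≥ 1/n_perm), mapped to z; the max-statistic
family-wise p per voxel is also reported in the map's diagnostics.
Zero-variance voxels are flagged and set to z = 0 in either mode.

**Component selection.** Given the n × d matrix of Pearson correlations
between group maps and the m = 7 network templates (computed over the brain
mask, unthresholded by default; a template-support mask and a display-style
|z| threshold are available as options), a component is matched when
(a) its row maximum exceeds `r_threshold` = 0.4, (b) the maximum beats the
second-highest value in its row by more than `ratio_threshold` = 1.3, and
(c) likewise for the second-highest value in its matched column. Ratios
with nonpositive denominators pass (the maximum is overwhelming — the
comparison value carries no positive evidence); ties for the row maximum go
to the lowest network index. Inequalities are strict. The column rule makes
matched networks distinct, which is asserted. The dimension sweep runs the
full chain at every d in `d_range` (default 1..15) and keeps the lowest d
attaining the largest match count; a failure at one dimension (e.g. a
non-converging ICA) is recorded as zero matches and does not abort the
sweep.

**Region and subfield statistics.** Mean Fisher-z per (participant,
hemisphere, region, FC map) cell is modeled as
`mean_z ~ hemisphere + fc_map * region + (1 | participant)` (REML, sum
coding). Type III tests are Wald chi-squares on the sum-coded term blocks;
p-values use the large-sample chi-square and the fit records
`df_method="normal"`. The post-hoc statistic throughout is the z-ratio
(estimate/SE), which needs no small-sample df correction; the
implementation is cross-checked against lme4/lmerTest/emmeans (via Rscript)
to 1e-5 on fixed effects, marginal means and variance components. A
singular fit (participant variance collapsing to zero) falls back to OLS
with a warning and a flag — on the synthetic cohorts this is the rule, not
the exception, because Fisher-z maps are invariant to participant amplitude
scale, so the planted amplitude offsets produce almost no participant-level
z variance. Marginal means are averaged over hemisphere before contrasting
(hemisphere is an additive nuisance). The "effect" contrast compares each
region with the unweighted mean of the other regions (the grand-mean
variant, differing only by the factor R/(R−1), is available); estimates are
zero-sum within each FC map (asserted at 1e-8). Bonferroni family size
defaults to regions × FC maps. Subfield ranking uses the identical model
with the six subfield labels, all S(S−1)/2 pairwise marginal-mean
differences per FC map, signed z-ratios summed per subfield (zero-sum
pre-threshold, asserted), thresholded at > 0 and ranked descending. No
multiplicity correction is applied inside the ranking: the z-ratios act as
a ranking statistic, not as tests. The interaction gate (post-hocs only
when the fc_map × region interaction has p < .05) applies when at least two
FC maps are present.

## The synthetic cohort

The generator emulates the study conditions at desk scale; its defaults are
the conditions every acceptance simulation uses.

| parameter | default | meaning |
|---|---|---|
| grid | 24³ voxels, 1.6 mm | common lattice; brain = centered sphere |
| N, runs, T | 20, 2, 200 | participants × runs × volumes per run |
| ROI | two mirrored curved tubes | 3×3 six-layer cross-section, ML central, constant along the long axis; ≥ 4 voxels per subfield per hemisphere |
| atlas | 42 regions/hemisphere | k-means parcels on the left hemisphere, mirrored right (codes +1000); bilateral by construction |
| networks | 7 | disjoint unions of atlas parcels, bilateral binary maps |
| sources | 2 | long-axis Gaussians at fractions 0.2 (σ 0.12) and 0.7 (σ 0.18) |
| subfield weights | A: CA1/CA3 1.0, CA4/DG 0.6, SUB 0.1, ML 0.3; B: SUB 1.0, CA4/DG 0.6, CA1/CA3 0.1, ML 0.3 | within-ROI loading per source; ML only ever receives bleed-over |
| network coupling | indices (1, 6); weight 0.6 | each source's time course also drives its network's parcels |
| hemisphere gain | +10 % left | recoverable hemisphere main effect |
| participant offsets | sd 0.1 | multiplicative amplitude variation |
| nuisance | amplitude 1.0 in CSF/WM masks, leak 0.05 brain-wide | removed by confound regression |
| noise | AR(1), coefficient 0.3, plus white; equal variance split | exercises variance normalization non-trivially |
| snr | 0.7 | source amplitude / total noise sd |

The `snr` default deserves a note, because its effect is not monotone. With
variance normalization on, each ROI voxel is scaled by its total sd, so at
*high* snr the source maps saturate toward support indicators, their
overlap (shared CA4/DG loading and Gaussian tails) is amplified, and the
d = 2 ICA can converge to stable mixtures of the two sources (recovery
collapsed at snr 1.5). At snr 0.7 — noise sd ≈ 1.4 × signal amplitude,
which is also the realistic regime for single-voxel resting BOLD
fluctuations — recovery is clean: across the ten default cohorts the sweep
selects both components at d = 2 with hotspot map correlations of 0.99
against the planted fields. Amplitude 0 gives the null cohort (noise sd
1/snr): nuisance plus noise only.

Atlas and subfield jitter reassigns a random ~20 % of internal label
boundary voxels to a neighboring label drawn from the *template* volume
(hence displacement ≤ 1 voxel), never moves mask support, and preserves the
per-hemisphere minimum counts. It emulates participant-specific morphology
for the label-intersection stages without implementing registration.

What the generator does **not** emulate: hemodynamic response convolution,
physiological noise spectra, head motion, spatial autocorrelation of noise,
MNI geometry, or realistic network map shapes. Passing tests therefore
demonstrate correctness of the algorithms under a known generative model —
recovery of planted structure, specificity under the null, calibration of
the permutation test — not performance on real 7T data.

## Problem sizes used by the validation suites

Recovery uses the default cohort above (ten seeds; the full sweep over
d = 1..15 takes ≈ 25 s per cohort on one CPU). Null calibration uses twenty
amplitude-0 cohorts at N = 10, T = 120, sweeping d = 1..8 — the null
decision is driven by the correlation threshold, which noise-only group
maps (spatial correlations with templates of order 1/√V ≈ 0.01) never
approach, so the smaller cohort tests the same mechanism. Sign-flip
calibration uses 20 × 1000 null voxels with 1000 permutations.

## Numerical conventions and degenerate inputs

- Partial correlations are clamped to |r| ≤ 1 − 1e−7 before atanh
  (z ≈ 8.41 at the clamp); normal quantiles are clipped at |z| = 37.
- Constant (zero-variance) voxels: flagged, z = 0 in stage 2 and in group
  maps; zeroed and flagged in group concatenation; correlation entries with
  zero-variance inputs are 0.
- A confound that is identically zero (e.g. extracted from a constant
  image) is tolerated as informationless; collinearity among nonzero
  confounds, collinear component maps (condition number > 1e8) and
  rank-exceeding ICA dimensions are errors.
- 0/0 Wald ratios on exactly constant responses are reported as 0.
- Determinism: every stochastic step (anatomy, jitter, time courses, noise,
  ICA restarts, sign flips) derives from explicit integer seeds; reruns are
  bit-identical, and the cohort manifest is byte-stable.
- d = 1 ICA is the first principal component (a 1-D rotation is a sign).

## Known limitations

- Satterthwaite degrees of freedom are not implemented; all p-values from
  the mixed model are large-sample. At the cell counts used here (≥ 3000
  observations for the region model) the difference is negligible, and the
  ranking statistics are z-ratios either way.
- The mixed model's participant intercept is rarely identifiable on
  synthetic cohorts (see above); the OLS fallback is exercised instead, and
  the mixed path is validated on directly simulated region tables.
- MELODIC-style probabilistic mixture-model thresholding of component maps
  and TFCE-style cluster inference are out of scope; the display threshold
  (|z| > 4) affects reports only, never computation.
- The selection thresholds (0.4, 1.3) are fixed inputs, not estimated; the
  pipeline makes no attempt to automate their choice.
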