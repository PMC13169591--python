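# Methods

This note documents the models implemented in `alpscog`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a user auditing results will care about.

## Signal model and tensor estimation

Diffusion-weighted signals follow the monoexponential tensor model
`S(g, b) = S0·exp(−b·gᵀDg)` with `D` the symmetric 3×3 diffusion tensor in
subject axes (x = left–right, y = anterior–posterior, z =
superior–inferior; nothing in the package reorients data, and every
volume container carries this axis tag). Tensors are fitted voxelwise by
unweighted log-linear least squares on `ln S`: with at least one b = 0
volume and directions spanning six independent outer products the design
is full rank, and on noise-free data the fit is exact to machine
precision. An optional one-pass signal-weighted refit (`weighted=True`)
is available; it reduces the log-transform bias at low SNR but is not the
default because the unweighted fit is the plainest reading of
"estimated" tensors and is exactly invertible in the noise-free case.
Voxels with non-positive signals are flagged invalid rather than raising;
fits with negative eigenvalues are clamped to 1e−7 mm²/s and flagged, so
downstream ROI means stay defined while degeneracy stays visible.

Scalar maps use the eigenvalue definitions: MD = mean(λ), AD = λ₁,
RD = (λ₂+λ₃)/2, FA = √(3/2)·‖λ−MD‖/‖λ‖ (defined as 0 for an all-zero
tensor). MD/AD/RD are reported in 10⁻³ mm²/s where they enter cohort
tables, matching the conventional printed scale.

## ALPS index and automated ROI localization

`ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)`. Dzz of
the projection ROI and Dyy of the association ROI are measured and
reported but deliberately excluded from the formula — they are the
diffusivities *along* each fiber population. The index is scale-invariant
and equals 1 for any isotropic field.

ROI localization follows the profile-curve construction: at each
candidate (y, z) anchor in a user- or truth-supplied search band, the
mean Dxx/Dyy/Dzz over an in-plane circle (default radius 5 mm,
unspecified in the source methodology and chosen as a few voxel widths)
is swept along x. Per hemisphere, the projection ROI is centered at the
maximum of the Dzz ("blue") curve over the whole candidate grid and the
association ROI at the Dyy ("green") maximum. Deterministic tie-break:
highest value wins; exact plateaus resolve to the candidate closest to
the band center. A peak must exceed the median of its hemisphere's pooled
curve values by `min_prominence` (default 2×10⁻⁴ mm²/s, about a quarter
of typical white-matter diffusivity) or localization fails — a uniform
field therefore raises rather than returning an arbitrary voxel. The
hemisphere split defaults to the volume x-center and is configurable.
Template (MNI) registration for initial seeding is intentionally out of
scope; the explicit search band replaces it and is recorded in the
result's provenance.

The nominal "3 mm spherical ROI" is read as a 1.5 mm radius in mm space.
On grids of ≥ 2 mm spacing this admits only the center voxel, so the
radius is configurable and logged; 2.6 mm (adding the face-neighbor
voxels on a 2 mm grid) is the recommended setting for coarse grids and is
what the Monte-Carlo recovery studies use. Distances are computed between
voxel centers in mm, so anisotropic voxels are handled correctly.
Bilateral ALPS is the arithmetic mean of the two hemisphere indices;
whether a published ALPS is bilateral or unilateral is often ambiguous,
so all three values are always reported.

## Synthetic phantoms

`make_phantom` builds a 64×64×32 volume of 2 mm isotropic voxels
(background isotropic D = 0.8×10⁻³ mm²/s) containing 5×5×5-voxel
projection blocks (D = (1.2, 0.8, 1.6)×10⁻³, Dz-dominant) and association
blocks (D = (1.2, 1.6, 0.8)×10⁻³, Dy-dominant) flanking the midline in a
mid-axial band — the geometry of the periventricular ALPS level reduced
to its essentials. The right hemisphere is the exact x-mirror of the
left, so left and right truth ALPS are equal by construction and the
default truth ALPS is 1.5, a healthy-range value. Acquisition follows the
study protocol shape: b = 0 plus b = 1000 s/mm² along 64 directions. The
direction table is a fixed package fixture generated once by antipodal
electrostatic-repulsion minimization (minimum pair angle ≈ 17°); the
actual scanner table is not public, so this is a stand-in with the same
design character, not a reproduction. Noise is Rician by default
(magnitude MRI) with σ = S0/30, i.e. b0 SNR ≈ 30, a mid-range clinical
value chosen because the acquisition SNR is not reported; Gaussian and
noise-free modes exist for analytic checks. Exactly-isotropic blocks are
accepted as a degenerate analytic case (truth ALPS = 1) even though
regular phantoms require strict Dz/Dy dominance.

What the phantom does **not** emulate: real anatomy and partial-volume
mixtures, multi-shell acquisitions, motion/eddy/susceptibility artifacts,
and spatially varying coil sensitivity. Passing the recovery studies
therefore demonstrates correctness of the estimator chain (fit →
localization → extraction → index) under controlled noise, not robustness
to real-world preprocessing failures, which the pipeline deliberately
assumes have been handled upstream.

## Synthetic cohorts

`make_cohort` emulates the statistical structure the cohort analysis
assumes: 45 patients and 41 controls by default, age ≈ N(43, 11²) years,
one-third male (sex coded 0 = female, 1 = male throughout), education
≈ N(10, 3²) years; ALPS ≈ N(1.42, 0.27²) in patients vs N(1.53, 0.19²) in
controls and nWMV ≈ N(35.2, 3.2²) vs N(36.0, 1.7²) — group means at the
published magnitudes with SDs reconstructed from the printed SEMs. Raw
cognitive scores are linear in centered age/sex/education plus a
patient-group shift plus planted ALPS/nWMV terms plus Gaussian noise.
Planted effects are specified as *standardized* betas and converted to
raw coefficients in closed form from the independent-covariate variance
decomposition (σ²_Y = (σ²_cov + σ²_ε)/(1 − Σβ²_std)), so the planted
standardized beta is exactly the estimand the adjusted regression
recovers. Default planted effects mirror the reported association
pattern (ALPS on SDMT 0.40, PASAT-3s 0.30, PASAT-2s 0.43, COWA 0.30).

A planted impairment label is generated from
`logit P(impaired) = c₀ + c_a·z(ALPS) + c_n·z(nWMV)` with per-SD
log-odds defaults −0.93 and −0.81 (the published odds ratios converted to
the per-SD scale) and c₀ = 0 (≈ 50% prevalence, matching 22/45). This
label is the synthetic ground truth for selection-recovery and AUC
studies; the pipeline's own Z-score-derived classification is computed
independently and the two need not coincide subject-by-subject, since the
BICAMS rule sees only three domain scores.

## Statistics

- **Normative Z-scores**: OLS of each raw score on age, sex, education
  over controls; residual scale uses the n − p denominator. Z = residual /
  scale, so the fitting sample has mean Z = 0 exactly. A degenerate
  (zero-residual) norm maps on-plane subjects to Z = 0 and raises
  otherwise. MMSE/MoCA are Z-scored by the same procedure as every other
  test.
- **Impairment**: Z ≤ −1.5 in ≥ 2 of the three BICAMS domains; the
  boundary −1.5 counts as impaired. Missing scores are a hard error.
- **Comparisons**: Shapiro–Wilk at α = 0.05 in *both* groups gates a
  pooled-variance Student t (Cohen's d, pooled SD) versus a Mann–Whitney
  U (tie-corrected asymptotic Z without continuity correction, the
  SPSS-style statistic; effect size r = |Z|/√N). N in r defaults to the
  analyzed rows but is set to the full study N even for subgroup
  comparisons in the pipeline, because that is the convention the
  published effect sizes follow (e.g. 2.680/√86 = 0.289). Categorical
  variables use Pearson χ² without continuity correction. "Mean ±" group
  descriptives are mean ± SEM: with the SD reading the published t
  statistics are impossible to reproduce from the printed summaries,
  with SEM they reproduce within rounding (`summary_ttest` demonstrates
  this; it uses Welch's t since only summaries are available, while
  full-data comparisons default to the pooled t the study names).
- **FDR**: Benjamini–Hochberg, one family per analysis block
  (patients-vs-controls table, cognition table, subgroup table, the
  correlation screen, each adjusted-model predictor set); family labels
  are explicit arguments since no source defines the families.
- **Adjusted models**: OLS of each cognitive Z on the Spearman-screened
  (p < 0.05) imaging predictors plus age/sex/education; per-predictor B
  with 95% CI, standardized β (unit-SD scaling of predictor and outcome),
  VIF from auxiliary regressions on all other right-hand-side terms, q
  within the model family.
- **Stepwise logistic**: candidates are the variables univariately
  significant (p < 0.05) between impaired and preserved patients; backward
  elimination removes the largest Wald p while it exceeds 0.05 (criterion
  and threshold are unstated in the source and fixed here explicitly).
  Diverging coefficients (|B| > 50) or non-convergence raise a separation
  error rather than reporting meaningless ORs. ORs carry Wald 95% CIs;
  ROC AUC = U/(n₁n₂) with half-credit ties is reported for the final model
  and per retained predictor (oriented ≥ 0.5 with a direction flag).
- **Degenerate inputs**: two identical constant groups return statistic 0,
  p = 1, d = 0; constant columns in the Spearman screen are flagged
  undefined; empty stepwise candidate sets and single-class outcomes
  degrade to recorded notes, not crashes.

## Problem sizes and determinism

Monte-Carlo studies use the sizes at which the estimators' behavior is
already clearly resolved: 10 phantom seeds at 64×64×32 for ALPS recovery,
50 cohort seeds at 200 patients for selection/beta recovery, 100 null
simulations for type-I calibration, 1000 random vectors for the FDR
oracle. All generators take explicit seeds and are byte-deterministic
under a fixed spec + seed; the acceptance script derives every stream
from its `--seed`.

## Known limitations

- The ALPS ROI search needs a caller-supplied periventricular band on
  real data; there is no built-in atlas registration.
- The white-matter diffusion summary is an FA > 0.2 mask mean, a
  registration-free stand-in for skeleton-projected (TBSS-style)
  statistics; absolute values are comparable in magnitude but not
  numerically interchangeable with skeleton means.
- Lesion metrics count 26-connected components of a supplied mask;
  segmentation itself (and lesion filling, tissue segmentation, cortical
  thickness) is out of scope — those arrive as precomputed inputs.
- The published refinement of peak positions beyond deterministic peak
  selection is not algorithmically specified anywhere; this package
  implements exactly the deterministic peak choice and documents it.
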