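# Methods notes

This note records the models, conventions and numerical choices behind
`nmseg`, in the spirit of a methods appendix: what is simulated, what each
stage assumes, which knobs matter, and what the synthetic validation does
and does not establish about real data.

## Imaging model and phantoms (`nmseg.phantom`)

The phantom emulates a 2-D MT-prepared GRE slab: by default a 96 × 96 × 16
grid at 0.5 × 0.5 × 2.0 mm (0.5 mm³ voxels), acquired as 5 (optionally 10)
repeated measurements. The scene is a uniform background (default 100
signal units) with a bilateral, crescent-shaped SNc elevated by a
fractional contrast `snc_contrast` (default 0.3, i.e. SNc = 130). The
crescents are voxel-aligned differences of ellipsoids totalling ~380 mm³
— a realistic nigral volume — and carry small opposite through-plane
offsets (±1 mm) so that the scene has first-order sensitivity to
out-of-plane rotation, which an axially symmetric blob would not. A
disjoint pair of ellipsoids at background intensity defines the cerebral
peduncle reference region; it is deliberately invisible in the GRE scene,
as a pure-white-matter reference would be. `snc_voxels` forces an exact
ground-truth voxel count (used by tests that need, say, exactly 700
voxels); voxels are added/removed deterministically by signed distance to
the crescent boundary.

Per-measurement rigid motion (3 translations mm, 3 rotations deg about the
grid centre) is applied by resampling the scene; the first measurement is
required to be motion-free because it defines the native frame. Noise is
Rician — the magnitude-MRI convention: `|(S + n₁) + i n₂|` with
`n₁, n₂ ~ N(0, σ)` — reducing to Rayleigh at zero signal and to
approximately `N(S + σ²/2S, σ)` at high SNR; a Gaussian option exists via
`noise_model`. With σ = 0 the phantom is exactly piecewise-constant, so
noise-free segmentation recovery can be checked for bit-exact equality.

The probabilistic atlas is the template-space truth mask smoothed with a
2 mm Gaussian and peak-normalised to [0, 1]; its > 0.05 support strictly
contains the truth. The template "space" is the phantom's own grid with a
stored template→native affine (identity by default) — no external template
is shipped, and nothing is ever estimated against one.

What the phantom does *not* model: graded neuromelanin contrast (real SNc
intensity tapers, the phantom is binary), bias fields, susceptibility or
k-space artefacts, and anatomy beyond the few structures registration
needs. Consequences are listed under Limitations.

## Cohort simulator (`nmseg.cohort`)

`simulate_cohort` draws one row per subject: group label, age, sex, site,
total brain volume, clinical scores and an SNc volume

    volume = group_mean + Σ effect_j · (covariate_j − E[covariate_j]) + ε,

with `ε ~ N(0, σ_resid)` and `σ_resid` chosen so the *marginal* group SD
equals the specification regardless of the covariate effects (effects are
mean-centred, and their analytically computed variance is subtracted).
Covariate effects default to zero, so the marginal group distributions
equal the specified means/SDs exactly; nonzero effects are opt-in for
ANCOVA power experiments. Volumes are truncated at 0 mm³ (a volume cannot
be negative); at the default group parameters the truncation probability
is below ~0.7% in the worst group and the induced bias is under 1 mm³.

Two ready-made designs mirror the published study structure: a five-group
cohort (control/hyposmia/RBD/de-novo-PD/moderate-PD, n = 50/217/76/194/26,
volume means 395.2/332.1/336.0/309.4/291.2 mm³ with SDs
117.0/100.7/96.6/100.0/118.3) and a three-group non-manifest-carrier
cohort (control/LRRK2/GBA1, n = 50/46/44, means 395.2/381/379 mm³).
Demographics (age, sex ratios, clinical scores) follow the corresponding
group tables. Total brain volume is not reported in those tables; the
simulator uses 1.15 × 10⁶ ± 1.1 × 10⁵ mm³, a realistic adult value, the
same for all groups. Sites default to four equiprobable labels with no
intensity consequences (site-dependent scaling is configurable but off).

## Preprocessing (`nmseg.preprocess`)

Stages run in the fixed order **denoise → motion-correct → average**; the
pipeline config rejects any other order unless explicitly overridden.

**Patch-PCA denoising.** The stack is tiled into 4³-voxel patches; each
patch yields an (n_voxels × n_measurements) matrix. The per-voxel mean
across measurements — the repeated signal — is always kept; the residual
is SVD-shrunk, discarding components whose covariance eigenvalues fall
below a Marchenko–Pastur bulk edge estimated from the trailing spectrum.
Constant stacks pass through bit-exactly, and for an already-aligned stack
the output reduces to per-voxel averaging (no spatial blur). The flip side
is documented under Limitations: genuine *inter-measurement* structure —
uncorrected motion — survives only while it stays above the noise edge.

**Rigid registration.** Every measurement is registered to the first by
maximising normalised cross-correlation under a 6-parameter rigid
transform (translations in mm, rotations in degrees about the fixed
image's world centre), trilinear interpolation, constant padding at the
border median. The metric is evaluated on smoothed (σ = 1.5 mm,
anisotropic in voxel units so thick slices are not over-blurred),
in-plane 2×-decimated copies; since the transform lives in world mm the
decimation does not limit sub-voxel accuracy, and it cuts the cost ~4×.
Optimisation is Powell's method after a multi-start sweep over coarse
translations (±1, ±2 in-plane voxels, ±1 slice). Estimates within 0.005
mm/deg of identity are snapped to the exact identity so already-aligned
measurements are passed through without resampling — this is what makes
noise-free recovery bit-exact. A registration that fails to improve on the
identity falls back to identity with a logged warning. On default phantoms
the residual alignment error is ≈ 0.1 in-plane voxels (mean over the SNc).

**Averaging** is the voxel-wise arithmetic mean, permutation-invariant.

## Transforms and resampling (`nmseg.spatial`)

World coordinates are RAS+ mm; voxel indices are 0-based; NIfTI affines
are honoured on read/write. An `AffineTransform` maps source-space world
coordinates to target-space world coordinates, with space labels checked
when chains are composed. Whenever an object crosses several frames
(template → T1 → GRE), the chain composes into a single matrix and exactly
one resampling is performed — the single-step rule; the test suite shows
the composed round trip never loses more mask overlap than two sequential
resamplings. Masks are warped nearest-neighbour by default (they remain
strictly binary); a trilinear-then-threshold-at-0.5 dialect is available.
Scalar images are warped trilinearly. `estimate_affine` extends the rigid
registration to 12 dof (log-scales and shears) for template↔T1-style
alignment; nonlinear registration is deliberately out of scope, so the
synthetic template↔native mapping is affine and known, never estimated.

## Segmentation (`nmseg.segmentation`)

* σ_ref uses the population convention (divide by n); reference ROIs have
  hundreds of voxels, so the choice is immaterial, and `ddof=1` is a flag.
* Both thresholds are **strict**: atlas probability `> 0.05`, intensity
  `> μ_ref + k·σ_ref`. A voxel exactly at the threshold is excluded.
* Dilation of the atlas support uses the 6-connected (city-block radius-1)
  structuring element, iterated `dilation_radius_voxels` times (default 1).
* σ_ref = 0 is legal (the threshold degenerates to μ_ref); NaNs inside the
  search region are an error; an empty search region after warping is an
  error (it signals a failed ROI transfer).
* No connected-component or size filtering is applied by default — the
  rule is purely intensity-based; a keep-largest-two-components filter
  exists behind a flag.
* The whole rule is scaling-equivariant: multiplying the image by c > 0
  scales μ_ref, σ_ref and the threshold by c and leaves the mask unchanged.
* The contrast map is `(I − μ_ref)/μ_ref`, a reference-normalised
  magnetisation-transfer contrast; the normalisation is this package's
  documented choice.

## Population maps (`nmseg.popmaps`)

Subject masks are warped to the template grid (one composed resample each)
with trilinear interpolation and averaged, so a map voxel is the fraction
of subjects whose SNc covers it — a proportion, not a label; values are
provably in [0, 1] and adding one subject moves any voxel by at most 1/n.
The voxel-sharing proportion of a sub-ROI is the mean map value over it.

## Cohort statistics (`nmseg.stats`)

The ANCOVA is an OLS fit of `outcome ~ group + covariates` with treatment
coding. The group effect is the partial F from dropping the group columns;
in this main-effects-only model that equals the Type III convention of
standard clinical software, including under unbalanced groups. Estimated
marginal means are model predictions per group with numeric covariates at
their sample means and categorical covariates weighted equally over
levels; their SEs come from the coefficient covariance. Post hoc pairwise
comparisons are two-tailed t tests on adjusted mean differences,
**uncorrected** by default (matching the reporting convention of the
studies this mirrors); Holm/Bonferroni are flags. Rank-deficient designs
raise an error naming the aliased columns (pivoted QR), as does a fit with
no residual degrees of freedom. Missing data are dropped listwise with a
logged count. Partial correlation residualises both variables on the
controls (intercept included, categorical controls dummy-coded) and uses
`df = n − 2 − k` for the t-based p-value, k the number of control
regressors. Shapiro–Wilk runs per group (n ≥ 3; constant samples are an
error, never a silent pass) and warns rather than aborts at p < 0.05.

Simulation scales: the null-calibration check uses 2000 two-group
replicates (n = 30 + 30), chosen to give a binomial standard error of
~0.005 on the rejection rate; the power check uses 500 replicates of the
full 563-subject design, where a noncentral-F calculation on the specified
effect sizes predicts power ≈ 0.998.

## Design decisions that were genuinely open

* **Denoising algorithm**: the underlying method was only cited, never
  specified, in the source pipeline description; patch PCA across repeated
  measurements was chosen as the self-contained default that matches the
  intent (exploit measurement redundancy), with `gaussian`/`none` dialects.
* **Registration metric/interpolation**: unspecified upstream; NCC +
  trilinear + Powell is robust for mono-modal stacks and fully
  deterministic.
* **Strict vs inclusive atlas threshold**: strict, matching the strict
  intensity rule; configurable.
* **Bilateral volume**: reported as a single total per subject (the
  convention of the mirrored study); per-hemisphere output is a flag.
* **Clinical correlation control set**: both {age, total brain volume} and
  {age, sex} appear in the source reporting; `partial_correlation` takes
  the control list explicitly and neither is canonical.

## Limitations

* **Partial-volume shell bias.** On a binary phantom, any resampling of
  moved measurements leaves a one-voxel shell of intermediate intensities
  around the SNc boundary. When denoising/averaging makes σ_ref small
  relative to the contrast, the strict threshold sits just above
  background and picks that shell up: volumes inflate by roughly 15% at a
  realistic single-measurement CNR of 2 with sub-millimetre motion (see
  `analysis/02`), and more at unrealistically high SNR. The bias is
  common-mode across groups — group separation is preserved — but
  absolute volumes from motion-resampled stacks should be read with this
  in mind. Real, graded-contrast anatomy blunts but does not remove the
  effect.
* **Denoising vs motion.** Across-measurement patch PCA treats
  inter-measurement structure below the noise edge as noise; with large
  noise and small motions, part of the motion signal is absorbed before
  motion correction sees it. The stage order (denoise first) follows the
  mirrored pipeline; with heavy motion and low SNR, `denoise="none"` is
  the safer configuration.
* **Out-of-plane rotation** is intrinsically weakly determined by a
  16-slice slab of smooth structures; recovered rx/ry can be off by ~0.5°
  even when the implied SNc displacement is well under a quarter voxel.
  The displacement metric, not the raw angle, is the meaningful accuracy
  number.
* **Affine-only template mapping.** Nonlinear warps are not estimated;
  synthetic template↔native mappings are affine and known. Results say
  nothing about FNIRT-grade registration accuracy on real anatomy.
* **Statistics assume the simulator's model** (Gaussian residuals,
  additive covariate effects). Calibration and power results transfer to
  real cohorts only insofar as those assumptions hold there.
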