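# Methods

## The inverse problem

Gradient-echo (GRE) phase measures the tissue-induced magnetic field shift,
which is the convolution of the susceptibility distribution chi with the
unit dipole response. In k-space,

    phi(r) = gamma * B0 * TE * F^-1{ D(k) F{chi(r)} },
    D(k)   = 1/3 - (k . b_hat)^2 / |k|^2,

with gamma = 2.675e8 rad/s/T. D vanishes on the magic-angle cone, so direct
inversion amplifies noise into streaks and is blind to the cone content.
Quantitative susceptibility mapping (QSM) is the regularized inversion of
this relation. Conventions used throughout:

- D(0) := 0. Every reconstruction is therefore mean-free over the volume;
  comparisons that need an absolute zero re-reference explicitly (CSF for
  ROI regression, mean-matching for the COSMOS check).
- The frequency lattice is the FFT lattice scaled per axis by the voxel
  size; anisotropic voxels are handled by scaling, never by resampling.
- Susceptibility is carried in ppb and field maps in ppm at every public
  interface. Inside the solver both are dimensionless fractions
  (1 ppb = 1e-9); see "Objective scaling" below.
- Spatial gradients are forward differences with a replicate boundary; the
  divergence used in the normal equations is their exact negative adjoint.

## The constrained solver

The reconstruction minimizes

    f(chi) = 1/2 ||W (F^-1 D F chi - dB)||^2
             + lambda1 * sum_i ||P_i G_i chi||_1
             + lambda2/2 * ||R chi||^2

- `W`: data-fidelity weight, proportional to the echo magnitude and
  normalized to mean 1 over the brain; zero outside the brain, in signal
  voids, and on phase-aliased voxels (below).
- `P_i`: per-axis binary edge-exclusion masks. An edge is a voxel whose
  structural-image or initial-susceptibility derivative exceeds 2.5x the
  noise level of that derivative volume (robust sigma = 1.4826 x MAD within
  the brain; for noiseless piecewise-constant inputs, where the MAD is
  exactly zero, the threshold falls back to a 1e-6 fraction of the peak
  gradient so that "any nonzero gradient is an edge"). Edges are exempt
  from the l1 penalty and therefore never smoothed.
- `R`: protection weight for the l2 term — the structural image normalized
  to [0, 1], hard-zeroed on deep-gray labels and on voxels whose homodyne
  high-pass filtered initial susceptibility exceeds 250 ppb in magnitude
  (veins, microbleeds, calcifications). Protected voxels feel no shrinkage.
- `lambda1 = 0.005 * lambda2` (fixed ratio); per-echo lambda2 defaults are
  the L-curve-selected presets {6.81, 1.47, 3.16, 1.00}e-3 (simulated) and
  {1, 1.47, 1, 1}e-4 (in vivo), in chain order.

### Objective scaling

The regularization weights only have meaning relative to the scale of chi
and dB in the objective. This implementation evaluates the objective on
dimensionless fractional quantities (a susceptibility of 100 ppb enters as
1e-7). On that scale the preset lambda2 values balance the three terms so
that the l1 term dominates noise gradients by orders of magnitude while the
data term retains authority over regional mean values — which is what
produces per-structure standard deviations of a few ppb at SNR 10 together
with unbiased means. Evaluating the same objective on ppm numerals with the
same lambdas would weaken the l1 term by ~1e3 and reproduce neither.

### Optimization

The l1 term is handled by iteratively reweighted least squares (IRLS):
|v| is majorized by v^2 / (2 sqrt(v_prev^2 + eps^2)) + const with
eps = 1e-8 (0.01 ppb/mm — far below any noise or anatomical gradient), and
each outer iteration solves the induced normal equations by conjugate
gradient. The preconditioner is circulant (an FFT-diagonal symbol built
from the dipole spectrum, the mean of W^2 and lambda2 R^2, and the brain
median of the IRLS weights times the Laplacian symbol). A pointwise
diagonal cannot precondition the IRLS-weighted Laplacian that dominates the
spectrum in flat regions; with the circulant symbol the inner solves reach
5e-4 relative residual in a few hundred iterations. Defaults:
outer_max_iter 8, outer_tol 1e-2 (relative chi change), cg_max_iter 250,
cg_tol 5e-4; all config-exposed. Warm-started (chained) echoes converge in
two to three outer iterations; the first echo, started from the noisy
multi-echo iSWIM estimate, typically needs five to seven.

### Multi-echo chain and fusion

Echo order: FA_L TE1 -> FA_H TE1 -> FA_L TE2 -> FA_H TE2. The first echo is
initialized with the multi-echo R2*-weighted iSWIM estimate (the same map
that feeds the P/R masks, built once and kept fixed); each later echo with
the previous echo's solution. Per-echo maps are fused voxelwise with
weights w_i^2, w_i = TE_i exp(-TE_i R2*), where R2* comes from the two-echo
log-ratio of magnitudes per flip angle, averaged over the two flip angles.
An exactly zero voxel in some echo's map contributes no weight there.

## Phase handling

1. **Spatial unwrapping** (short echoes): spectral Laplacian estimate under
   a DCT (mirror) boundary, followed by congruence restoration — the
   estimate is anchored by the circular mean of its residual against the
   wrapped phase and then snapped voxelwise to the nearest 2 pi multiple of
   the measurement. Output is exactly congruent with the input modulo 2 pi.
2. **Temporal bootstrap** (long echoes): the short echo's unwrapped phase
   scaled by TE2/TE1 predicts the long echo's phase; the wrapped long echo
   is snapped to that prediction per voxel. This recovers phase even where
   the long echo's spatial gradient exceeds pi per voxel, which no spatial
   unwrapper can do.
3. **Reliability masking**: faces between in-brain voxels whose wrapped
   phase step exceeds 2 rad mark both voxels unreliable (dilated once,
   because a step that wraps past 2 pi aliases back under the threshold on
   the immediately adjacent face). Unreliable voxels get W = 0: the
   surrounding field and the other echoes determine them. Next to a
   +-3000 ppb, 3 mm insert the Itoh condition is genuinely violated —
   without this masking the corrupted shell drags the recovered insert to
   ~60-85% of its true value; with it, recovery is within a few ppb.
4. **SHARP** background removal (in vivo only; the phantom has no external
   sources): spherical-mean-value filtering with kernel radius 6 voxels,
   truncated-SVD deconvolution at threshold 0.05, output on the mask eroded
   by the kernel radius. The operator is only approximately idempotent
   (reapplication moves the local field by a few percent RMS): masking
   before deconvolution truncates the filtered field at the boundary, which
   is a global spectral perturbation inherent to the windowed formulation.

## Baselines

- **TKD**: k-space division with the kernel clipped at |D| >= 0.1,
  sign-preserving substitution below. Underestimates compact sources and
  streaks; serves as the floor.
- **iSWIM**: TKD followed by four iterations of constrained k-space cone
  refilling. The constraint map keeps voxels whose homodyne high-pass
  (centered 32^3 Hanning window in k-space) exceeds 250 ppb; measured
  k-space on {|D| >= 0.1} is never modified. Neither internal constant is
  published for this use; both are config-exposed.
- **COSMOS**: voxelwise-in-k weighted least squares over >= 3 orientations
  (the B0 direction is rotated, never the volume). Noiseless, it inverts to
  < 2 ppb RMSE after mean re-referencing; the residual DC is the
  unobservable mean under the D(0) = 0 convention.

## The synthetic phantom

The phantom emulates the published simulation recipe: a labeled brain with
WM, GM, deep-gray nuclei (CN, GP, PT, THA, RN, SN, crus cerebri),
ventricles/CSF and two major veins; susceptibility, T1 and proton density
per structure from the published tissue table; five sphere inserts
(microbleeds +1000 ppb/5 mm and +3000 ppb/3 mm frontal, calcifications
-1000 ppb/5 mm and -3000 ppb/3 mm posterior, pineal -3000 ppb/3 mm
midline); R2* = 20/s + 0.125 chi with 40/s and zero proton density inside
the inserts; Ernst-equation magnitudes for the four STAGE echoes (FA 6/24
deg, TE 7.5/8.75 and 17.5/18.75 ms, TR 25 ms, 3 T); complex Gaussian noise
with per-channel sigma = (mean noise-free brain magnitude)/SNR at SNR 10,
per echo.

The geometry itself is a stand-in (the original laboratory model is not
distributed): brain and nuclei are ellipsoids, veins are capsules, placed
at anatomically plausible fractional offsets of the brain semi-axes so the
same anatomy scales across grid presets. Consequences: per-structure voxel
counts, partial-volume structure and streak geometry differ from the
original, so ROI standard deviations, RMSE and SSIM are comparable only in
magnitude, not digit-for-digit; sphere inserts, which are fully specified,
are comparable tightly. What the phantom does not emulate: background
fields from air/tissue interfaces (SHARP is therefore off in the phantom
pipeline), intravoxel dephasing, flow, motion, B1 inhomogeneity, and
realistic noise correlations.

Grid presets: `default` 160x160x96 at 1x1x1.5 mm; `compact` 128x128x80
(the desk-scale evaluation condition used by the acceptance script and the
accuracy tests; a full four-echo reconstruction takes ~10 min on one CPU);
`tiny` 64x64x40 for smoke tests only — its cramped anatomy degrades ROI
accuracy by design.

## Evaluation

RMSE and mean local 3D SSIM (Gaussian window sigma 1.5, K1 = 0.01,
K2 = 0.03, data range from the reference within the mask) over the brain
mask; per-structure mean/sd over full 3D labels; ordinary least squares of
bilateral-averaged deep-gray means against reference values after
subtracting each side's CSF mean. The L-curve module scans log-spaced
lambda2 values, records the weighted data residual and the ratio-weighted
penalty norm, and selects the maximum-curvature grid point (PCHIP
interpolation onto a dense log-lambda grid, three-point finite-difference
curvature, edge samples ignored).

## Known limitations

- The first chain echo converges in ~5-7 outer iterations rather than the
  2-3 of warm-started echoes; a cleaner initial estimate would close that
  gap.
- The reliability mask cannot flag an aliased face whose true step is close
  to an exact multiple of 2 pi on both the face and its neighbors; at the
  phantom's insert sizes the single dilation covers the blind zone, but
  larger or stronger sources may need a second dilation.
- iSWIM's recovered insert means depend visibly on the unpublished homodyne
  window and clip threshold; the defaults here reproduce the qualitative
  ordering (TKD < iSWIM < constrained solver) but not the exact published
  iSWIM means.
- SHARP's output is undefined within one kernel radius of the brain
  boundary (the eroded rim), and its TSVD step is not exactly idempotent.
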