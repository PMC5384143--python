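# Methods

## The signal model

Each voxel's diffusion-weighted magnitude signal is modeled as one
axially symmetric anisotropic tensor — the coherent axon bundle — plus
a discrete spectrum of isotropic tensors:

    S_k / S_0 = f · exp(−b_k λ⊥) · exp(−b_k (λ∥ − λ⊥) cos²Φ_k)
                + Σ_i w_i · exp(−b_k D_i)

where Φ_k is the angle between the k-th diffusion gradient and the
fiber axis, f is the fiber's signal fraction, λ∥ and λ⊥ its axial and
radial diffusivities, and w_i the signal fraction at isotropic
diffusivity D_i. Diffusivities are carried in μm²/ms and b-values in
s/mm²; the 10⁻³ conversion making b·D dimensionless is applied once,
inside the forward model.

The isotropic spectrum is partitioned at an apparent diffusion
coefficient of 0.3 μm²/ms (boundary inclusive on the restricted side):
mass at D ≤ 0.3 is read as restricted diffusion (cellularity), mass at
0.3 < D ≤ 3 as non-restricted diffusion (vasogenic edema and CSF).
The fiber fraction is read as apparent axon density. Whether these
fractions are T2-weighted signal fractions or volume fractions is not
determined by the acquisition; they are treated as signal fractions
throughout.

## Acquisition scheme

The default scheme is 25 quasi-uniform encoding directions plus one
b = 0 volume. Directions come from a deterministic electrostatic
repulsion (antipodally symmetric Coulomb forces, seeded start, fixed
iteration budget), reaching ≈27.9° minimum pairwise axis separation.
Each direction carries a unique b-value: uniformly spaced over
(0, b_max] in direction order, with the largest exactly b_max
(default 2200 s/mm²). The historical 25-direction icosahedral table
this emulates is not publicly tabulated; any measured table can be
supplied as FSL-style bval/bvec files and used unchanged.

The in-plane resolution quoted as "117 μm²" is ambiguous; the package
reads it as a 117-μm pixel edge by default (consistent with nerve
volumes of ~0.08 mm³ spanning ~7 pixels at 0.8-mm slice thickness) and
offers the literal 117-μm²-area reading as a config option
(`voxel.in_plane_interpretation: area_um2`).

## The inversion

Fitting one voxel proceeds in three stages:

1. **Fiber axis.** Principal eigenvector of a preliminary single-tensor
   fit. If the preliminary FA is below 0.1 the voxel carries no usable
   orientation information; it is flagged near-isotropic and assigned
   the through-plane axis as a deterministic tie-break.
2. **Diffusivity search.** A bounded 2-D Nelder–Mead over (λ∥, λ⊥)
   (bounds [0.5, 3.0] and [0.0, 1.0] μm²/ms), multistarted from a 3×3
   interior grid over the bounds, ftol 10⁻⁸, at most 500 evaluations
   per start. Out-of-bounds and λ⊥ > λ∥ proposals are clipped with a
   smooth quadratic penalty. The objective is the residual of the
   inner problem below.
3. **Spectrum.** At fixed fiber geometry, nonnegative least squares on
   a design whose first column is the fiber decay and whose remaining
   columns are isotropic decays on a grid of 31 diffusivities
   (0 to 3 μm²/ms, step 0.1 — finer than the 0.3 partition):

       min_{w ≥ 0} ‖A w − S‖² + α ‖w_iso‖²,  α = (c · σ_max(A))²

   Tikhonov regularization acts on the spectrum weights only — the
   ill-posed part of the deconvolution; the fiber weight is well
   determined and left unpenalized, which keeps the fiber fraction
   unbiased in noise-free recovery (penalizing all weights biases it
   by 0.02–0.1 at realistic mixtures). The relative ridge weight c
   defaults to 0.01 of the design's spectral norm. Fitted weights are
   normalized by their total so fractions sum to one.

The inner solver is Lawson–Hanson active-set NNLS, compiled with
numba because the outer search evaluates it thousands of times per
voxel. Two variants are used: with the ridge on, the walk runs on the
normal equations (diagonal conditioned by α) and is warm-started from
the unconstrained solution since the regularized solution is dense;
with the ridge off — the exactness path used by the oracle tests — it
runs on the equilibrated columns of A itself with thin-QR subproblem
solves, residual-first gradient evaluation, and an anti-cycling rule
for degenerate pivots, reaching KKT optimality at machine scale.
scipy's NNLS is used in the test suite as an independent oracle and
never inside the package.

On this 26-volume design the 31-column dictionary is underdetermined:
noise-free mixtures of three or more nearby interior diffusivities
admit a polytope of exact nonnegative solutions, so per-weight
recovery is only meaningful for configurations the model is built to
separate (restricted, hindered, free pools). The oracle tests sample
those.

## Magnitude noise

Rician noise is simulated as sqrt((ν+n₁)² + n₂²) with n₁, n₂ zero-mean
Gaussians of standard deviation σ = S₀/SNR. The pipeline estimates σ
from signal-free background voxels (Rayleigh mean σ√(π/2)) and feeds
the spectral fit a signed bias-corrected signal
ν̂ = sign(M²−2σ²)·√|M²−2σ²|, which is close to mean-unbiased at all
signal levels; hard censoring at zero instead inflates apparent decay
along the fiber. Without any correction, the high-b noise floor
masquerades as restricted-fraction signal. The single-tensor
comparator fits the raw magnitude (its log-linear estimator needs
positive values), matching common practice.

## The single-tensor comparator

Weighted linear least squares on the log signal with one reweighting
pass (weights = squared predicted signal); volumes with non-positive
signal are excluded, at least seven usable volumes are required, and
negative eigenvalues are clamped to zero with a degenerate flag so
cohort tables stay rectangular under noise. This comparator is
deliberately susceptible to the inflammation confound: restricted
isotropic signal drags its λ∥ down and fast isotropic signal pushes
its λ⊥ up, monotonically in the contaminating mass.

## Pipeline fit stage: the coherent-bundle estimator

At a realistic SNR of 30, fully per-voxel joint estimation of
(λ∥, λ⊥, spectrum) shows a one-sided isotropic-mass bias of ≈+0.05 at
near-pure-fiber voxels: nonnegative mass can only be added, and the
λ⊥/edema degeneracy lets the spectrum chase noise. Since the optic
nerve is a single coherent bundle, the pipeline's default fit stage
(`fit_mode: bundle`) estimates the fiber axis and diffusivities once
per nerve from the ROI-mean signal — SNR higher by √(voxel count) —
and then refits only the spectrum and fiber weight per voxel at those
shared parameters. The λ∥/λ⊥/FA maps are constant over a nerve by
construction; the fraction maps remain per-voxel. `fit_mode: voxel`
restores fully independent per-voxel fits, and the per-voxel
`fit_dbsi` API is unchanged. With the bundle estimator the cohort-mean
axon-loss estimate tracks the generated truth to within a few
percentage points at SNR 30 (the swelling-with-loss test measures the
gap); fully per-voxel fitting underestimates the loss noticeably more
because its baseline fiber fractions are biased low.

## Synthetic cohort

The phantom emulates the study design end to end: 8 mice × 2 eyes ×
3 timepoints (naive baseline; onset of optic neuritis in the first
eye; onset in the fellow eye), one 0.8-mm slice per scan, 117-μm
pixels, one nerve per dataset as a disc of through-plane fiber voxels
surrounded by a two-voxel free-water rim (D = 3.0 μm²/ms) and
noise-only background, Rician noise at SNR 30.

Timepoint group means follow the cohort tables the model targets:
λ∥ 1.79/1.82/1.57, λ⊥ 0.17/0.20/0.21 μm²/ms; nerve volumes
0.08/0.10/0.12 mm³ (discretized to whole voxels: 7/9/11). Isotropic
truth sits at two discrete pools — restricted 0.15, non-restricted
1.5 μm²/ms — matching the two-pool reading of cellularity and edema
and making recovery oracles exact. Per-nerve parameters are drawn
around the group means with the reported between-animal SDs, and
per-voxel truth is drawn around the per-nerve means with the same
spread (within-nerve heterogeneity is not reported anywhere; i.i.d.
voxels are an explicit assumption).

Two disease effects are generated separately:

* **Swelling** raises nerve volume (baseline → +25% → +50%) and
  dilutes the fiber fraction at constant true axon volume;
* **Axonal loss** multiplies the true axon volume (nerve volume ×
  fiber fraction) by (1 − loss), default 16% at time 1 and 17% at
  time 2, applied exactly in the bookkeeping (the printed center-ROI
  isotropic fractions at later timepoints are internally inconsistent
  with the printed volumes and losses; the volume/loss bookkeeping is
  authoritative here and the isotropic mass absorbs the difference at
  the preset restricted:non-restricted ratio).

One randomly chosen second eye never converts and keeps baseline truth
at all timepoints but remains in every analysis, mirroring the study's
single non-converting eye. Visual acuity is a linear function of the
true fiber fraction (slope 0.6 c/d, intercept −0.17 c/d, noise SD
0.01 c/d, clamped to [0, 0.5] c/d), chosen so baseline maps well above
the 0.25 c/d impairment threshold and onset-level fiber fractions map
below it. Histology readouts are linear couplings plus Gaussian noise:
SMI-31 area fraction tracks λ∥ (slope 0.30), MBP tracks λ⊥ negatively
(−1.5), SMI-312 tracks fiber fraction (0.5), DAPI counts track the
restricted fraction (20 000 counts per unit fraction), each clamped to
its valid range.

What the phantom does not emulate: partial-volume mixing at the
nerve/CSF boundary, anatomical shape (chiasm, curvature), spatially
correlated truth, motion/eddy artifacts, multi-slice geometry, or
relaxation-time effects. Passing tests therefore demonstrate
correctness of the estimators under the stated generative model, not
robustness to those real-data effects.

## Statistics

The study's mixed random-effects repeated-measures model (AR(1)
covariance, Kenward–Rogers degrees of freedom) is off-the-shelf
statistics rather than part of the method under test; the package
replaces it with eye-averaged paired contrasts: each mouse contributes
the mean of its eyes per timepoint and a paired t-test is run on the
per-mouse (timepoint − baseline) differences. Mice missing an eye are
kept with their single eye and flagged. Degenerate zero-variance
differences are flagged with p at the smallest positive float. The
cohort CSV is long-format, so an external mixed-model refit is a
one-liner in any stats package. Histology couplings are assessed by
ordinary least squares with a two-sided slope test. All tests are
two-sided; no multiplicity correction is applied.

Type-I calibration of the paired contrast is checked on 2000 null
cohorts (mouse random effect + measurement noise, no time effect).

## Problem sizes used by the test and acceptance suites

Recovery checks use 100 noise-free and 200 SNR-30 voxels; the
swelling-with-loss property uses 20 full cohorts (8 mice × 2 eyes ×
3 timepoints, ≈430 voxel fits each); calibration uses 2000 simulated
null cohorts; the determinism check runs the complete default study
twice. These sizes give stable Monte-Carlo estimates for every
asserted property while keeping a full run of the suite in the
minutes range on a single core.

## Known limitations

* Per-voxel fraction estimates at SNR 30 are biased: spurious
  isotropic mass ≈+0.05 appears at near-pure-fiber voxels
  (nonnegativity is one-sided), and the restricted fraction is
  under-recovered by up to ≈0.1 when it is large (≥0.2). The latter is
  an acquisition-design effect: with a unique b-value per direction,
  separating restricted water from the fiber compartment requires a
  volume that is simultaneously high-b and near-parallel to the
  fiber, which for most fiber orientations does not exist; the
  resulting misfit sits on one or two volumes and is absorbed by a
  small λ∥ shift. Group means inherit these biases; the bundle
  estimator mitigates but does not remove them.
* The spectrum grid is a discretization; truth between grid points
  splits mass across neighbors (fractions are preserved, peak
  positions are not).
* The λ⊥-restricted-pool degeneracy (fiber λ⊥ numerically equal to a
  restricted diffusivity) is structurally unidentifiable in any
  single-voxel fit of this design.
* Axon volume = nerve volume × fiber fraction equates a signal
  fraction with a volume fraction; any T2 difference between
  compartments would bias it in real data.
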