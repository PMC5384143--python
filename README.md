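# dbspectra

Multi-compartment diffusion-MRI analysis of optic neuritis: diffusion
basis spectrum imaging (DBSI) model fitting, a conventional DTI
comparator, synthetic longitudinal optic-nerve phantoms with known
ground truth, swelling-aware axon-volume quantification, and cohort
statistics.

## The problem

In inflammatory demyelinating disease (experimental autoimmune
encephalomyelitis in mice; multiple sclerosis in humans), optic-nerve
voxels contain a mixture of pathologies: axonal injury and loss,
demyelination, cellular infiltration, and vasogenic edema. A
single-tensor DTI fit folds all of them into three eigenvalues, so
inflammation masquerades as axonal injury (λ∥ drops) and demyelination
(λ⊥ rises), and nerve swelling dilutes apparent axon density. This
package implements the spectral alternative and quantifies exactly
that failure mode.

## The model

Each voxel is one axially symmetric fiber tensor plus a spectrum of
isotropic tensors:

S_k = S₀ [ f·e^(−b_k λ⊥)·e^(−b_k (λ∥−λ⊥) cos²Φ_k) + Σᵢ wᵢ·e^(−b_k Dᵢ) ]

with Φ_k the angle between gradient k and the fiber axis. The fitted
spectrum w(D) on D ∈ [0, 3] μm²/ms is partitioned at 0.3 μm²/ms into a
**restricted fraction** (cellularity) and a **non-restricted fraction**
(edema/CSF); f is the **fiber fraction** (apparent axon density), and
**axon volume** = nerve volume × fiber fraction is the longitudinal
axonal-loss readout that stays valid while the nerve swells. The
inversion is a regularized nonnegative spectral deconvolution inside a
bounded 2-D search over (λ∥, λ⊥); see `docs/methods.md` for every
numerical choice.

## Worked example

Fit one voxel whose ground truth mimics an inflamed nerve at acute
optic neuritis — fiber λ∥ = 1.82, λ⊥ = 0.20 μm²/ms, 17% isotropic
contamination (8% cells at D = 0.15, 9% edema at D = 1.5):

```python
import numpy as np
from dbspectra import (AnisotropicComponent, IsotropicSpectrum, VoxelTruth,
                       build_default_scheme, predict_signal, fit_dbsi, fit_dti)

scheme = build_default_scheme()          # 25 directions + one b=0, b_max 2200
truth = VoxelTruth(
    AnisotropicComponent([0.0, 0.0, 1.0], 1.82, 0.20, 0.83),
    IsotropicSpectrum([0.15, 1.5], [0.08, 0.09]),
)
signal = predict_signal(truth, scheme)
dbsi = fit_dbsi(signal, scheme)
dti = fit_dti(signal, scheme)
print(f"DBSI: lambda_par={dbsi.lambda_par:.3f} fiber={dbsi.fiber_fraction:.3f} "
      f"restricted={dbsi.restricted_fraction:.3f}")
print(f"DTI:  lambda_par={dti.lambda_par:.3f} lambda_perp={dti.lambda_perp:.3f}")
```

prints

```
DBSI: lambda_par=1.798 fiber=0.831 restricted=0.045
DTI:  lambda_par=1.551 lambda_perp=0.243
```

The spectral fit recovers the fiber's true λ∥ (1.798 vs 1.82) and
fraction (0.831 vs 0.83) despite the contamination, while the
single-tensor fit on the *same signal* reports λ∥ = 1.551 — a spurious
15% "axonal injury" that is really inflammation.

## The full pipeline

```bash
dbspectra run --seed 4 --out-dir study_run
```

simulates the default longitudinal cohort (8 mice × 2 eyes × 3
timepoints: naive baseline, onset of optic neuritis in the first eye,
onset in the fellow eye; Rician noise at SNR 30), fits DTI and DBSI
maps per nerve, quantifies ROI means, nerve volume and axon volume,
and runs paired change-from-baseline contrasts plus histology
regressions. Stages are also available separately (`simulate`, `fit`,
`quantify`, `stats`) and consume each other's on-disk outputs, so real
NIfTI data with FSL-style bval/bvec tables can enter at the `fit`
stage. Everything is configurable through a YAML file:

```yaml
seed: 4
scheme: {n_directions: 25, b_max: 2200.0}
voxel: {in_plane: 117.0, in_plane_interpretation: edge_um, slice_thickness_mm: 0.8}
dbsi: {grid_step: 0.1, restricted_threshold: 0.3, regularization_weight: 0.01}
cohort: {n_mice: 8, snr: 30.0, axon_loss_time1: 0.16, axon_loss_time2: 0.17}
```

Outputs: per-dataset NIfTI parametric maps (`dbsi_lambda_par`,
`dbsi_fiber_fraction`, `dti_fa`, ...), a long-format
`cohort_metrics.csv` (one row per mouse × eye × timepoint: `mouse`,
`eye`, `timepoint`, `va`, center-ROI means of every metric,
`nerve_volume`, `fiber_fraction_whole_nerve`, `axon_volume`,
`percent_axon_volume_change_from_baseline`, ...), `contrasts.csv`,
`regressions.csv`, a plain-text summary and a JSON manifest with a
content hash of every output file — repeated runs at a fixed seed are
manifest-identical.

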