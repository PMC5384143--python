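"""Forward diffusion-signal model for a coherent fiber bundle.

Each voxel is one axially symmetric anisotropic tensor (the fiber,
e.g. retinal ganglion cell axons in optic nerve) plus a discrete
spectrum of isotropic tensors covering restricted diffusion (cells),
hindered diffusion (edema), and free water (CSF):

    S_k / S_0 = f · exp(-b_k λ⊥) · exp(-b_k (λ∥ - λ⊥) cos²Φ_k)
                + Σ_i w_i · exp(-b_k D_i)

with Φ_k the angle between the k-th gradient and the fiber axis.
Diffusivities are carried in μm²/ms and b-values in s/mm²; the 1e-3
conversion making b·D dimensionless is applied here, once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import GradientScheme

__all__ = [
    "AnisotropicComponent",
    "IsotropicSpectrum",
    "VoxelTruth",
    "predict_signal",
    "add_rician_noise",
    "rician_bias_correct",
    "B_CONVERSION",
]

#: s/mm² × μm²/ms → dimensionless exponent.
B_CONVERSION = 1e-3

_FRACTION_TOL = 1e-6


@dataclass(frozen=True)
class AnisotropicComponent:
    """Axially symmetric fiber tensor with a signal fraction."""

    principal_direction: np.ndarray
    lambda_par: float
    lambda_perp: float
    fraction: float

    def __post_init__(self) -> None:
        direction = np.asarray(self.principal_direction, dtype=float).ravel()
        if direction.size != 3:
            raise ValueError("principal_direction must be a 3-vector")
        norm = np.linalg.norm(direction)
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise ValueError("principal_direction must be unit-norm")
        if not 0.0 <= self.lambda_perp <= self.lambda_par:
            raise ValueError("requires lambda_par >= lambda_perp >= 0")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        object.__setattr__(self, "principal_direction", direction)


@dataclass(frozen=True)
class IsotropicSpectrum:
    """Discrete isotropic diffusivity spectrum f(D) on an ordered grid."""

    grid: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float).ravel()
        weights = np.asarray(self.weights, dtype=float).ravel()
        if grid.size != weights.size:
            raise ValueError("grid and weights must align")
        if grid.size and (np.any(np.diff(grid) <= 0) or grid[0] < 0):
            raise ValueError("grid must be strictly increasing and non-negative")
        if np.any(weights < -_FRACTION_TOL):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "weights", np.maximum(weights, 0.0))

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


@dataclass(frozen=True)
class VoxelTruth:
    """Generative per-voxel parameters: fiber + isotropic spectrum + s0."""

    aniso: AnisotropicComponent
    iso: IsotropicSpectrum
    s0: float = 1.0

    def __post_init__(self) -> None:
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        total = self.aniso.fraction + self.iso.total_weight
        if abs(total - 1.0) > _FRACTION_TOL:
            raise ValueError(f"fractions must sum to 1 (got {total:.8f})")


def predict_signal(truth: VoxelTruth, scheme: GradientScheme) -> np.ndarray:
    """Noise-free signal for every volume of ``scheme``.

    Returns an array of length ``scheme.n_volumes``; the b=0 entry
    equals ``truth.s0`` for a normalized voxel.
    """
    b = scheme.bvalues * B_CONVERSION
    cos_phi = scheme.directions @ truth.aniso.principal_direction
    lpar, lperp = truth.aniso.lambda_par, truth.aniso.lambda_perp
    fiber = truth.aniso.fraction * np.exp(-b * lperp - b * (lpar - lperp) * cos_phi**2)
    iso = np.exp(-np.outer(b, truth.iso.grid)) @ truth.iso.weights
    return truth.s0 * (fiber + iso)


def add_rician_noise(
    signal: np.ndarray, snr: float, seed, s0: float | None = None
) -> np.ndarray:
    """Corrupt a magnitude signal with Rician noise.

    SNR is defined on the unweighted volume: sigma = s0 / snr, with
    ``s0`` defaulting to ``signal.max()``. Each value v is replaced by
    sqrt((v + n1)² + n2²) with n1, n2 ~ N(0, sigma²); identical
    (signal, snr, seed) gives bit-identical output. ``seed`` is
    anything ``numpy.random.default_rng`` accepts.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    signal = np.asarray(signal, dtype=float)
    if s0 is None:
        s0 = float(signal.max())
    sigma = s0 / snr
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def rician_bias_correct(
    signal: np.ndarray, sigma: float, mode: str = "signed"
) -> np.ndarray:
    """Moment-based Rician bias correction of a magnitude signal.

    For Rician magnitude data, E[M²] = ν² + 2σ², so the underlying
    amplitude is estimated from M² − 2σ². ``mode='censored'`` clamps
    negative differences to zero (always non-negative, but upward
    biased near the noise floor and downward censored exactly at it);
    ``mode='signed'`` (default) keeps sign(M² − 2σ²)·sqrt(|M² − 2σ²|),
    which is close to mean-unbiased everywhere and is the right input
    for least-squares fits that tolerate small negative values.
    ``sigma`` is the per-channel noise standard deviation, typically
    estimated from background voxels (whose Rayleigh mean is
    σ·sqrt(π/2)).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if mode not in ("signed", "censored"):
        raise ValueError("mode must be 'signed' or 'censored'")
    signal = np.asarray(signal, dtype=float)
    diff = signal**2 - 2.0 * sigma**2
    if mode == "censored":
        return np.sqrt(np.maximum(diff, 0.0))
    return np.sign(diff) * np.sqrt(np.abs(diff))
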