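"""Conventional single-tensor DTI fit (the confounded comparator).

In inflamed white matter a single tensor absorbs cell infiltration and
edema into its eigenvalues: restricted isotropic signal drags the fitted
axial diffusivity down and fast isotropic signal pushes the radial
diffusivity up, which is exactly the confound the spectral model is
built to avoid. This module provides that comparator: a weighted
log-linear least-squares tensor fit with one reweighting pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import GradientScheme
from .signal_model import B_CONVERSION

__all__ = ["DTIFit", "FitError", "fit_dti", "fractional_anisotropy"]


class FitError(RuntimeError):
    """Raised when a tensor fit cannot be performed."""


@dataclass(frozen=True)
class DTIFit:
    """Single-tensor fit: eigenvalues in μm²/ms, sorted descending."""

    eigenvalues: np.ndarray
    principal_direction: np.ndarray
    s0_hat: float
    degenerate: bool
    n_used: int

    @property
    def lambda_par(self) -> float:
        return float(self.eigenvalues[0])

    @property
    def lambda_perp(self) -> float:
        return float(0.5 * (self.eigenvalues[1] + self.eigenvalues[2]))

    @property
    def md(self) -> float:
        return float(self.eigenvalues.mean())

    @property
    def fa(self) -> float:
        return fractional_anisotropy(self.eigenvalues)


def fractional_anisotropy(eigenvalues: np.ndarray) -> float:
    """Standard FA of three tensor eigenvalues, clipped to [0, 1]."""
    ev = np.asarray(eigenvalues, dtype=float)
    denom = np.sqrt((ev**2).sum())
    if denom == 0.0:
        return 0.0
    md = ev.mean()
    fa = np.sqrt(1.5 * ((ev - md) ** 2).sum()) / denom
    return float(np.clip(fa, 0.0, 1.0))


def _design_matrix(scheme: GradientScheme) -> np.ndarray:
    b = scheme.bvalues * B_CONVERSION
    g = scheme.directions
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2.0 * b * g[:, 0] * g[:, 1],
            -2.0 * b * g[:, 0] * g[:, 2],
            -2.0 * b * g[:, 1] * g[:, 2],
        ]
    )


def fit_dti(signal: np.ndarray, scheme: GradientScheme) -> DTIFit:
    """Fit a single diffusion tensor by weighted log-linear least squares.

    An ordinary log-linear solve is refined by one reweighting pass with
    weights equal to the squared predicted signal (the standard WLS
    linearization of the Rician-free noise model). Volumes with
    non-positive signal are excluded; fewer than 7 usable volumes is an
    error. Negative eigenvalues are clamped to zero and flagged.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    if signal.size != scheme.n_volumes:
        raise FitError(
            f"signal length {signal.size} does not match scheme with "
            f"{scheme.n_volumes} volumes"
        )
    usable = signal > 0
    if usable.sum() < 7:
        raise FitError(f"only {int(usable.sum())} usable volumes; need >= 7")
    X = _design_matrix(scheme)[usable]
    y = np.log(signal[usable])

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    weights = np.exp(X @ beta) ** 2  # one reweighting pass
    Xw = X * weights[:, None]
    beta = np.linalg.solve(X.T @ Xw, Xw.T @ y)

    tensor = np.array(
        [
            [beta[1], beta[4], beta[5]],
            [beta[4], beta[2], beta[6]],
            [beta[5], beta[6], beta[3]],
        ]
    )
    evals, evecs = np.linalg.eigh(tensor)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    degenerate = bool(evals[-1] < 0)
    evals = np.maximum(evals, 0.0)
    return DTIFit(
        eigenvalues=evals,
        principal_direction=evecs[:, 0],
        s0_hat=float(np.exp(beta[0])),
        degenerate=degenerate,
        n_used=int(usable.sum()),
    )
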