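"""Diffusion-encoding schemes and FSL-style gradient-table I/O.

A :class:`GradientScheme` pairs unit gradient directions with per-volume
b-values. The default scheme mirrors a small-animal optic-nerve protocol:
25 quasi-uniform encoding directions, each carrying a distinct b-value up
to a 2200 s/mm² maximum, plus a single unweighted (b = 0) volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GradientScheme",
    "InvalidSchemeError",
    "build_default_scheme",
    "repulsion_directions",
    "min_angular_separation",
    "load_bvals_bvecs",
    "save_bvals_bvecs",
]

#: RNG seed for the deterministic electrostatic-repulsion direction layout.
_REPULSION_SEED = 20_170_407

_UNIT_TOL = 1e-9


class InvalidSchemeError(ValueError):
    """Raised when a gradient scheme violates its construction contract."""


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion acquisition: unit directions plus aligned b-values.

    Parameters
    ----------
    directions : (V, 3) array
        Unit gradient directions; the zero vector is permitted only for
        b = 0 volumes.
    bvalues : (V,) array
        Diffusion weightings in s/mm², aligned with ``directions``.
    """

    directions: np.ndarray
    bvalues: np.ndarray
    name: str = field(default="custom")

    def __post_init__(self) -> None:
        directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        bvalues = np.asarray(self.bvalues, dtype=float).ravel()
        if directions.shape[1] != 3:
            raise InvalidSchemeError("directions must be (V, 3)")
        if directions.shape[0] != bvalues.size:
            raise InvalidSchemeError("directions and bvalues must align")
        if np.any(bvalues < 0):
            raise InvalidSchemeError("b-values must be non-negative")
        norms = np.linalg.norm(directions, axis=1)
        weighted = bvalues > 0
        if np.any(np.abs(norms[weighted] - 1.0) > _UNIT_TOL):
            raise InvalidSchemeError("weighted directions must be unit-norm")
        object.__setattr__(self, "directions", directions)
        object.__setattr__(self, "bvalues", bvalues)

    @property
    def n_volumes(self) -> int:
        return self.bvalues.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues == 0.0

    @property
    def b_max(self) -> float:
        return float(self.bvalues.max())


def min_angular_separation(directions: np.ndarray) -> float:
    """Smallest pairwise angle (degrees) between direction axes.

    Directions are treated as axes: ``g`` and ``-g`` encode the same
    diffusion weighting, so the absolute dot product is used.
    """
    d = np.asarray(directions, dtype=float)
    dots = np.abs(d @ d.T)
    np.fill_diagonal(dots, 0.0)
    return float(np.degrees(np.arccos(np.clip(dots.max(), -1.0, 1.0))))


def repulsion_directions(
    n: int, seed: int = _REPULSION_SEED, n_iter: int = 1000, step: float = 0.01
) -> np.ndarray:
    """Quasi-uniform unit directions by electrostatic repulsion.

    Antipodally symmetric Coulomb forces (each point repels both the
    others and their antipodes) are relaxed by projected gradient steps
    from a seeded random start, so the layout is deterministic.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    for _ in range(n_iter):
        diff = x[:, None, :] - x[None, :, :]      # repulsion from points
        anti = x[:, None, :] + x[None, :, :]      # ... and from antipodes
        d3 = np.linalg.norm(diff, axis=-1) ** 3
        a3 = np.linalg.norm(anti, axis=-1) ** 3
        np.fill_diagonal(d3, np.inf)
        np.fill_diagonal(a3, np.inf)
        force = (diff / d3[..., None]).sum(axis=1) + (anti / a3[..., None]).sum(axis=1)
        # project the force onto the tangent plane before stepping
        force -= (force * x).sum(axis=1, keepdims=True) * x
        x = x + step * force
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    return x


def build_default_scheme(n_directions: int = 25, b_max: float = 2200.0) -> GradientScheme:
    """Build the default multi-b scheme: one b=0 plus ``n_directions`` volumes.

    Each weighted direction carries a unique b-value; b-values increase
    strictly with direction index, are uniformly spaced over
    ``(0, b_max]``, and the largest equals ``b_max`` exactly.

    Raises
    ------
    InvalidSchemeError
        If ``n_directions`` < 6 (single tensor underdetermined) or
        ``b_max`` is not positive.
    """
    if n_directions < 6:
        raise InvalidSchemeError(
            f"n_directions={n_directions}: at least 6 directions are needed "
            "to determine a diffusion tensor"
        )
    if b_max <= 0:
        raise InvalidSchemeError("b_max must be positive")
    dirs = repulsion_directions(n_directions)
    bvals = b_max * np.arange(1, n_directions + 1) / n_directions
    directions = np.vstack([np.zeros(3), dirs])
    bvalues = np.concatenate([[0.0], bvals])
    return GradientScheme(directions, bvalues, name=f"default-{n_directions}")


def load_bvals_bvecs(bval_path: str | Path, bvec_path: str | Path) -> GradientScheme:
    """Read an FSL-style gradient table (bval: one row; bvec: three rows)."""
    bval_path, bvec_path = Path(bval_path), Path(bvec_path)
    for p in (bval_path, bvec_path):
        if not p.exists():
            raise FileNotFoundError(f"gradient table file not found: {p}")
    bvalues = np.loadtxt(bval_path, ndmin=1)
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous square table: FSL convention stores one row per axis
        bvecs = bvecs.T
    return GradientScheme(bvecs, bvalues, name=bval_path.stem)


def save_bvals_bvecs(
    scheme: GradientScheme, bval_path: str | Path, bvec_path: str | Path
) -> None:
    """Write the scheme as FSL-style bval/bvec text files."""
    np.savetxt(bval_path, scheme.bvalues[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.10f")
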