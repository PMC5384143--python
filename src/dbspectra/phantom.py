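"""Synthetic longitudinal optic-nerve phantoms with known ground truth.

The generator emulates the study conditions the pipeline is built for:
a single 0.8-mm slice through a mouse optic nerve at 117-μm in-plane
resolution, imaged with a 25-direction multi-b scheme plus one b=0, at
three timepoints — naive baseline, onset of optic neuritis in the first
eye (time 1) and onset in the fellow eye (time 2). Each nerve is a disc
of fiber voxels (axis through-plane) surrounded by free-water CSF;
per-voxel truth is drawn around timepoint group means.

Two disease effects are generated separately so tests can probe each:

* swelling — inflammation adds isotropic (restricted + non-restricted)
  signal mass and enlarges the nerve, diluting the fiber fraction at
  constant true axon volume;
* axonal loss — the true axon volume (nerve volume × fiber fraction)
  drops by a configured percentage (defaults 16% at time 1, 17% at
  time 2), implemented exactly in the cohort bookkeeping.

Visual acuity and immunohistochemistry readouts are emulated as linear
couplings to the truth parameters plus Gaussian noise, so regression
recovery has a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .acquisition import GradientScheme, build_default_scheme
from .signal_model import (
    AnisotropicComponent,
    IsotropicSpectrum,
    VoxelTruth,
    add_rician_noise,
    predict_signal,
)

__all__ = [
    "NerveTimepointConfig",
    "CohortConfig",
    "VACoupling",
    "StainCoupling",
    "HistologyCoupling",
    "PhantomDataset",
    "TIMEPOINT_PRESETS",
    "make_nerve",
    "make_cohort",
    "make_histology",
]

_Z = np.array([0.0, 0.0, 1.0])

TIMEPOINTS = ("baseline", "time1", "time2")


@dataclass(frozen=True)
class NerveTimepointConfig:
    """Group-mean truth for one nerve at one timepoint.

    Diffusivities in μm²/ms, volumes in mm³. ``sd`` holds the
    between-voxel standard deviation per parameter.
    """

    mean_lambda_par: float
    mean_lambda_perp: float
    mean_fiber_fraction: float
    mean_restricted_fraction: float
    mean_nonrestricted_fraction: float
    nerve_volume: float
    sd: dict = field(
        default_factory=lambda: {
            "lambda_par": 0.12,
            "lambda_perp": 0.03,
            "fiber_fraction": 0.03,
            "restricted_fraction": 0.01,
            "nonrestricted_fraction": 0.01,
        }
    )
    restricted_D: float = 0.15
    nonrestricted_D: float = 1.5
    csf_D: float = 3.0

    def __post_init__(self) -> None:
        total = (
            self.mean_fiber_fraction
            + self.mean_restricted_fraction
            + self.mean_nonrestricted_fraction
        )
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mean fractions must sum to 1 (got {total:.8f})")
        if self.nerve_volume <= 0:
            raise ValueError("nerve_volume must be positive")


#: Per-timepoint group means: a naive control nerve, onset of optic
#: neuritis in the first eye, and onset in the fellow eye. Diffusivity
#: and isotropic-fraction means follow the multi-compartment readouts
#: of the corresponding cohort; nerve volumes swell 0.08 → 0.10 → 0.12 mm³.
TIMEPOINT_PRESETS: dict[str, NerveTimepointConfig] = {
    "baseline": NerveTimepointConfig(
        mean_lambda_par=1.79,
        mean_lambda_perp=0.17,
        mean_fiber_fraction=0.97,
        mean_restricted_fraction=0.01,
        mean_nonrestricted_fraction=0.02,
        nerve_volume=0.08,
    ),
    "time1": NerveTimepointConfig(
        mean_lambda_par=1.82,
        mean_lambda_perp=0.20,
        mean_fiber_fraction=0.93,
        mean_restricted_fraction=0.03,
        mean_nonrestricted_fraction=0.04,
        nerve_volume=0.10,
    ),
    "time2": NerveTimepointConfig(
        mean_lambda_par=1.57,
        mean_lambda_perp=0.21,
        mean_fiber_fraction=0.83,
        mean_restricted_fraction=0.08,
        mean_nonrestricted_fraction=0.09,
        nerve_volume=0.12,
    ),
}


@dataclass(frozen=True)
class VACoupling:
    """Linear link from true fiber fraction to visual acuity (c/d).

    Defaults are chosen so that baseline fiber fractions map well above
    the 0.25 c/d impairment threshold while onset-level fiber fractions
    (diluted by swelling and reduced by loss) map below it.
    """

    slope: float = 0.6
    intercept: float = -0.17
    noise_sd: float = 0.01
    va_min: float = 0.0
    va_max: float = 0.5


@dataclass(frozen=True)
class StainCoupling:
    """Linear link from one truth parameter to one stain readout."""

    truth: str
    slope: float
    intercept: float
    noise_sd: float
    lo: float = 0.0
    hi: float = np.inf


@dataclass(frozen=True)
class HistologyCoupling:
    """Per-stain couplings: axon markers, myelin, and nuclear counts."""

    smi31: StainCoupling = field(
        default_factory=lambda: StainCoupling("lambda_par", 0.30, -0.20, 0.02, 0.0, 1.0)
    )
    mbp: StainCoupling = field(
        default_factory=lambda: StainCoupling("lambda_perp", -1.5, 0.70, 0.03, 0.0, 1.0)
    )
    smi312: StainCoupling = field(
        default_factory=lambda: StainCoupling("fiber_fraction", 0.5, 0.05, 0.02, 0.0, 1.0)
    )
    dapi: StainCoupling = field(
        default_factory=lambda: StainCoupling("restricted_fraction", 20000.0, 800.0, 300.0)
    )

    def items(self):
        return (
            ("smi31", self.smi31),
            ("mbp", self.mbp),
            ("smi312", self.smi312),
            ("dapi", self.dapi),
        )


@dataclass(frozen=True)
class CohortConfig:
    """Longitudinal cohort design and disease-effect sizes."""

    n_mice: int = 8
    eyes_per_mouse: int = 2
    timepoints: tuple[str, ...] = TIMEPOINTS
    snr: float = 30.0
    voxel_dims: tuple[float, float, float] = (0.117, 0.117, 0.8)
    axon_loss_time1: float = 0.16
    axon_loss_time2: float = 0.17
    va_coupling: VACoupling = field(default_factory=VACoupling)
    histology_coupling: HistologyCoupling = field(default_factory=HistologyCoupling)
    include_nonconverting_eye: bool = True
    grid_shape: tuple[int, int] = (12, 12)

    def __post_init__(self) -> None:
        if self.n_mice < 1 or self.eyes_per_mouse < 1:
            raise ValueError("counts must be >= 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        for loss in (self.axon_loss_time1, self.axon_loss_time2):
            if not 0.0 <= loss < 1.0:
                raise ValueError("axon loss fractions must lie in [0, 1)")


@dataclass
class PhantomDataset:
    """One simulated scan: image, masks, truth maps and covariates."""

    dwi: np.ndarray  # (nx, ny, 1, n_volumes)
    nerve_mask: np.ndarray  # (nx, ny) bool
    center_roi_mask: np.ndarray  # (nx, ny) bool
    truth_maps: dict  # name -> (nx, ny) float, NaN off-nerve
    voxel_truths: dict  # (i, j) -> VoxelTruth, nerve and CSF voxels
    scheme: GradientScheme
    voxel_dims: tuple[float, float, float]
    snr: float
    seed: int
    covariates: dict = field(default_factory=dict)

    @property
    def noise_free(self) -> np.ndarray:
        """Regenerate the noise-free signal image from the stored truth."""
        out = np.zeros_like(self.dwi)
        for (i, j), truth in self.voxel_truths.items():
            out[i, j, 0, :] = predict_signal(truth, self.scheme)
        return out


def _disc_mask(grid_shape: tuple[int, int], n_voxels: int) -> np.ndarray:
    """The ``n_voxels`` grid cells closest to the grid center.

    Ties in distance are broken lexicographically so the disc is
    deterministic.
    """
    nx, ny = grid_shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    d2 = (ii - cx) ** 2 + (jj - cy) ** 2
    order = np.lexsort((jj.ravel(), ii.ravel(), np.round(d2.ravel(), 9)))
    mask = np.zeros(grid_shape, dtype=bool)
    flat = order[:n_voxels]
    mask[np.unravel_index(flat, grid_shape)] = True
    return mask


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    """Normal draw clipped into [lo, hi] (simple truncation by clipping)."""
    return np.clip(rng.normal(mean, sd, size=size), lo, hi)


def make_nerve(
    config: NerveTimepointConfig,
    scheme: GradientScheme | None = None,
    snr: float = 30.0,
    voxel_dims: tuple[float, float, float] = (0.117, 0.117, 0.8),
    seed: int = 0,
    grid_shape: tuple[int, int] = (12, 12),
) -> PhantomDataset:
    """Simulate one nerve cross-section at one timepoint.

    The nerve is a disc whose voxel count is the nearest integer to
    ``config.nerve_volume / voxel_volume``, surrounded by a two-voxel
    CSF rim of free water (D = ``config.csf_D``); remaining voxels are
    noise-only background. Per-voxel truth is drawn around the config
    means, fractions renormalized to sum to one, fiber axis
    through-plane. The center ROI is the disc eroded by one voxel,
    falling back to the single most central voxel.
    """
    scheme = scheme or build_default_scheme()
    vvol = float(np.prod(voxel_dims))
    n_vox = int(round(config.nerve_volume / vvol))
    if n_vox < 1:
        raise ValueError(
            f"nerve_volume {config.nerve_volume} mm³ is smaller than one "
            f"voxel ({vvol:.6f} mm³)"
        )
    nerve = _disc_mask(grid_shape, n_vox)
    csf = ndimage.binary_dilation(nerve, iterations=2) & ~nerve

    center = ndimage.binary_erosion(nerve)
    if not center.any():
        nx, ny = grid_shape
        cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
        ii, jj = np.nonzero(nerve)
        k = np.argmin((ii - cx) ** 2 + (jj - cy) ** 2)
        center = np.zeros(grid_shape, dtype=bool)
        center[ii[k], jj[k]] = True

    # independent child streams for truth draws and noise so that the
    # integer sub-seeds of neighbouring datasets cannot collide
    truth_ss, noise_ss = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(truth_ss)
    truth_names = (
        "lambda_par",
        "lambda_perp",
        "fiber_fraction",
        "restricted_fraction",
        "nonrestricted_fraction",
    )
    truth_maps = {name: np.full(grid_shape, np.nan) for name in truth_names}
    voxel_truths: dict[tuple[int, int], VoxelTruth] = {}

    for i, j in zip(*np.nonzero(nerve)):
        lpar = _truncated_normal(rng, config.mean_lambda_par, config.sd["lambda_par"], 0.5, 3.0)
        lperp = _truncated_normal(
            rng, config.mean_lambda_perp, config.sd["lambda_perp"], 0.01, min(1.0, lpar)
        )
        raw = np.array(
            [
                rng.normal(config.mean_fiber_fraction, config.sd["fiber_fraction"]),
                rng.normal(config.mean_restricted_fraction, config.sd["restricted_fraction"]),
                rng.normal(
                    config.mean_nonrestricted_fraction, config.sd["nonrestricted_fraction"]
                ),
            ]
        )
        raw = np.maximum(raw, 0.0)
        if raw.sum() == 0:
            raw = np.array([1.0, 0.0, 0.0])
        fr = raw / raw.sum()
        truth = VoxelTruth(
            aniso=AnisotropicComponent(_Z, float(lpar), float(lperp), float(fr[0])),
            iso=IsotropicSpectrum(
                [config.restricted_D, config.nonrestricted_D], [fr[1], fr[2]]
            ),
            s0=1.0,
        )
        voxel_truths[(i, j)] = truth
        truth_maps["lambda_par"][i, j] = lpar
        truth_maps["lambda_perp"][i, j] = lperp
        truth_maps["fiber_fraction"][i, j] = fr[0]
        truth_maps["restricted_fraction"][i, j] = fr[1]
        truth_maps["nonrestricted_fraction"][i, j] = fr[2]

    csf_truth = VoxelTruth(
        aniso=AnisotropicComponent(_Z, 1.0, 1.0, 0.0),
        iso=IsotropicSpectrum([config.csf_D], [1.0]),
        s0=1.0,
    )
    for i, j in zip(*np.nonzero(csf)):
        voxel_truths[(i, j)] = csf_truth

    nx, ny = grid_shape
    clean = np.zeros((nx, ny, 1, scheme.n_volumes))
    for (i, j), truth in voxel_truths.items():
        clean[i, j, 0, :] = predict_signal(truth, scheme)
    noisy = add_rician_noise(clean, snr, seed=noise_ss, s0=1.0)

    return PhantomDataset(
        dwi=noisy,
        nerve_mask=nerve,
        center_roi_mask=center,
        truth_maps=truth_maps,
        voxel_truths=voxel_truths,
        scheme=scheme,
        voxel_dims=voxel_dims,
        snr=snr,
        seed=seed,
    )


def _subseed(master_seed: int, index: int) -> int:
    """Deterministic per-dataset sub-seed: master × 10⁴ + index."""
    return master_seed * 10_000 + index


def _nerve_timepoint_configs(
    cohort: CohortConfig, converting: bool, rng
) -> dict[str, tuple[NerveTimepointConfig, float]]:
    """Per-nerve truth for every timepoint, with exact loss bookkeeping.

    Nerve-level parameters are drawn around the timepoint group means
    with the preset standard deviations (the between-animal spread the
    group tables report), so cohort regressions against emulated
    histology have genuine between-nerve variance. The true axon
    volume (discretized nerve volume × mean fiber fraction) at
    time 1/2 equals this nerve's baseline × (1 − loss): swelling
    raises the nerve volume per the preset while the fiber fraction is
    lowered accordingly, and the extra isotropic mass keeps the
    preset's restricted : non-restricted ratio up to a small jitter.
    A non-converting eye keeps its baseline truth at every timepoint.
    """
    base = TIMEPOINT_PRESETS["baseline"]
    vvol = float(np.prod(cohort.voxel_dims))

    def discrete_volume(v: float) -> float:
        return round(v / vvol) * vvol

    r0 = float(np.clip(rng.normal(base.mean_restricted_fraction,
                                  base.sd["restricted_fraction"]), 0.0, 0.2))
    nr0 = float(np.clip(rng.normal(base.mean_nonrestricted_fraction,
                                   base.sd["nonrestricted_fraction"]), 0.0, 0.2))
    ff0 = 1.0 - r0 - nr0
    lpar0 = _truncated_normal(rng, base.mean_lambda_par, base.sd["lambda_par"], 0.5, 3.0)
    lperp0 = _truncated_normal(
        rng, base.mean_lambda_perp, base.sd["lambda_perp"], 0.01, min(1.0, lpar0)
    )
    base_cfg = replace(
        base,
        mean_lambda_par=float(lpar0),
        mean_lambda_perp=float(lperp0),
        mean_fiber_fraction=ff0,
        mean_restricted_fraction=r0,
        mean_nonrestricted_fraction=nr0,
    )
    base_axon = discrete_volume(base.nerve_volume) * ff0
    out = {"baseline": (base_cfg, base_axon)}

    losses = {"time1": cohort.axon_loss_time1, "time2": cohort.axon_loss_time2}
    for timepoint in ("time1", "time2"):
        preset = TIMEPOINT_PRESETS[timepoint]
        lpar_t = _truncated_normal(
            rng, preset.mean_lambda_par, preset.sd["lambda_par"], 0.5, 3.0
        )
        lperp_t = _truncated_normal(
            rng, preset.mean_lambda_perp, preset.sd["lambda_perp"], 0.01, min(1.0, lpar_t)
        )
        if not converting:
            out[timepoint] = (base_cfg, base_axon)
            continue
        axon = base_axon * (1.0 - losses[timepoint])
        fiber = axon / discrete_volume(preset.nerve_volume)
        iso = 1.0 - fiber
        preset_iso = preset.mean_restricted_fraction + preset.mean_nonrestricted_fraction
        share = float(np.clip(
            rng.normal(preset.mean_restricted_fraction / preset_iso, 0.05), 0.05, 0.95
        ))
        out[timepoint] = (
            replace(
                preset,
                mean_lambda_par=float(lpar_t),
                mean_lambda_perp=float(lperp_t),
                mean_fiber_fraction=fiber,
                mean_restricted_fraction=iso * share,
                mean_nonrestricted_fraction=iso * (1.0 - share),
            ),
            axon,
        )
    return out


def make_cohort(
    cohort: CohortConfig | None = None,
    master_seed: int = 0,
    scheme: GradientScheme | None = None,
) -> tuple[list[PhantomDataset], pd.DataFrame]:
    """Simulate the full mouse × eye × timepoint cohort.

    Returns the datasets plus a long-format truth table (one row per
    nerve scan). When ``include_nonconverting_eye`` is set, one
    randomly chosen eye 2 never develops optic neuritis and keeps its
    baseline truth, but stays in the cohort.
    """
    cohort = cohort or CohortConfig()
    scheme = scheme or build_default_scheme()
    master_rng = np.random.default_rng(master_seed)
    nonconverting_mouse = -1
    if cohort.include_nonconverting_eye and cohort.eyes_per_mouse >= 2:
        nonconverting_mouse = int(master_rng.integers(cohort.n_mice))

    datasets: list[PhantomDataset] = []
    rows = []
    index = 0
    for mouse in range(cohort.n_mice):
        for eye in range(1, cohort.eyes_per_mouse + 1):
            converting = not (mouse == nonconverting_mouse and eye == 2)
            nerve_rng = np.random.default_rng(
                np.random.SeedSequence((master_seed, mouse, eye))
            )
            per_tp = _nerve_timepoint_configs(cohort, converting, nerve_rng)
            for timepoint in cohort.timepoints:
                cfg, true_axon = per_tp[timepoint]
                seed = _subseed(master_seed, index)
                ds = make_nerve(
                    cfg,
                    scheme=scheme,
                    snr=cohort.snr,
                    voxel_dims=cohort.voxel_dims,
                    seed=seed,
                    grid_shape=cohort.grid_shape,
                )
                va_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
                vac = cohort.va_coupling
                va = float(
                    np.clip(
                        vac.slope * cfg.mean_fiber_fraction
                        + vac.intercept
                        + va_rng.normal(0.0, vac.noise_sd),
                        vac.va_min,
                        vac.va_max,
                    )
                )
                vvol = float(np.prod(cohort.voxel_dims))
                nerve_volume = float(ds.nerve_mask.sum()) * vvol
                ds.covariates = {
                    "mouse": mouse,
                    "eye": eye,
                    "timepoint": timepoint,
                    "converting": converting,
                    "va": va,
                    "true_axon_volume": true_axon,
                }
                datasets.append(ds)
                rows.append(
                    {
                        "mouse": mouse,
                        "eye": eye,
                        "timepoint": timepoint,
                        "converting": converting,
                        "va": va,
                        "nerve_volume_true": nerve_volume,
                        "lambda_par_true": cfg.mean_lambda_par,
                        "lambda_perp_true": cfg.mean_lambda_perp,
                        "fiber_fraction_true": cfg.mean_fiber_fraction,
                        "restricted_fraction_true": cfg.mean_restricted_fraction,
                        "nonrestricted_fraction_true": cfg.mean_nonrestricted_fraction,
                        "axon_volume_true": true_axon,
                        "seed": seed,
                    }
                )
                index += 1
    return datasets, pd.DataFrame(rows)


def make_histology(
    truth_table: pd.DataFrame,
    coupling: HistologyCoupling | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate per-nerve immunohistochemistry readouts.

    Each stain is a linear function of one truth parameter plus
    Gaussian noise, clamped to its valid range: SMI-31 (intact axons)
    tracks λ∥, MBP (myelin) tracks −λ⊥, SMI-312 (total axons) tracks
    fiber fraction and DAPI counts track the restricted fraction.
    """
    coupling = coupling or HistologyCoupling()
    rng = np.random.default_rng(seed)
    out = truth_table[["mouse", "eye", "timepoint"]].copy()
    for stain, c in coupling.items():
        x = truth_table[f"{c.truth}_true"].to_numpy()
        vals = c.slope * x + c.intercept + rng.normal(0.0, c.noise_sd, size=x.size)
        out[stain] = np.clip(vals, c.lo, c.hi)
    return out
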