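"""End-to-end orchestration: simulate → fit → quantify → stats.

Each stage consumes the previous stage's on-disk outputs, so real
(non-simulated) NIfTI data laid out the same way can enter at the fit
stage. A JSON run-manifest records the configuration, the seed,
package versions and a content hash of every output file; repeated
runs at a fixed seed are manifest-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acquisition import GradientScheme, build_default_scheme
from .dbsi import DBSIConfig, fit_dbsi, fit_isotropic_spectrum, partition_spectrum
from .dti import FitError, fit_dti, fractional_anisotropy
from .io import load_dataset_images, save_dataset, save_map
from .phantom import CohortConfig, make_cohort, make_histology
from .quantify import add_percent_change, nerve_metrics
from .stats import change_from_baseline, linear_regression

__all__ = [
    "RunConfig",
    "StageError",
    "estimate_background_sigma",
    "fit_voxel_maps",
    "fit_bundle_maps",
    "run_pipeline",
    "load_config",
]

log = logging.getLogger("dbspectra")

#: fitted-map name -> attribute on the per-voxel fit objects
_DTI_MAPS = {
    "dti_lambda_par": "lambda_par",
    "dti_lambda_perp": "lambda_perp",
    "dti_fa": "fa",
    "dti_md": "md",
}
_DBSI_MAPS = {
    "dbsi_lambda_par": "lambda_par",
    "dbsi_lambda_perp": "lambda_perp",
    "dbsi_fa": "fiber_fa",
    "dbsi_fiber_fraction": "fiber_fraction",
    "dbsi_restricted_fraction": "restricted_fraction",
    "dbsi_nonrestricted_fraction": "nonrestricted_fraction",
}

#: metrics contrasted against baseline in the stats stage
_CONTRAST_METRICS = (
    "dti_lambda_par",
    "dti_lambda_perp",
    "dbsi_lambda_par",
    "dbsi_lambda_perp",
    "dbsi_fiber_fraction",
    "dbsi_restricted_fraction",
    "dbsi_nonrestricted_fraction",
    "nerve_volume",
    "axon_volume",
)

#: histology stain -> fitted metric regressed against it
_REGRESSION_PAIRS = {
    "smi31": "dbsi_lambda_par",
    "mbp": "dbsi_lambda_perp",
    "smi312": "dbsi_fiber_fraction",
    "dapi": "dbsi_restricted_fraction",
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (see ``load_config`` for the schema).

    ``in_plane_interpretation`` resolves the ambiguity of an in-plane
    resolution quoted as "117 μm2": ``edge_um`` reads it as a 117-μm
    pixel edge (the default; consistent with nerve volumes of
    ~0.08 mm³ spanning a handful of voxels), ``area_um2`` as a pixel
    area of 117 μm².
    """

    seed: int = 0
    out_dir: str = "dbspectra_run"
    log_level: str = "INFO"
    fit_mode: str = "bundle"
    scheme_n_directions: int = 25
    scheme_b_max: float = 2200.0
    in_plane: float = 117.0
    in_plane_interpretation: str = "edge_um"
    slice_thickness_mm: float = 0.8
    dbsi: DBSIConfig = field(default_factory=DBSIConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self) -> None:
        if self.in_plane_interpretation not in ("edge_um", "area_um2"):
            raise ValueError(
                "in_plane_interpretation must be 'edge_um' or 'area_um2'"
            )
        if self.fit_mode not in ("bundle", "voxel"):
            raise ValueError("fit_mode must be 'bundle' or 'voxel'")
        if self.in_plane <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("voxel geometry must be positive")

    @property
    def voxel_dims(self) -> tuple[float, float, float]:
        if self.in_plane_interpretation == "edge_um":
            edge = self.in_plane / 1000.0
        else:
            edge = float(np.sqrt(self.in_plane)) / 1000.0
        return (edge, edge, self.slice_thickness_mm)

    def build_scheme(self) -> GradientScheme:
        return build_default_scheme(self.scheme_n_directions, self.scheme_b_max)


_SCHEMA = {
    "seed": int,
    "out_dir": str,
    "log_level": str,
    "fit_mode": str,
    "scheme": {"n_directions": int, "b_max": (int, float)},
    "voxel": {
        "in_plane": (int, float),
        "in_plane_interpretation": str,
        "slice_thickness_mm": (int, float),
    },
    "dbsi": {
        "grid_min": (int, float),
        "grid_max": (int, float),
        "grid_step": (int, float),
        "restricted_threshold": (int, float),
        "regularization_weight": (int, float),
        "lambda_par_bounds": list,
        "lambda_perp_bounds": list,
    },
    "cohort": {
        "n_mice": int,
        "eyes_per_mouse": int,
        "snr": (int, float),
        "axon_loss_time1": (int, float),
        "axon_loss_time2": (int, float),
        "include_nonconverting_eye": bool,
    },
}


def _check_block(data: dict, schema: dict, path: str = "") -> None:
    for key, val in data.items():
        where = f"{path}{key}"
        if key not in schema:
            raise ValueError(f"unknown config key: {where}")
        expected = schema[key]
        if isinstance(expected, dict):
            if not isinstance(val, dict):
                raise ValueError(f"config key {where} must be a mapping")
            _check_block(val, expected, where + ".")
        elif not isinstance(val, expected):
            raise ValueError(f"config key {where} has wrong type")


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file plus overrides.

    The YAML layout mirrors the module structure::

        seed: 0
        scheme: {n_directions: 25, b_max: 2200.0}
        voxel: {in_plane: 117.0, in_plane_interpretation: edge_um,
                slice_thickness_mm: 0.8}
        dbsi: {grid_step: 0.1, regularization_weight: 0.01, ...}
        cohort: {n_mice: 8, snr: 30.0, ...}

    Unknown keys and wrong types are rejected before any stage runs.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        for key, val in overrides.items():
            if isinstance(val, dict):
                data.setdefault(key, {}).update(val)
            else:
                data[key] = val
    _check_block(data, _SCHEMA)

    dbsi_kwargs = dict(data.get("dbsi", {}))
    for bound in ("lambda_par_bounds", "lambda_perp_bounds"):
        if bound in dbsi_kwargs:
            dbsi_kwargs[bound] = tuple(dbsi_kwargs[bound])
    cohort_kwargs = dict(data.get("cohort", {}))
    voxel = data.get("voxel", {})
    scheme = data.get("scheme", {})

    cfg = RunConfig(
        seed=data.get("seed", 0),
        out_dir=data.get("out_dir", "dbspectra_run"),
        log_level=data.get("log_level", "INFO"),
        fit_mode=data.get("fit_mode", "bundle"),
        scheme_n_directions=scheme.get("n_directions", 25),
        scheme_b_max=float(scheme.get("b_max", 2200.0)),
        in_plane=float(voxel.get("in_plane", 117.0)),
        in_plane_interpretation=voxel.get("in_plane_interpretation", "edge_um"),
        slice_thickness_mm=float(voxel.get("slice_thickness_mm", 0.8)),
        dbsi=DBSIConfig(**dbsi_kwargs),
        cohort=CohortConfig(**cohort_kwargs),
    )
    # the cohort simulates on the configured voxel grid
    from dataclasses import replace as _replace

    object.__setattr__(cfg, "cohort", _replace(cfg.cohort, voxel_dims=cfg.voxel_dims))
    return cfg


def estimate_background_sigma(dwi: np.ndarray, nerve_mask: np.ndarray) -> float:
    """Noise standard deviation from signal-free background voxels.

    Background is everything further than three dilations from the
    nerve (beyond the CSF rim); its magnitude values are Rayleigh
    distributed with mean σ·sqrt(π/2). Returns 0.0 when no background
    voxel exists, which disables downstream bias correction.
    """
    from scipy import ndimage

    nerve_mask = np.asarray(nerve_mask, dtype=bool)
    background = ~ndimage.binary_dilation(nerve_mask, iterations=3)
    if not background.any():
        return 0.0
    vals = dwi[background] if dwi.ndim == 3 else dwi[:, :, 0, :][background]
    return float(vals.mean() / np.sqrt(np.pi / 2.0))


def fit_voxel_maps(
    dwi: np.ndarray,
    scheme: GradientScheme,
    mask: np.ndarray,
    dbsi_config: DBSIConfig | None = None,
    noise_sigma: float = 0.0,
) -> tuple[dict, np.ndarray]:
    """Fit DTI and DBSI in every masked voxel of a 4-D image.

    When ``noise_sigma`` > 0 the magnitude signal entering the
    multi-compartment fit is Rician-bias corrected (signed mode, see
    :func:`~dbspectra.signal_model.rician_bias_correct`); otherwise the
    high-b noise floor masquerades as restricted isotropic signal. The
    single-tensor comparator always fits the raw magnitude, as its
    log-linear estimator requires positive values.
    Returns (maps, failed): 2-D parametric maps named ``dti_*`` /
    ``dbsi_*`` (NaN outside the mask) plus a boolean map of voxels
    whose fit raised, which downstream ROI means exclude.
    """
    from .signal_model import rician_bias_correct

    dbsi_config = dbsi_config or DBSIConfig()
    nx, ny = dwi.shape[:2]
    maps = {name: np.full((nx, ny), np.nan) for name in (*_DTI_MAPS, *_DBSI_MAPS)}
    failed = np.zeros((nx, ny), dtype=bool)
    for i, j in zip(*np.nonzero(np.asarray(mask, dtype=bool))):
        signal = dwi[i, j, 0, :] if dwi.ndim == 4 else dwi[i, j, :]
        dbsi_signal = signal
        if noise_sigma > 0.0:
            dbsi_signal = rician_bias_correct(signal, noise_sigma)
        try:
            dti = fit_dti(signal, scheme)
            dbsi = fit_dbsi(dbsi_signal, scheme, dbsi_config)
        except FitError:
            failed[i, j] = True
            continue
        for name, attr in _DTI_MAPS.items():
            maps[name][i, j] = getattr(dti, attr)
        for name, attr in _DBSI_MAPS.items():
            maps[name][i, j] = getattr(dbsi, attr)
    return maps, failed


def fit_bundle_maps(
    dwi: np.ndarray,
    scheme: GradientScheme,
    mask: np.ndarray,
    dbsi_config: DBSIConfig | None = None,
    noise_sigma: float = 0.0,
) -> tuple[dict, np.ndarray]:
    """Coherent-bundle fit of one nerve: shared fiber, per-voxel spectra.

    The optic nerve is a single coherent fiber bundle, so the fiber
    parameters (axis, λ∥, λ⊥) are estimated once from the ROI-mean
    signal — whose SNR is higher by the square root of the voxel
    count — and every voxel is then given a spectrum-plus-fiber-weight
    fit at those shared parameters. This removes most of the per-voxel
    λ⊥/edema degeneracy that biases fiber fractions at realistic SNR.
    DTI maps remain per-voxel fits of the raw magnitude. Returns the
    same (maps, failed) pair as :func:`fit_voxel_maps`; the fitted λ∥,
    λ⊥ and FA maps are constant over the nerve by construction.
    """
    from .signal_model import rician_bias_correct

    dbsi_config = dbsi_config or DBSIConfig()
    mask = np.asarray(mask, dtype=bool)
    nx, ny = dwi.shape[:2]
    maps = {name: np.full((nx, ny), np.nan) for name in (*_DTI_MAPS, *_DBSI_MAPS)}
    failed = np.zeros((nx, ny), dtype=bool)

    voxels = list(zip(*np.nonzero(mask)))
    if not voxels:
        return maps, failed
    signals = {}
    for i, j in voxels:
        s = dwi[i, j, 0, :] if dwi.ndim == 4 else dwi[i, j, :]
        if noise_sigma > 0.0:
            signals[(i, j)] = rician_bias_correct(s, noise_sigma)
        else:
            signals[(i, j)] = np.asarray(s, dtype=float)

    mean_signal = np.mean(list(signals.values()), axis=0)
    bundle = fit_dbsi(mean_signal, scheme, dbsi_config)
    fiber_fa = fractional_anisotropy(
        np.array([bundle.lambda_par, bundle.lambda_perp, bundle.lambda_perp])
    )

    for i, j in voxels:
        raw = dwi[i, j, 0, :] if dwi.ndim == 4 else dwi[i, j, :]
        try:
            dti = fit_dti(raw, scheme)
            fiber_w, spectrum, _ = fit_isotropic_spectrum(
                signals[(i, j)],
                scheme,
                bundle.fiber.principal_direction,
                bundle.lambda_par,
                bundle.lambda_perp,
                dbsi_config,
            )
        except FitError:
            failed[i, j] = True
            continue
        total = fiber_w + spectrum.total_weight
        if total <= 0:
            failed[i, j] = True
            continue
        restricted, nonrestricted = partition_spectrum(
            spectrum, dbsi_config.restricted_threshold
        )
        for name, attr in _DTI_MAPS.items():
            maps[name][i, j] = getattr(dti, attr)
        maps["dbsi_lambda_par"][i, j] = bundle.lambda_par
        maps["dbsi_lambda_perp"][i, j] = bundle.lambda_perp
        maps["dbsi_fa"][i, j] = fiber_fa
        maps["dbsi_fiber_fraction"][i, j] = fiber_w / total
        maps["dbsi_restricted_fraction"][i, j] = restricted / total
        maps["dbsi_nonrestricted_fraction"][i, j] = nonrestricted / total
    return maps, failed


def analyze_cohort(
    cohort: CohortConfig | None = None,
    master_seed: int = 0,
    dbsi_config: DBSIConfig | None = None,
    scheme: GradientScheme | None = None,
    fit_mode: str = "bundle",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate, fit and quantify one cohort without touching disk.

    Runs the same computational path as the simulate → fit → quantify
    stages and returns (metrics table with percent changes, truth
    table). Convenient for resampling studies where the NIfTI round
    trip is irrelevant.
    """
    from .phantom import make_cohort

    cohort = cohort or CohortConfig()
    datasets, truth = make_cohort(cohort, master_seed, scheme=scheme)
    fitter = fit_bundle_maps if fit_mode == "bundle" else fit_voxel_maps
    rows = []
    for ds in datasets:
        sigma = estimate_background_sigma(ds.dwi, ds.nerve_mask)
        maps, failed = fitter(ds.dwi, ds.scheme, ds.nerve_mask, dbsi_config, sigma)
        row = {k: ds.covariates[k] for k in ("mouse", "eye", "timepoint", "converting", "va")}
        row.update(
            nerve_metrics(maps, ds.nerve_mask, ds.center_roi_mask, ds.voxel_dims, failed)
        )
        rows.append(row)
    return add_percent_change(pd.DataFrame(rows)), truth


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _dataset_dirname(cov: dict) -> str:
    return f"mouse{cov['mouse']:02d}_eye{cov['eye']}_{cov['timepoint']}"


def stage_simulate(config: RunConfig, out_dir: Path) -> list[Path]:
    """Generate the cohort and write every dataset plus truth tables."""
    scheme = config.build_scheme()
    datasets, truth = make_cohort(config.cohort, config.seed, scheme=scheme)
    written: list[Path] = []
    for ds in datasets:
        ds_dir = out_dir / "datasets" / _dataset_dirname(ds.covariates)
        written += save_dataset(ds, ds_dir)
        meta = ds_dir / "covariates.json"
        meta.write_text(json.dumps(ds.covariates, indent=1, sort_keys=True) + "\n")
        written.append(meta)
    truth_path = out_dir / "truth_table.csv"
    truth.to_csv(truth_path, index=False)
    written.append(truth_path)

    histo = make_histology(
        truth[truth["timepoint"] == "time2"].reset_index(drop=True),
        config.cohort.histology_coupling,
        seed=config.seed + 1,
    )
    histo_path = out_dir / "histology.csv"
    histo.to_csv(histo_path, index=False)
    written.append(histo_path)
    return written


def stage_fit(config: RunConfig, out_dir: Path) -> list[Path]:
    """Fit parametric maps for every dataset directory on disk."""
    ds_root = out_dir / "datasets"
    if not ds_root.is_dir():
        raise StageError(f"fit: no datasets directory at {ds_root}")
    written: list[Path] = []
    for ds_dir in sorted(p for p in ds_root.iterdir() if p.is_dir()):
        try:
            dwi, nerve_mask, _, scheme, voxel_dims = load_dataset_images(ds_dir)
        except FileNotFoundError as exc:
            raise StageError(f"fit: {exc}") from exc
        sigma = estimate_background_sigma(dwi, nerve_mask)
        fitter = fit_bundle_maps if config.fit_mode == "bundle" else fit_voxel_maps
        maps, failed = fitter(dwi, scheme, nerve_mask, config.dbsi, sigma)
        for name, arr in maps.items():
            p = ds_dir / f"{name}.nii"
            save_map(arr, p, voxel_dims)
            written.append(p)
        p = ds_dir / "failed_fits.nii"
        save_map(failed.astype(float), p, voxel_dims)
        written.append(p)
    return written


def stage_quantify(config: RunConfig, out_dir: Path) -> list[Path]:
    """Reduce fitted maps to the long-format per-nerve metrics table."""
    ds_root = out_dir / "datasets"
    if not ds_root.is_dir():
        raise StageError(f"quantify: no datasets directory at {ds_root}")
    rows = []
    for ds_dir in sorted(p for p in ds_root.iterdir() if p.is_dir()):
        try:
            _, nerve_mask, center_roi, _, voxel_dims = load_dataset_images(ds_dir)
            maps = {}
            for name in (*_DTI_MAPS, *_DBSI_MAPS):
                arr, _ = _load_2d(ds_dir / f"{name}.nii")
                maps[name] = arr
            failed, _ = _load_2d(ds_dir / "failed_fits.nii")
        except FileNotFoundError as exc:
            raise StageError(f"quantify: {exc}") from exc
        cov = json.loads((ds_dir / "covariates.json").read_text())
        row = {k: cov[k] for k in ("mouse", "eye", "timepoint", "converting", "va")}
        row.update(
            nerve_metrics(maps, nerve_mask, center_roi, voxel_dims, failed > 0.5)
        )
        rows.append(row)
    table = add_percent_change(pd.DataFrame(rows))
    path = out_dir / "cohort_metrics.csv"
    table.to_csv(path, index=False)
    return [path]


def _load_2d(path: Path) -> tuple[np.ndarray, tuple]:
    from .io import load_map

    arr, dims = load_map(path)
    return arr[..., 0], dims


def stage_stats(config: RunConfig, out_dir: Path) -> list[Path]:
    """Contrasts vs baseline and histology regressions, written as CSV."""
    metrics_path = out_dir / "cohort_metrics.csv"
    if not metrics_path.exists():
        raise StageError(f"stats: missing {metrics_path}")
    table = pd.read_csv(metrics_path)
    contrast_rows = []
    for metric in _CONTRAST_METRICS:
        for timepoint in ("time1", "time2"):
            res = change_from_baseline(table, metric, timepoint)
            contrast_rows.append(
                {
                    "metric": res.metric,
                    "timepoint": res.timepoint,
                    "estimate": res.estimate,
                    "se": res.se,
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "n_pairs": res.n_pairs,
                    "degenerate": res.degenerate,
                }
            )
    contrasts = pd.DataFrame(contrast_rows)
    contrasts_path = out_dir / "contrasts.csv"
    contrasts.to_csv(contrasts_path, index=False)
    written = [contrasts_path]

    histo_path = out_dir / "histology.csv"
    if histo_path.exists():
        histo = pd.read_csv(histo_path)
        merged = histo.merge(
            table[table["timepoint"] == "time2"],
            on=("mouse", "eye", "timepoint"),
        )
        reg_rows = []
        for stain, metric in _REGRESSION_PAIRS.items():
            res = linear_regression(merged[metric], merged[stain])
            reg_rows.append(
                {
                    "stain": stain,
                    "metric": metric,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "r_squared": res.r_squared,
                    "slope_se": res.slope_se,
                    "p": res.p,
                    "n": res.n,
                }
            )
        reg_path = out_dir / "regressions.csv"
        pd.DataFrame(reg_rows).to_csv(reg_path, index=False)
        written.append(reg_path)
    return written


def _summary_text(out_dir: Path) -> str:
    table = pd.read_csv(out_dir / "cohort_metrics.csv")
    lines = ["per-timepoint group means", "-" * 25]
    cols = [
        "nerve_volume",
        "axon_volume",
        "dbsi_lambda_par",
        "dti_lambda_par",
        "dbsi_restricted_fraction",
        "dbsi_nonrestricted_fraction",
    ]
    means = table.groupby("timepoint")[cols].mean()
    lines.append(means.round(4).to_string())
    for tp in ("time1", "time2"):
        sub = table[table["timepoint"] == tp]
        lines.append(
            f"mean axon-volume change at {tp}: "
            f"{sub['percent_axon_volume_change_from_baseline'].mean():+.1f}%"
        )
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate → fit → quantify → stats and write the manifest.

    Returns the manifest dict. Any stage failure raises
    :class:`StageError` naming the stage; outputs of completed stages
    are left on disk.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    for name, stage in (
        ("simulate", stage_simulate),
        ("fit", stage_fit),
        ("quantify", stage_quantify),
        ("stats", stage_stats),
    ):
        log.info("stage %s", name)
        try:
            files += stage(config, out_dir)
        except StageError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError(f"{name}: {exc}") from exc

    summary_path = out_dir / "summary.txt"
    summary_path.write_text(_summary_text(out_dir))
    files.append(summary_path)

    cfg_dict = asdict(config)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "package": "dbspectra",
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(cfg_json),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "versions": _versions(),
        "files": {
            str(p.relative_to(out_dir)): _sha256(p) for p in sorted(set(files))
        },
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def _versions() -> dict:
    import nibabel
    import numba
    import scipy

    return {
        "dbspectra": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "nibabel": nibabel.__version__,
        "numba": numba.__version__,
    }
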