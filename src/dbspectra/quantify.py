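"""ROI-level morphometry: map means, nerve volume, axon volume, change.

Two ROIs per nerve mirror the acquisition protocol: the whole-nerve
mask drives volume estimation and the fiber fraction entering axon
volume, while the eroded center ROI (minimal partial-volume
contamination) supplies the per-metric group statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "roi_mean",
    "nerve_volume",
    "axon_volume",
    "percent_change",
    "nerve_metrics",
    "add_percent_change",
]


def roi_mean(
    parametric_map: np.ndarray, roi: np.ndarray, failed: np.ndarray | None = None
) -> float:
    """Arithmetic mean of a parametric map over an ROI.

    Voxels flagged in ``failed`` (failed fits) and NaNs are excluded.
    Raises ``ValueError`` if the ROI is empty or no usable voxel remains.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != np.asarray(parametric_map).shape:
        raise ValueError("roi and map shapes differ")
    if not roi.any():
        raise ValueError("empty ROI")
    usable = roi.copy()
    if failed is not None:
        usable &= ~np.asarray(failed, dtype=bool)
    vals = np.asarray(parametric_map, dtype=float)[usable]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no usable voxels in ROI")
    return float(vals.mean())


def nerve_volume(mask: np.ndarray, voxel_dims: tuple[float, float, float]) -> float:
    """Voxel count × voxel volume, in mm³."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return float(mask.sum()) * float(np.prod(voxel_dims))


def axon_volume(nerve_vol: float, fiber_fraction_mean: float) -> float:
    """Axon volume = nerve volume × whole-nerve mean fiber fraction."""
    return float(nerve_vol) * float(fiber_fraction_mean)


def percent_change(baseline: float, followup: float) -> float:
    """100 × (followup − baseline) / baseline; loss comes out negative."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (followup - baseline) / baseline


def nerve_metrics(
    maps: dict,
    nerve_mask: np.ndarray,
    center_roi_mask: np.ndarray,
    voxel_dims: tuple[float, float, float],
    failed: np.ndarray | None = None,
) -> dict:
    """All per-nerve scalars from one scan's fitted parametric maps.

    ``maps`` holds 2-D parametric maps keyed by metric name (the
    ``dbsi_fiber_fraction`` map is required). Center-ROI means are
    produced for every map; volume and axon volume use the whole-nerve
    mask, with the fiber fraction entering axon volume computed by the
    same ``roi_mean`` code path as every other mean.
    """
    out = {}
    for name, pmap in maps.items():
        out[name] = roi_mean(pmap, center_roi_mask, failed)
    nv = nerve_volume(nerve_mask, voxel_dims)
    ff_whole = roi_mean(maps["dbsi_fiber_fraction"], nerve_mask, failed)
    out["nerve_volume"] = nv
    out["fiber_fraction_whole_nerve"] = ff_whole
    out["axon_volume"] = axon_volume(nv, ff_whole)
    return out


def add_percent_change(
    table: pd.DataFrame,
    metrics: tuple[str, ...] = ("axon_volume", "nerve_volume"),
    baseline_label: str = "baseline",
) -> pd.DataFrame:
    """Append per-nerve percent-change-from-baseline columns.

    Rows are matched within each (mouse, eye); nerves without a
    baseline row get NaN.
    """
    table = table.copy()
    for metric in metrics:
        col = f"percent_{metric}_change_from_baseline"
        table[col] = np.nan
        for (_, _), grp in table.groupby(["mouse", "eye"]):
            base_rows = grp[grp["timepoint"] == baseline_label]
            if base_rows.empty:
                continue
            base = float(base_rows[metric].iloc[0])
            table.loc[grp.index, col] = [
                percent_change(base, v) for v in grp[metric]
            ]
    return table
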