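"""NIfTI and gradient-table I/O for phantom datasets and parametric maps."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .acquisition import GradientScheme, load_bvals_bvecs, save_bvals_bvecs
from .phantom import PhantomDataset

__all__ = [
    "save_map",
    "load_map",
    "save_dataset",
    "load_dataset_images",
]


def _affine(voxel_dims: tuple[float, float, float]) -> np.ndarray:
    return np.diag([voxel_dims[0], voxel_dims[1], voxel_dims[2], 1.0])


def save_map(array: np.ndarray, path: str | Path, voxel_dims: tuple[float, float, float]) -> None:
    """Write a 2-D map or 4-D volume as an uncompressed NIfTI-1 file."""
    arr = np.asarray(array, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    img = nib.Nifti1Image(arr, _affine(voxel_dims))
    nib.save(img, str(path))


def load_map(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI file; returns (array, voxel_dims in mm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"NIfTI file not found: {path}")
    img = nib.load(str(path))
    dims = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=np.float64), dims


def save_dataset(ds: PhantomDataset, out_dir: str | Path) -> list[Path]:
    """Write one phantom scan: DWI, masks, truth maps and gradient table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(name: str, arr: np.ndarray) -> None:
        p = out_dir / name
        save_map(arr, p, ds.voxel_dims)
        written.append(p)

    _w("dwi.nii", ds.dwi)
    _w("nerve_mask.nii", ds.nerve_mask.astype(float))
    _w("center_roi_mask.nii", ds.center_roi_mask.astype(float))
    for name, tmap in ds.truth_maps.items():
        _w(f"truth_{name}.nii", tmap)
    save_bvals_bvecs(ds.scheme, out_dir / "dwi.bval", out_dir / "dwi.bvec")
    written += [out_dir / "dwi.bval", out_dir / "dwi.bvec"]
    return written


def load_dataset_images(
    dataset_dir: str | Path,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GradientScheme, tuple[float, float, float]]:
    """Read the images a fit stage needs from one dataset directory.

    Returns (dwi, nerve_mask, center_roi_mask, scheme, voxel_dims).
    Raises ``FileNotFoundError`` naming the first missing path, so
    external data can be dropped in with the same layout.
    """
    d = Path(dataset_dir)
    for required in ("dwi.nii", "nerve_mask.nii", "center_roi_mask.nii", "dwi.bval", "dwi.bvec"):
        if not (d / required).exists():
            raise FileNotFoundError(f"missing required input: {d / required}")
    dwi, voxel_dims = load_map(d / "dwi.nii")
    nerve_mask, _ = load_map(d / "nerve_mask.nii")
    center_roi, _ = load_map(d / "center_roi_mask.nii")
    scheme = load_bvals_bvecs(d / "dwi.bval", d / "dwi.bvec")
    return (
        dwi,
        nerve_mask[..., 0] > 0.5,
        center_roi[..., 0] > 0.5,
        scheme,
        voxel_dims,
    )
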