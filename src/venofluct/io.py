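"""Reading and writing the pipeline's on-disk formats.

Image stacks travel as NIfTI volumes with axes (x, y, t); ROI masks as
same-geometry NIfTI volumes or as plain-text lists of 0-based ``row col``
pixel indices; velocity maps as NIfTI or whitespace-separated text
matrices; tables as tab-separated text; configurations and scenarios as
YAML.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "load_image_stack",
    "save_image_stack",
    "load_mask",
    "save_mask",
    "load_velocity_map",
    "load_yaml",
    "save_yaml",
    "write_table",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def load_image_stack(path: str | Path) -> np.ndarray:
    """Load a (rows, cols, n_frames) stack from a NIfTI volume."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D (x, y, t) volume, got shape {data.shape}")
    return data


def save_image_stack(stack: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(stack, dtype=np.float64), np.eye(4)), str(path))


def load_mask(path: str | Path, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Load a boolean pixel mask.

    NIfTI volumes are thresholded at 0.5.  Text files hold one ``row col``
    pair per line (0-based, row-major); ``shape`` is then required.
    """
    path = Path(path)
    if _is_nifti(path):
        data = np.squeeze(np.asarray(nib.load(str(path)).get_fdata()))
        if data.ndim != 2:
            raise ValueError(f"{path}: mask volume must be 2-D")
        return data > 0.5
    if shape is None:
        raise ValueError("shape is required for text-format masks")
    idx = np.loadtxt(path, dtype=int, ndmin=2)
    if idx.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (row col)")
    mask = np.zeros(shape, dtype=bool)
    mask[idx[:, 0], idx[:, 1]] = True
    return mask


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), np.eye(4)), str(path))
    else:
        rows, cols = np.nonzero(mask)
        np.savetxt(path, np.column_stack([rows, cols]), fmt="%d")


def load_velocity_map(path: str | Path) -> np.ndarray:
    """2-D velocity image from NIfTI or a whitespace-separated text matrix."""
    path = Path(path)
    if _is_nifti(path):
        data = np.squeeze(np.asarray(nib.load(str(path)).get_fdata(), dtype=float))
    else:
        data = np.loadtxt(path, ndmin=2)
    if data.ndim != 2:
        raise ValueError(f"{path}: velocity map must be 2-D")
    return data


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def save_yaml(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
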