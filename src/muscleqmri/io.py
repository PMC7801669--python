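"""NIfTI helpers for parameter maps and ROI masks (nibabel-backed)."""

from __future__ import annotations

import numpy as np
import nibabel as nib

__all__ = ["save_map", "load_map", "load_mask"]


def save_map(array, path, affine=None) -> None:
    """Write a parameter map (any dimensionality) as NIfTI."""
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float64), affine), str(path))


def load_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)


def load_mask(path) -> np.ndarray:
    """Load an ROI mask: any nonzero voxel is a member."""
    return nib.load(str(path)).get_fdata() != 0
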