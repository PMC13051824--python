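"""NIfTI reading and writing with an enforced RAS+ orientation contract.

All volumes in this package live in RAS+ world coordinates. ``read_nifti``
reorients any axis-permuted/flipped input (e.g. LPS-coded) to the closest
canonical RAS+ frame, with a warning, so downstream geometry can assume a
consistent convention. Only 3-D and 4-D images are accepted.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["read_nifti", "write_nifti"]


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3-D/4-D NIfTI as ``(data, affine)`` in RAS+ orientation."""
    img = nib.load(str(path))
    if img.ndim not in (3, 4):
        raise ValueError(f"expected 3-D or 4-D image, got {img.ndim}-D: {path}")
    orientation = nib.aff2axcodes(img.affine)
    if orientation != ("R", "A", "S"):
        warnings.warn(
            f"{path}: reorienting {''.join(orientation)} input to RAS+",
            stacklevel=2,
        )
        img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj, dtype=np.float64)
    return data, np.asarray(img.affine, dtype=float)


def write_nifti(path, data: np.ndarray, affine: np.ndarray, description: str = "") -> None:
    """Write a 3-D/4-D volume losslessly (float64) with its affine.

    ``description`` (e.g. the physical unit of the values) is stored in the
    header's descrip field, truncated to its 79-byte capacity.
    """
    data = np.asarray(data)
    if data.ndim not in (3, 4):
        raise ValueError(f"expected 3-D or 4-D data, got {data.ndim}-D")
    img = nib.Nifti1Image(data.astype(np.float64), np.asarray(affine, dtype=float))
    if description:
        img.header["descrip"] = description.encode()[:79]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
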