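"""NIfTI and sidecar I/O helpers shared by all pipeline stages."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np


def save_nifti(data: np.ndarray, path: str | Path, pixel_mm: float,
               slice_thickness_mm: float = 1.0) -> Path:
    """Write an array as NIfTI-1 with an axis-aligned affine (mm units)."""
    path = Path(path)
    affine = np.diag([pixel_mm, pixel_mm, slice_thickness_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    # mtime=0 in the gzip stream keeps rebuilt files byte-identical
    nib.save(img, str(path))
    return path


def load_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def array_hash(arr: np.ndarray) -> str:
    """SHA-256 of the raw array bytes (shape- and dtype-tagged)."""
    h = hashlib.sha256()
    a = np.ascontiguousarray(arr)
    h.update(str(a.dtype).encode())
    h.update(str(a.shape).encode())
    h.update(a.tobytes())
    return h.hexdigest()


def dataframe_hash(df) -> str:
    """SHA-256 of a DataFrame's CSV rendering (column order preserved)."""
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()
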