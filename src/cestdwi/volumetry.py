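"""Tumor volumetry from T2-grid ROI masks.

Volume is pure voxel arithmetic: in-mask pixel count x pixel area x slice
thickness, summed over slices. Masks drawn on the high-resolution T2 grid are
carried to the coarser CEST/DWI grid by block majority voting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import AcquisitionGeometry

__all__ = ["ROIMask", "VolumeRecord", "tumor_volume", "downsample_mask",
           "volume_timecourse", "auto_roi_otsu"]


@dataclass
class ROIMask:
    """Binary tumor mask tied to its acquisition geometry."""

    labels: np.ndarray  # (nx, ny) or (nx, ny, n_slices), values {0, 1}
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.isin(lab, (0, 1)).all():
            raise ValueError("mask labels must be 0/1")
        self.labels = lab.astype(np.uint8)


@dataclass
class VolumeRecord:
    animal: str
    group: str
    day: int
    volume_mm3: float
    n_pixels: int


def tumor_volume(mask: ROIMask) -> float:
    """Tumor volume in mm^3 from pixel count and physical geometry."""
    n = int(mask.labels.sum())
    if n == 0:
        warnings.warn("empty ROI mask; volume is 0.0 mm^3")
        return 0.0
    g = mask.geometry
    return n * g.t2_pixel_mm**2 * g.slice_thickness_mm


def downsample_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Block-downsample a binary mask by majority vote (ties included).

    Each ``factor x factor`` block maps to one output pixel, included iff at
    least half of the block is in-mask (>= 2 of 4 for the default 256 -> 128
    case). Deterministic; raises for non-divisible shapes.
    """
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError("downsample_mask expects a single 2-d slice")
    if m.shape[0] % factor or m.shape[1] % factor:
        raise ValueError(f"mask shape {m.shape} not divisible by factor {factor}")
    nx, ny = m.shape[0] // factor, m.shape[1] // factor
    blocks = m.reshape(nx, factor, ny, factor).sum(axis=(1, 3))
    return blocks >= (factor * factor) / 2.0


def volume_timecourse(records: list[VolumeRecord] | pd.DataFrame) -> pd.DataFrame:
    """Per-(group, day) mean +/- SD volume table.

    Cells with a single animal report SD 0 and are flagged; missing design
    cells are simply absent (never imputed).
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([r.__dict__ for r in records])
    if records.empty:
        raise ValueError("no volume records")
    rows = []
    for (group, day), sub in records.groupby(["group", "day"], sort=True):
        v = sub["volume_mm3"].to_numpy(dtype=float)
        rows.append({
            "group": group, "day": day, "n": v.size,
            "mean_mm3": v.mean(),
            "sd_mm3": v.std(ddof=1) if v.size > 1 else 0.0,
            "single_animal": v.size == 1,
        })
    return pd.DataFrame(rows)


def auto_roi_otsu(t2_slice: np.ndarray) -> np.ndarray:
    """Demonstration-only automatic ROI: Otsu threshold of one T2 slice.

    The validated path uses the supplied (ground-truth or hand-drawn) masks;
    this helper exists to show how a threshold ROI would plug in.
    """
    from skimage.filters import threshold_otsu

    thr = threshold_otsu(np.asarray(t2_slice, dtype=float))
    return np.asarray(t2_slice) > thr
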