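"""Per-pixel ADC estimation from multi-b-value diffusion-weighted series.

The signal model is the mono-exponential decay S(b) = S0 exp(-b * ADC). With
only three b-values (0, 1000, 2000 s/mm^2) the fit is an ordinary least
squares regression of ln S on b; the ADC is the negated slope and the
intercept estimates ln S0. A weighted variant (weights proportional to S^2,
the first-order correction for log-transformed noise) is available by flag.

Non-positive signals cannot enter the log fit; such points are dropped per
pixel, and a pixel with fewer than two usable points is flagged invalid
rather than zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DWISeries", "ADCMap", "fit_adc", "adc_map"]


@dataclass
class DWISeries:
    """A b-value table plus the per-pixel signal stack on one grid."""

    b_values: np.ndarray
    signals: np.ndarray  # (..., n_b)

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b.ndim != 1 or np.any(b < 0) or not np.all(np.diff(b) > 0) or b[0] != 0:
            raise ValueError("b_values must be non-negative, strictly "
                             "increasing, and include 0 first")
        if self.signals.shape[-1] != b.size:
            raise ValueError("signal stack and b-value table disagree")
        self.b_values = b
        self.signals = np.asarray(self.signals, dtype=float)


@dataclass
class ADCMap:
    """Fitted ADC image (mm^2/s) with per-pixel diagnostics."""

    adc: np.ndarray       # NaN on invalid pixels
    r_squared: np.ndarray
    valid: np.ndarray
    n_dropped_signals: int = 0

    def summary(self) -> dict:
        vals = self.adc[self.valid & np.isfinite(self.adc)]
        return {
            "n_pixels": int(vals.size),
            "mean_adc": float(vals.mean()) if vals.size else float("nan"),
            "sd_adc": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        }


def fit_adc(
    signals: np.ndarray,
    b_values: np.ndarray,
    weighted: bool = False,
) -> tuple[float, dict]:
    """Log-linear ADC fit for one pixel.

    Returns ``(adc, diagnostics)`` where diagnostics carries ``ln_s0``,
    ``r_squared``, ``n_used`` and ``valid``. Non-positive signals are
    excluded; fewer than two usable points marks the pixel invalid
    (``adc = nan``), never an exception.
    """
    s = np.asarray(signals, dtype=float)
    b = np.asarray(b_values, dtype=float)
    use = s > 0
    n_used = int(use.sum())
    diag = {"ln_s0": np.nan, "r_squared": np.nan, "n_used": n_used, "valid": False}
    if n_used < 2:
        return float("nan"), diag
    bs, ls = b[use], np.log(s[use])
    w = s[use] ** 2 if weighted else np.ones(n_used)
    wsum = w.sum()
    bbar = (w * bs).sum() / wsum
    lbar = (w * ls).sum() / wsum
    sxx = (w * (bs - bbar) ** 2).sum()
    if sxx == 0:
        return float("nan"), diag
    slope = (w * (bs - bbar) * (ls - lbar)).sum() / sxx
    intercept = lbar - slope * bbar
    resid = ls - (intercept + slope * bs)
    sst = (w * (ls - lbar) ** 2).sum()
    r2 = 1.0 if sst == 0 else 1.0 - (w * resid**2).sum() / sst
    diag.update({"ln_s0": float(intercept), "r_squared": float(r2), "valid": True})
    return float(-slope), diag


def adc_map(
    series: DWISeries,
    mask: np.ndarray,
    weighted: bool = False,
) -> ADCMap:
    """Fit every in-mask pixel of a DWI series."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.signals.shape[:-1]:
        raise ValueError("mask and DWI grid disagree")
    if not mask.any():
        raise ValueError("empty mask")
    adc = np.full(mask.shape, np.nan)
    r2 = np.full(mask.shape, np.nan)
    valid = np.zeros(mask.shape, dtype=bool)
    dropped = 0
    for ij in np.argwhere(mask):
        tij = tuple(ij)
        a, diag = fit_adc(series.signals[tij], series.b_values, weighted=weighted)
        dropped += series.b_values.size - diag["n_used"]
        if diag["valid"] and np.isfinite(a):
            adc[tij] = a
            r2[tij] = diag["r_squared"]
            valid[tij] = True
    return ADCMap(adc=adc, r_squared=r2, valid=valid, n_dropped_signals=dropped)
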