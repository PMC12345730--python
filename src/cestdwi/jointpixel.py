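"""Pixel-by-pixel joint analysis of ADC and creatine-MTR maps.

The signature readout of the pipeline: co-registered per-pixel
(ADC, MTRasym at +1.8 ppm) pairs inside the tumor mask, summarized per
(group, day) by their scatter correlation (Pearson with two-sided t-test p,
Spearman alongside), pixel-basis means +/- SDs of both axes, and a
conservative sign classification (negative / positive / none).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cest import MTRMap
from .dwi import ADCMap

__all__ = ["ScatterResult", "assemble_pixel_table", "correlate", "classify_sign"]


@dataclass
class ScatterResult:
    group: str
    day: int
    n_pixels: int
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    mean_adc: float
    sd_adc_pixelwise: float
    mean_mtr: float
    sd_mtr_pixelwise: float
    sign: str = "none"
    zero_variance: bool = False


def assemble_pixel_table(
    adc: ADCMap,
    mtr: MTRMap,
    mask: np.ndarray,
    animal: str = "",
    group: str = "",
    day: int = 0,
) -> pd.DataFrame:
    """One row per in-mask pixel with both maps valid.

    The two maps must already live on the same grid; a shape mismatch is a
    hard error (no silent resampling). Pixels invalid in either map are
    dropped and counted in the ``n_dropped`` attribute of the result.
    """
    if adc.adc.shape != mtr.values.shape:
        raise ValueError(
            f"grid mismatch: ADC map {adc.adc.shape} vs MTR map {mtr.values.shape}"
        )
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != adc.adc.shape:
        raise ValueError(f"mask grid {mask.shape} does not match maps {adc.adc.shape}")
    ok = mask & np.isfinite(adc.adc) & np.isfinite(mtr.values)
    n_dropped = int(mask.sum() - ok.sum())
    idx = np.flatnonzero(ok.ravel())
    table = pd.DataFrame({
        "animal": animal, "group": group, "day": day,
        "pixel": idx,
        "adc": adc.adc.ravel()[idx],
        "mtr_pct": mtr.values.ravel()[idx],
    })
    if table.empty:
        warnings.warn(
            f"empty pixel table for {animal or '<unnamed>'}: "
            f"{n_dropped} in-mask pixels dropped as invalid"
        )
    table.attrs["n_dropped"] = n_dropped
    return table


def _cell_result(group: str, day: int, adc: np.ndarray, mtr: np.ndarray,
                 r: float, p: float, rho: float) -> ScatterResult:
    return ScatterResult(
        group=group, day=day, n_pixels=adc.size,
        pearson_r=r, pearson_p=p, spearman_rho=rho,
        mean_adc=float(adc.mean()), sd_adc_pixelwise=float(adc.std(ddof=1)),
        mean_mtr=float(mtr.mean()), sd_mtr_pixelwise=float(mtr.std(ddof=1)),
    )


def correlate(
    table: pd.DataFrame,
    pooling: str = "pooled",
    r_threshold: float = 0.1,
    alpha: float = 0.05,
) -> list[ScatterResult]:
    """Scatter correlation per (group, day) cell of a pixel table.

    ``pooled`` (default) pools pixels across animals within each cell, the
    convention for one scatter plot per group/day; ``per_animal`` computes
    Pearson/Spearman within each animal and reports their plain mean across
    animals (identical to pooled for a single-animal cell). Zero variance on
    either axis leaves r undefined and the sign ``none`` with a flag.
    """
    if pooling not in ("pooled", "per_animal"):
        raise ValueError(f"unknown pooling {pooling!r}")
    results = []
    for (group, day), sub in table.groupby(["group", "day"], sort=True):
        adc = sub["adc"].to_numpy(dtype=float)
        mtr = sub["mtr_pct"].to_numpy(dtype=float)
        if adc.size < 3:
            raise ValueError(f"cell ({group}, {day}) has fewer than 3 pixels")
        if np.ptp(adc) == 0 or np.ptp(mtr) == 0:
            res = _cell_result(group, day, adc, mtr, np.nan, np.nan, np.nan)
            res.zero_variance = True
            res.sign = "none"
            results.append(res)
            continue
        if pooling == "pooled":
            r, p = stats.pearsonr(adc, mtr)
            rho = stats.spearmanr(adc, mtr).statistic
        else:
            rs, ps, rhos = [], [], []
            for _, asub in sub.groupby("animal"):
                aa = asub["adc"].to_numpy(dtype=float)
                mm = asub["mtr_pct"].to_numpy(dtype=float)
                if aa.size < 3 or np.ptp(aa) == 0 or np.ptp(mm) == 0:
                    continue
                pr = stats.pearsonr(aa, mm)
                rs.append(pr.statistic)
                ps.append(pr.pvalue)
                rhos.append(stats.spearmanr(aa, mm).statistic)
            if not rs:
                res = _cell_result(group, day, adc, mtr, np.nan, np.nan, np.nan)
                res.zero_variance = True
                results.append(res)
                continue
            r, p, rho = float(np.mean(rs)), float(np.mean(ps)), float(np.mean(rhos))
        res = _cell_result(group, day, adc, mtr, float(r), float(p), float(rho))
        res.sign = classify_sign(res, r_threshold=r_threshold, alpha=alpha)
        results.append(res)
    return results


def classify_sign(
    result: ScatterResult,
    r_threshold: float = 0.1,
    alpha: float = 0.05,
) -> str:
    """Conservative sign call: |r| must clear a magnitude and a p-value gate."""
    r, p = result.pearson_r, result.pearson_p
    if not np.isfinite(r) or not np.isfinite(p):
        return "none"
    if r < -r_threshold and p < alpha:
        return "negative"
    if r > r_threshold and p < alpha:
        return "positive"
    return "none"


def results_table(results: list[ScatterResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
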