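"""End-to-end orchestration: simulate -> cest -> dwi -> volume -> scatter -> stats.

A single :class:`RunConfig` drives a deterministic full-study run that writes
the analysis tables (volume timecourse, ADC and MTR summaries on both the
animal and pixel basis, MTR curves, the pixel table and scatter correlations,
ANOVA/Tukey stats) plus a machine-readable manifest with content hashes of
every table, so two runs with the same seed can be compared bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cest, dwi, groupstats, jointpixel, volumetry
from .ioutils import array_hash, dataframe_hash, load_nifti, read_json, write_json
from .phantom import PhantomSpec, build_study

log = logging.getLogger("cestdwi")

__all__ = ["RunConfig", "PipelineResult", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage and offending input."""


@dataclass
class RunConfig:
    """Processing flags and the generative spec for one full run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    b0_correct: bool = True
    b0_window_ppm: float = 1.0
    s0_floor: float = 50.0
    weighted_adc: bool = False
    pooling: str = "pooled"
    curve_aggregation: str = "per_animal_then_group"
    offset_ppm: float = 1.8
    r_threshold: float = 0.1
    alpha: float = 0.05
    make_plots: bool = True

    def to_json(self, path: str | Path) -> None:
        write_json(path, _config_dict(self))


def _phantom_json(spec: PhantomSpec) -> str:
    from .phantom import _spec_to_dict

    return json.dumps(_spec_to_dict(spec))


@dataclass
class PipelineResult:
    out_dir: Path
    tables: dict[str, pd.DataFrame]
    manifest: dict
    elapsed_s: float


def _stage(name: str, what: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed on {what}") from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> PipelineResult:
    """Run the full synthetic study and analysis; return tables + manifest."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study_dir = out / "study"

    with _stage("simulate", "phantom spec"):
        truth = build_study(config.phantom, study_dir)

    geometry = config.phantom.geometry
    factor = geometry.downsample_factor
    central = geometry.n_slices_t2 // 2

    vol_records: list[volumetry.VolumeRecord] = []
    adc_rows, mtr_rows = [], []
    pixel_tables = []
    curve_entries: dict[tuple[str, int], list] = {}
    drop_log = {"invalid_s0": 0, "nonpositive_dwi": 0, "pixel_table": 0}

    for rec in truth.manifest.itertuples():
        key = f"{rec.animal} day {rec.day}"
        with _stage("volume", rec.mask_t2):
            mask_t2 = load_nifti(rec.mask_t2).astype(np.uint8)
            roi = volumetry.ROIMask(labels=mask_t2, geometry=geometry)
            vol_records.append(volumetry.VolumeRecord(
                animal=rec.animal, group=rec.group, day=rec.day,
                volume_mm3=volumetry.tumor_volume(roi),
                n_pixels=int(mask_t2.sum()),
            ))
            mask128 = volumetry.downsample_mask(mask_t2[:, :, central], factor)

        with _stage("cest", rec.cest):
            series = load_nifti(rec.cest)[:, :, 0, :]
            sidecar = read_json(rec.cest_sidecar)
            offsets = np.asarray(sidecar["offsets_ppm"], dtype=float)
            z, s0, valid = cest.normalize_series(
                series, offsets, sidecar.get("reference_index", 0),
                s0_floor=config.s0_floor,
            )
            drop_log["invalid_s0"] += int((~valid & mask128).sum())
            if config.b0_correct:
                z, _shifts = cest.b0_correct_stack(
                    z, offsets, mask128 & valid, config.b0_window_ppm)
            mmap = cest.mtr_map(z, offsets, mask128, config.offset_ppm)
            mtr_rows.append(_roi_row(rec, mmap.values, mask128, scale=1.0))
            curve_entries.setdefault((rec.group, rec.day), []).append(
                (z, mask128 & valid))

        with _stage("dwi", rec.dwi):
            dseries = load_nifti(rec.dwi)[:, :, 0, :]
            bvals = np.asarray(read_json(rec.dwi_sidecar)["bvalues_s_per_mm2"],
                               dtype=float)
            amap = dwi.adc_map(dwi.DWISeries(b_values=bvals, signals=dseries),
                               mask128, weighted=config.weighted_adc)
            drop_log["nonpositive_dwi"] += amap.n_dropped_signals
            adc_rows.append(_roi_row(rec, amap.adc, mask128, scale=1.0))

        with _stage("scatter", key):
            table = jointpixel.assemble_pixel_table(
                amap, mmap, mask128, animal=rec.animal,
                group=rec.group, day=rec.day)
            drop_log["pixel_table"] += table.attrs["n_dropped"]
            pixel_tables.append(table)

    tables: dict[str, pd.DataFrame] = {}
    with _stage("aggregate", "volume tables"):
        tables["volumes"] = pd.DataFrame([r.__dict__ for r in vol_records])
        tables["volume_timecourse"] = volumetry.volume_timecourse(vol_records)
    with _stage("aggregate", "map summaries"):
        tables["adc_animal_summary"] = pd.DataFrame(adc_rows)
        tables["mtr_animal_summary"] = pd.DataFrame(mtr_rows)
        pixel_table = pd.concat(pixel_tables, ignore_index=True)
        tables["pixel_table"] = pixel_table
        tables["adc_pixel_summary"] = _pixel_summary(pixel_table, "adc")
        tables["mtr_pixel_summary"] = _pixel_summary(pixel_table, "mtr_pct")
    with _stage("aggregate", "MTR curves"):
        rows = []
        for (group, day), entries in sorted(curve_entries.items()):
            curve = cest.mtr_curve(entries, offsets,
                                   aggregation=config.curve_aggregation)
            for o, m, s in zip(curve.offsets_ppm, curve.mtr_pct, curve.dispersion):
                rows.append({"group": group, "day": day, "offset_ppm": o,
                             "mean_pct": m, "sd_pct": s, "n": curve.n,
                             "aggregation": curve.aggregation})
        tables["mtr_curves"] = pd.DataFrame(rows)
    with _stage("scatter", "correlation"):
        results = jointpixel.correlate(pixel_table, pooling=config.pooling,
                                       r_threshold=config.r_threshold,
                                       alpha=config.alpha)
        tables["scatter_results"] = jointpixel.results_table(results)
    with _stage("stats", "ANOVA/Tukey"):
        tables["stats"] = _stats_table(tables, config.alpha)

    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)

    if config.make_plots:
        with _stage("plots", "scatter figures"):
            _scatter_plots(pixel_table, out / "plots")

    manifest = {
        "seed": config.phantom.seed,
        "config": _config_dict(config),
        "pixel_drops": drop_log,
        "hashes": {name: dataframe_hash(df) for name, df in tables.items()},
        "truth_hashes": {
            f"{g}_{d}_{a}": array_hash(np.nan_to_num(t.adc_map, nan=-1.0))
            for (g, d, a), t in sorted(truth.records.items())
        },
        "artifacts": sorted(p.name for p in out.glob("*.csv")),
    }
    write_json(out / "run_manifest.json", manifest)
    elapsed = time.time() - t0
    log.info("pipeline finished in %.1f s; pixel drops: %s", elapsed, drop_log)
    return PipelineResult(out_dir=out, tables=tables, manifest=manifest,
                          elapsed_s=elapsed)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return str(obj)


def _config_dict(config: RunConfig) -> dict:
    d = {f.name: getattr(config, f.name) for f in dataclasses.fields(config)
         if f.name != "phantom"}
    d["phantom"] = json.loads(_phantom_json(config.phantom))
    return json.loads(json.dumps(d, default=_jsonable))


def _roi_row(rec, values: np.ndarray, mask: np.ndarray, scale: float) -> dict:
    v = values[mask]
    v = v[np.isfinite(v)]
    return {
        "animal": rec.animal, "group": rec.group, "day": rec.day,
        "n_pixels": int(v.size),
        "mean": float(v.mean()) * scale if v.size else float("nan"),
        "sd": float(v.std(ddof=1)) * scale if v.size > 1 else 0.0,
    }


def _pixel_summary(pixel_table: pd.DataFrame, column: str) -> pd.DataFrame:
    rows = []
    for (group, day), sub in pixel_table.groupby(["group", "day"], sort=True):
        v = sub[column].to_numpy(dtype=float)
        rows.append({"group": group, "day": day, "n_pixels": v.size,
                     "mean": v.mean(),
                     "sd_pixelwise": v.std(ddof=1) if v.size > 1 else 0.0})
    return pd.DataFrame(rows)


def _stats_table(tables: dict[str, pd.DataFrame], alpha: float) -> pd.DataFrame:
    """All-pairs Tukey over group:day cells for volume, ADC and MTR."""
    frames = []
    specs = [
        ("volume_mm3", tables["volumes"], "volume_mm3"),
        ("adc_animal_mean", tables["adc_animal_summary"], "mean"),
        ("mtr_animal_mean", tables["mtr_animal_summary"], "mean"),
    ]
    for measure, df, col in specs:
        levels = df["group"].astype(str) + ":d" + df["day"].astype(str)
        if levels.nunique() < 2:
            continue
        res = groupstats.anova_tukey(df[col], levels, measure=measure,
                                     alpha=alpha)
        pairs = res.pairs.copy()
        pairs.insert(0, "measure", measure)
        pairs["anova_F"] = res.anova_F
        pairs["anova_p"] = res.anova_p
        frames.append(pairs)
    if not frames:  # single design cell: nothing to compare
        return pd.DataFrame(columns=["measure", "level_a", "level_b",
                                     "meandiff", "p_tukey", "stars",
                                     "anova_F", "anova_p"])
    return pd.concat(frames, ignore_index=True)


def _scatter_plots(pixel_table: pd.DataFrame, plot_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir.mkdir(parents=True, exist_ok=True)
    for (group, day), sub in pixel_table.groupby(["group", "day"], sort=True):
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(sub["adc"] * 1e3, sub["mtr_pct"], s=4, alpha=0.4)
        ax.set_xlabel("ADC (x10$^{-3}$ mm$^2$/s)")
        ax.set_ylabel("MTR asymmetry at 1.8 ppm (%)")
        ax.set_title(f"{group}, day {day} (n={len(sub)})")
        fig.tight_layout()
        fig.savefig(plot_dir / f"scatter_{group}_day{day:02d}.png", dpi=110)
        plt.close(fig)
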