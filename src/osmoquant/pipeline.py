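"""End-to-end orchestration: simulate -> screen -> annotate -> quantify -> stats.

A :class:`PipelineConfig` (human-editable YAML) drives the whole chain
and every tolerance in one place; the report bundle written to the
output directory echoes the effective settings and a config hash so a
run can be reproduced exactly.  All outputs are deterministic for a
fixed config and seed (no timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .msms import DEFAULT_MSMS_TOL_PPM, annotate_fragments
from .quant import SampleContext, fit_calibration, quantify_run
from .scenarios import ANALYTES, get_scenario
from .recovery import calibration_curve_for_seed, child_seeds
from .screening import (
    DEFAULT_TOL_PPM,
    attach_isotopologues,
    detect_features,
    differential_screen,
    extract_xic,
)
from .simulate import simulate_calibration, simulate_experiment
from .quant import integrate_peak
from .scenarios import default_calibration_design
from .stats import GroupSeries, tukey_hsd
from .run_io import load_run, write_mzml

log = logging.getLogger("osmoquant")

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline",
           "stage_simulate", "stage_screen", "stage_annotate",
           "stage_quantify", "stage_stats"]

#: The published MS/MS fragment peaks of cysteinolic acid [M+H]+ used by
#: the demo annotate stage: the precursor, the -H2O fragment and the
#: -(H2O + sulfonic group) fragment.
DEMO_MSMS_PEAKS = (156.03232, 138.02196, 56.04979)


class ConfigError(ValueError):
    """Configuration validation failure; message names the field."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on, in one validated place."""

    outdir: str
    seed: int = 0
    scenario: str = "tw_xenic"
    analyte: str = "cysteinolic acid"
    run_format: str = "json"            # "json" or "mzml"
    calibration_file: str | None = None  # CSV of measured points; None = simulate
    mz_tol_ppm: float = DEFAULT_TOL_PPM
    rt_tol_min: float = 0.3
    msms_tol_ppm: float = DEFAULT_MSMS_TOL_PPM
    min_snr: float = 3.0
    min_scans: int = 5
    fc_min: float = 1.5
    p_max: float = 0.05
    msms_peaks: tuple[float, ...] = DEMO_MSMS_PEAKS
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("mz_tol_ppm", "rt_tol_min", "msms_tol_ppm", "min_snr",
                     "fc_min", "p_max"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be > 0")
        if self.run_format not in ("json", "mzml"):
            raise ConfigError(f"run_format: must be 'json' or 'mzml'")
        if self.analyte not in ANALYTES:
            raise ConfigError(f"analyte: unknown analyte {self.analyte!r}")
        try:
            get_scenario(self.scenario)
        except KeyError as exc:
            raise ConfigError(f"scenario: {exc}") from exc
        if self.calibration_file is not None and not Path(self.calibration_file).exists():
            raise ConfigError(
                f"calibration_file: path does not exist: {self.calibration_file}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "msms_peaks" in payload:
            payload["msms_peaks"] = tuple(payload["msms_peaks"])
        config = cls(**payload)
        config.validate()
        return config

    def digest(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("outdir", "log_level")}
        canon = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# -- individual stages (each runnable on the previous stage's files) -----

def stage_simulate(config: PipelineConfig, outdir: Path) -> tuple[list[Path], Path]:
    """Simulate the scenario's runs plus a calibration series; write them."""
    scenario = get_scenario(config.scenario)
    runs_dir = outdir / "runs"
    runs_dir.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(config.seed, 2)
    run_paths: list[Path] = []
    meta_rows = []
    for run, meta in simulate_experiment(scenario, seed=seeds[0]):
        suffix = ".mzML" if config.run_format == "mzml" else ".json"
        path = runs_dir / f"{meta['sample_id']}{suffix}"
        if config.run_format == "mzml":
            write_mzml(run, path)
        else:
            run.save_json(path)
        run_paths.append(path)
        meta_rows.append({
            "sample_id": meta["sample_id"],
            "condition": meta["condition"],
            "replicate": meta["replicate"],
            "path": path.name,
            "cells_filtered": meta["cells_filtered"],
            "extract_volume_ml": meta["extract_volume_ml"],
            "dilution_factor": meta["dilution_factor"],
            "cell_volume_pl": meta["cell_volume_pl"],
        })
    pd.DataFrame(meta_rows).to_csv(outdir / "metadata.csv", index=False)

    design = default_calibration_design(ANALYTES[config.analyte])
    cal_rows = []
    for level, run in simulate_calibration(design, seed=seeds[1]):
        xic = extract_xic(run, design.analyte.mz, tol_ppm=config.mz_tol_ppm)
        area = integrate_peak(xic, (design.analyte.rt_min - 0.25,
                                    design.analyte.rt_min + 0.25))
        cal_rows.append({"concentration_um": level, "area": area})
    cal_path = outdir / "calibration.csv"
    pd.DataFrame(cal_rows).to_csv(cal_path, index=False)
    log.info("simulate: %d runs + %d calibration points",
             len(run_paths), len(cal_rows))
    return run_paths, cal_path


def stage_screen(run_paths: list[Path], metadata: pd.DataFrame,
                 config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    """Detect features per run, attach envelopes, screen low vs high salinity."""
    features_dir = outdir / "features"
    features_dir.mkdir(parents=True, exist_ok=True)
    by_condition: dict[str, list] = {}
    meta_by_sample = metadata.set_index("sample_id")
    for path in run_paths:
        run = load_run(path)
        sample_id = str(run.metadata.get("sample_id") or path.stem)
        feats = detect_features(run, min_snr=config.min_snr,
                                min_scans=config.min_scans,
                                tol_ppm=config.mz_tol_ppm)
        feats = attach_isotopologues(feats, run, tol_ppm=config.mz_tol_ppm)
        from .screening import sulfur_flag as _sflag
        pd.DataFrame([{
            "mz": f.mz, "rt_min": f.rt_min, "area": f.area, "snr": f.snr,
            "m2_shift": next((d for d, _ in f.envelope if d > 1.5), np.nan),
            "m2_ratio": next((a for d, a in f.envelope if d > 1.5), np.nan),
            "sulfur_flag": _sflag(f),
            "is_isotopologue": f.is_isotopologue,
        } for f in feats]).to_csv(features_dir / f"{sample_id}.csv", index=False)
        condition = str(meta_by_sample.loc[sample_id, "condition"])
        by_condition.setdefault(condition, []).append(feats)
    conditions = list(dict.fromkeys(metadata["condition"]))
    low, high = conditions[0], conditions[-1]
    candidates = differential_screen(
        by_condition[low], by_condition[high],
        fc_min=config.fc_min, p_max=config.p_max,
        tol_ppm=config.mz_tol_ppm, rt_tol_min=config.rt_tol_min,
    )
    table = pd.DataFrame([{
        "mz": c.mz, "rt_min": c.rt_min, "fold_change": c.fold_change,
        "p_value": c.p_value, "sulfur_flag": c.sulfur,
        "mean_low": c.mean_low, "mean_high": c.mean_high,
    } for c in candidates])
    table.to_csv(outdir / "candidates.csv", index=False)
    log.info("screen: %s vs %s -> %d candidates", low, high, len(table))
    return table


def stage_annotate(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    """Annotate the configured MS/MS peaks against the target analyte."""
    analyte = ANALYTES[config.analyte]
    assignments = annotate_fragments(
        analyte.formula, analyte.adduct, list(config.msms_peaks),
        tol_ppm=config.msms_tol_ppm,
    )
    table = pd.DataFrame([{
        "observed_mz": a.observed_mz,
        "assignment": a.label,
        "theoretical_mz": a.theoretical_mz,
        "error_ppm": a.error_ppm,
    } for a in assignments])
    table.to_csv(outdir / "assignments.csv", index=False)
    log.info("annotate: %d/%d peaks assigned",
             int(sum(a.assigned for a in assignments)), len(assignments))
    return table


def stage_quantify(run_paths: list[Path], metadata: pd.DataFrame,
                   calibration: pd.DataFrame, config: PipelineConfig,
                   outdir: Path) -> pd.DataFrame:
    """Fit the calibration and quantify the target analyte in every run."""
    if not {"concentration_um", "area"} <= set(calibration.columns):
        raise ConfigError(
            "calibration_file: expected columns concentration_um, area"
        )
    curve = fit_calibration(
        list(zip(calibration["concentration_um"], calibration["area"])),
        analyte=config.analyte,
    )
    analyte = ANALYTES[config.analyte]
    meta_by_sample = metadata.set_index("sample_id")
    rows = []
    for path in run_paths:
        run = load_run(path)
        sample_id = str(run.metadata.get("sample_id") or path.stem)
        meta = meta_by_sample.loc[sample_id]
        ctx = SampleContext(
            cells_filtered=float(meta["cells_filtered"]),
            extract_volume_ml=float(meta["extract_volume_ml"]),
            dilution_factor=float(meta["dilution_factor"]),
            cell_volume_pl=float(meta["cell_volume_pl"]),
        )
        q = quantify_run(run, analyte, curve, ctx, tol_ppm=config.mz_tol_ppm)
        rows.append({
            "sample_id": sample_id,
            "condition": str(meta["condition"]),
            "analyte": q.analyte,
            "area": q.area,
            "extract_conc_um": q.extract_conc_um,
            "per_cell_fmol": q.per_cell_fmol,
            "intracellular_mm": q.intracellular_mm,
            "flag": q.flag.value,
        })
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "quant.csv", index=False)
    curve_info = {
        "analyte": curve.analyte, "slope": curve.slope, "r": curve.r,
        "lod_um": curve.lod_um, "loq_um": curve.loq_um, "n": curve.n_points,
    }
    (outdir / "calibration_fit.json").write_text(
        json.dumps(curve_info, sort_keys=True, indent=1))
    log.info("quantify: slope=%.4g r=%.4f LOD=%.3g LOQ=%.3g",
             curve.slope, curve.r, curve.lod_um, curve.loq_um)
    return table


def stage_stats(quant: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    """Per-condition comparison: ANOVA + Tukey on per-cell amounts."""
    groups = [
        GroupSeries(label=str(cond), values=tuple(sub["per_cell_fmol"]))
        for cond, sub in quant.groupby("condition", sort=False)
    ]
    comparisons = tukey_hsd(groups)
    table = pd.DataFrame([{
        "reference": c.pair[0], "treatment": c.pair[1],
        "fold_change": c.fold_change, "anova_f": c.anova_f,
        "anova_p": c.anova_p, "tukey_p": c.tukey_p, "label": c.label,
    } for c in comparisons])
    table.to_csv(outdir / "comparisons.csv", index=False)
    log.info("stats: %d pairwise comparisons", len(table))
    return table


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle.

    Returns the machine-readable summary (also written as summary.json).
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    run_paths, cal_path = stage_simulate(config, outdir)
    metadata = pd.read_csv(outdir / "metadata.csv")
    candidates = stage_screen(run_paths, metadata, config, outdir)
    assignments = stage_annotate(config, outdir)
    cal_source = Path(config.calibration_file) if config.calibration_file else cal_path
    calibration = pd.read_csv(cal_source)
    quant = stage_quantify(run_paths, metadata, calibration, config, outdir)
    if quant["condition"].nunique() >= 2:
        comparisons = stage_stats(quant, outdir)
        comparison_rows = comparisons.to_dict(orient="records")
    else:
        comparison_rows = []

    per_condition = {
        str(cond): float(sub["per_cell_fmol"].mean())
        for cond, sub in quant.groupby("condition", sort=False)
    }
    summary = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.digest(),
        "n_runs": len(run_paths),
        "n_candidates": int(len(candidates)),
        "n_sulfur_candidates": int(candidates["sulfur_flag"].sum())
        if len(candidates) else 0,
        "assignments": assignments.to_dict(orient="records"),
        "per_condition_mean_fmol_per_cell": per_condition,
        "comparisons": comparison_rows,
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=1))
    return summary
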