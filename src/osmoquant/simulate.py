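"""Seeded synthetic LC-HRMS data with the statistical structure the
analysis assumes.

The generator stands in for the wet lab: it renders centroided runs in
which each analyte elutes as a Gaussian peak at its retention time,
carrying its full isotope envelope (from :mod:`osmoquant.chem`), on top of
a sparse random-noise baseline.  Three layers of randomness, all driven by
a single integer seed:

* biological scatter — per-replicate true per-cell amounts jittered by a
  mean-preserving log-normal with the configured biological CV;
* technical scatter — multiplicative log-normal noise on every centroid;
* baseline — Poisson-thinned random centroids across the m/z range.

Amount bookkeeping mirrors a filtration-based workflow: a known culture
volume at a known cell density is filtered, extracted into a fixed
extract volume, diluted, and injected.  The concentration actually
rendered into a run is the *measured* (post-dilution) concentration, so a
downstream quantification must undo the dilution and normalize by cells
to recover fmol/cell — exactly the chain the real analysis performs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .chem import AdductSpec, Formula, IsotopePattern, M_PLUS_H, adduct_mz, isotope_pattern
from .run_io import SyntheticRun

__all__ = [
    "AnalyteDef",
    "NoiseModel",
    "RunSettings",
    "ScenarioConfig",
    "CalibrationDesign",
    "simulate_run",
    "simulate_experiment",
    "simulate_calibration",
    "measured_concentration_um",
]


@dataclass(frozen=True)
class AnalyteDef:
    """A targeted analyte: identity, chromatography, and detector response."""

    name: str
    formula: Formula
    rt_min: float
    response_factor: float          # XIC area units per uM
    adduct: AdductSpec = M_PLUS_H

    def __post_init__(self) -> None:
        if self.response_factor <= 0:
            raise ValueError(f"response factor must be > 0 for {self.name}")

    @property
    def mz(self) -> float:
        return adduct_mz(self.formula, self.adduct)


@dataclass(frozen=True)
class NoiseModel:
    """Technical noise: per-centroid log-normal CV plus a random baseline."""

    technical_cv: float = 0.02
    baseline_rate: float = 2.0       # expected baseline centroids per scan
    baseline_intensity: float = 5e4  # exponential scale of baseline heights

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(technical_cv=0.0, baseline_rate=0.0)


@dataclass(frozen=True)
class RunSettings:
    """Acquisition geometry: 18 min runs, 0.5 s scans, m/z 75-200."""

    length_min: float = 18.0
    scan_interval_s: float = 0.5
    mz_range: tuple[float, float] = (75.0, 200.0)
    peak_sigma_min: float = 0.05
    pattern_threshold: float = 1e-4


@dataclass(frozen=True)
class CalibrationDesign:
    """An external-calibration dilution series for one analyte."""

    analyte: AnalyteDef
    levels_um: tuple[float, ...]
    replicates: int = 3
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(baseline_rate=0.5))

    def __post_init__(self) -> None:
        levels = tuple(self.levels_um)
        if any(c <= 0 for c in levels) or len(set(levels)) != len(levels):
            raise ValueError("calibration levels must be strictly positive and distinct")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        object.__setattr__(self, "levels_um", levels)


@dataclass(frozen=True)
class ScenarioConfig:
    """A multi-condition culture experiment.

    ``conditions`` maps condition label -> {analyte name: true fmol/cell}.
    The same analyte set must appear in every condition.
    """

    species: str
    analytes: tuple[AnalyteDef, ...]
    conditions: tuple[tuple[str, dict[str, float]], ...]
    replicates: int = 3
    biological_cv: float = 0.10
    cell_density_per_ml: float = 1e5
    culture_volume_ml: float = 30.0
    extract_volume_ml: float = 1.0
    dilution_factor: float = 3.0
    cell_volume_pl: float = 1.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    settings: RunSettings = field(default_factory=RunSettings)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.biological_cv < 0:
            raise ValueError("biological CV must be >= 0")
        for name, value in (
            ("cell_density_per_ml", self.cell_density_per_ml),
            ("culture_volume_ml", self.culture_volume_ml),
            ("extract_volume_ml", self.extract_volume_ml),
            ("dilution_factor", self.dilution_factor),
            ("cell_volume_pl", self.cell_volume_pl),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be > 0")
        names = {a.name for a in self.analytes}
        for label, amounts in self.conditions:
            if set(amounts) != names:
                raise ValueError(
                    f"condition {label!r} does not cover the scenario analyte set"
                )

    @property
    def cells_filtered(self) -> float:
        return self.cell_density_per_ml * self.culture_volume_ml

    def with_(self, **changes) -> "ScenarioConfig":
        return replace(self, **changes)


def measured_concentration_um(per_cell_fmol: float, scenario: ScenarioConfig) -> float:
    """Post-dilution extract concentration (uM) implied by a per-cell amount.

    fmol/cell x cells filtered gives total fmol; 1 uM in 1 mL is 1e6 fmol.
    """
    total_fmol = per_cell_fmol * scenario.cells_filtered
    extract_um = total_fmol / 1e6 / scenario.extract_volume_ml
    return extract_um / scenario.dilution_factor


_pattern_cache: dict[tuple[Formula, float], IsotopePattern] = {}


def _cached_pattern(formula: Formula, threshold: float) -> IsotopePattern:
    key = (formula, threshold)
    if key not in _pattern_cache:
        _pattern_cache[key] = isotope_pattern(formula, abundance_threshold=threshold)
    return _pattern_cache[key]


def simulate_run(
    analytes: list[AnalyteDef] | tuple[AnalyteDef, ...],
    amounts_um: dict[str, float],
    noise: NoiseModel | None = None,
    seed: int = 0,
    settings: RunSettings | None = None,
    metadata: dict | None = None,
) -> SyntheticRun:
    """Render one centroided run with the given analytes at the given
    (post-dilution) concentrations in uM.

    Identical arguments and seed give a bit-identical run.
    """
    if not analytes:
        raise ValueError("analyte list must not be empty")
    for name, amount in amounts_um.items():
        if amount < 0:
            raise ValueError(f"negative amount for {name}: {amount}")
    noise = NoiseModel() if noise is None else noise
    settings = RunSettings() if settings is None else settings
    rng = np.random.default_rng(seed)

    dt_min = settings.scan_interval_s / 60.0
    times = np.arange(0.0, settings.length_min, dt_min)
    n_scans = times.size
    sigma = settings.peak_sigma_min
    lo, hi = settings.mz_range

    scan_parts: list[np.ndarray] = []
    mz_parts: list[np.ndarray] = []
    inten_parts: list[np.ndarray] = []

    for analyte in analytes:
        conc = amounts_um.get(analyte.name, 0.0)
        if conc <= 0:
            continue
        area = analyte.response_factor * conc          # intensity x minutes
        apex = area / (sigma * math.sqrt(2.0 * math.pi))
        in_window = np.nonzero(np.abs(times - analyte.rt_min) <= 5.0 * sigma)[0]
        if in_window.size == 0:
            continue
        profile = apex * np.exp(
            -0.5 * ((times[in_window] - analyte.rt_min) / sigma) ** 2
        )
        pattern = _cached_pattern(analyte.formula, settings.pattern_threshold)
        shifts = np.array([s for s, _ in pattern.peaks])
        abund = np.array([a for _, a in pattern.peaks])
        mzs = analyte.mz + shifts / analyte.adduct.charge
        keep = (mzs >= lo) & (mzs <= hi)
        mzs, abund = mzs[keep], abund[keep]
        scan_parts.append(np.repeat(in_window, mzs.size))
        mz_parts.append(np.tile(mzs, in_window.size))
        inten_parts.append(np.outer(profile, abund).ravel())

    # baseline noise centroids (drawn after all analytes, in a fixed order)
    if noise.baseline_rate > 0:
        counts = rng.poisson(noise.baseline_rate, n_scans)
        total = int(counts.sum())
        scan_parts.append(np.repeat(np.arange(n_scans), counts))
        mz_parts.append(rng.uniform(lo, hi, total))
        inten_parts.append(rng.exponential(noise.baseline_intensity, total))

    if scan_parts:
        scan_idx = np.concatenate(scan_parts)
        mz = np.concatenate(mz_parts)
        inten = np.concatenate(inten_parts)
    else:
        scan_idx = np.empty(0, dtype=np.int64)
        mz = np.empty(0)
        inten = np.empty(0)

    if noise.technical_cv > 0 and inten.size:
        s = math.sqrt(math.log1p(noise.technical_cv ** 2))
        inten = inten * np.exp(rng.normal(-0.5 * s * s, s, inten.size))

    order = np.lexsort((mz, scan_idx))
    meta = {"seed": int(seed)}
    if metadata:
        meta.update(metadata)
    return SyntheticRun(
        times_min=times,
        scan_index=scan_idx[order],
        mz=mz[order],
        intensity=inten[order],
        metadata=meta,
    )


def simulate_experiment(
    scenario: ScenarioConfig, seed: int = 0
) -> list[tuple[SyntheticRun, dict]]:
    """Simulate one full multi-condition experiment.

    Returns one ``(run, sample metadata)`` pair per replicate per
    condition.  Metadata carries the jittered *true* per-cell amounts and
    the sample context (cells filtered, volumes, dilution, cell volume) so
    recovery can be checked against ground truth.
    """
    seeds = np.random.SeedSequence(seed).generate_state(
        len(scenario.conditions) * scenario.replicates * 2
    ) % (2 ** 31)
    out: list[tuple[SyntheticRun, dict]] = []
    k = 0
    for label, true_amounts in scenario.conditions:
        for rep in range(scenario.replicates):
            jitter_rng = np.random.default_rng(int(seeds[k]))
            run_seed = int(seeds[k + 1])
            k += 2
            if scenario.biological_cv > 0:
                s = math.sqrt(math.log1p(scenario.biological_cv ** 2))
                factors = {
                    name: math.exp(jitter_rng.normal(-0.5 * s * s, s))
                    for name in sorted(true_amounts)
                }
            else:
                factors = {name: 1.0 for name in true_amounts}
            sample_per_cell = {
                name: true_amounts[name] * factors[name] for name in true_amounts
            }
            amounts_um = {
                name: measured_concentration_um(value, scenario)
                for name, value in sample_per_cell.items()
            }
            sample_id = f"{scenario.species}_{label}_r{rep + 1}".replace(" ", "")
            meta = {
                "sample_id": sample_id,
                "species": scenario.species,
                "condition": label,
                "replicate": rep + 1,
                "true_per_cell_fmol": sample_per_cell,
                "configured_per_cell_fmol": dict(true_amounts),
                "cells_filtered": scenario.cells_filtered,
                "extract_volume_ml": scenario.extract_volume_ml,
                "dilution_factor": scenario.dilution_factor,
                "cell_volume_pl": scenario.cell_volume_pl,
            }
            run = simulate_run(
                list(scenario.analytes),
                amounts_um,
                noise=scenario.noise,
                seed=run_seed,
                settings=scenario.settings,
                metadata=meta,
            )
            out.append((run, meta))
    return out


def simulate_calibration(
    design: CalibrationDesign,
    seed: int = 0,
    settings: RunSettings | None = None,
) -> list[tuple[float, SyntheticRun]]:
    """Simulate a dilution series: one run per level per replicate."""
    settings = RunSettings() if settings is None else settings
    n = len(design.levels_um) * design.replicates
    seeds = np.random.SeedSequence(seed).generate_state(max(n, 1)) % (2 ** 31)
    out = []
    k = 0
    for level in design.levels_um:
        for rep in range(design.replicates):
            run = simulate_run(
                [design.analyte],
                {design.analyte.name: level},
                noise=design.noise,
                seed=int(seeds[k]),
                settings=settings,
                metadata={
                    "sample_id": f"cal_{design.analyte.name}_{level}uM_r{rep + 1}".replace(" ", ""),
                    "concentration_um": level,
                    "replicate": rep + 1,
                },
            )
            out.append((level, run))
            k += 1
    return out
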