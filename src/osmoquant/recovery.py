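"""End-to-end parameter-recovery experiments on the packaged scenarios.

Each experiment runs the full measurement chain — simulate the culture
experiment and an external calibration batch, extract and integrate the
cysteinolic acid XIC, invert the fitted calibration, normalize to
fmol/cell — and summarizes recovered quantities over independent seeds.
One calibration batch is simulated and fitted per seed and shared by all
scenarios quantified under that seed, mirroring per-batch calibration
practice.
"""

from __future__ import annotations

from dataclasses import dataclass
import zlib

import numpy as np

from .quant import (
    CalibrationCurve,
    SampleContext,
    fit_calibration,
    integrate_peak,
    quantify_run,
)
from .scenarios import CYSTEINOLIC_ACID, default_calibration_design
from .screening import extract_xic
from .simulate import ScenarioConfig, simulate_calibration, simulate_experiment

__all__ = [
    "child_seeds",
    "calibration_curve_for_seed",
    "condition_means",
    "fold_change_recovery",
    "baseline_ratio_recovery",
    "intracellular_recovery",
]


def child_seeds(base_seed: int, n: int, salt: str = "") -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from one base seed.

    An optional string salt decorrelates streams that share a base seed
    (e.g. two scenarios recovered side by side must not reuse the same
    biological jitter).
    """
    entropy = [base_seed]
    if salt:
        entropy.append(zlib.crc32(salt.encode()))
    return [int(s) for s in
            np.random.SeedSequence(entropy).generate_state(n) % (2 ** 31)]


def calibration_curve_for_seed(seed: int) -> CalibrationCurve:
    """Simulate and fit one external calibration batch."""
    design = default_calibration_design()
    points = []
    for level, run in simulate_calibration(design, seed=seed):
        xic = extract_xic(run, design.analyte.mz)
        area = integrate_peak(
            xic,
            (design.analyte.rt_min - 0.25, design.analyte.rt_min + 0.25),
        )
        points.append((level, area))
    return fit_calibration(points, analyte=design.analyte.name)


@dataclass(frozen=True)
class SeedRecovery:
    """Recovered per-condition mean fmol/cell for one seed."""

    seed: int
    means: dict[str, float]
    n_runs: int


def _context(scenario: ScenarioConfig) -> SampleContext:
    return SampleContext(
        cells_filtered=scenario.cells_filtered,
        extract_volume_ml=scenario.extract_volume_ml,
        dilution_factor=scenario.dilution_factor,
        cell_volume_pl=scenario.cell_volume_pl,
    )


def condition_means(
    scenario: ScenarioConfig,
    base_seed: int,
    n_seeds: int = 10,
    curves: list[CalibrationCurve] | None = None,
) -> list[SeedRecovery]:
    """Recover per-condition mean fmol/cell of cysteinolic acid, per seed."""
    seeds = child_seeds(base_seed, 2 * n_seeds, salt=scenario.species)
    ctx = _context(scenario)
    out = []
    for k in range(n_seeds):
        exp_seed, cal_seed = seeds[2 * k], seeds[2 * k + 1]
        curve = (curves[k] if curves is not None
                 else calibration_curve_for_seed(cal_seed))
        per_condition: dict[str, list[float]] = {}
        samples = simulate_experiment(scenario, seed=exp_seed)
        for run, meta in samples:
            result = quantify_run(run, CYSTEINOLIC_ACID, curve, ctx)
            per_condition.setdefault(meta["condition"], []).append(
                result.per_cell_fmol
            )
        out.append(SeedRecovery(
            seed=exp_seed,
            means={c: float(np.mean(v)) for c, v in per_condition.items()},
            n_runs=len(samples),
        ))
    return out


def fold_change_recovery(
    scenario: ScenarioConfig,
    reference: str,
    treatment: str,
    base_seed: int,
    n_seeds: int = 10,
) -> tuple[float, int]:
    """Mean over seeds of mean(treatment)/mean(reference) fmol/cell.

    Returns ``(mean fold change, total runs simulated)``.
    """
    recoveries = condition_means(scenario, base_seed, n_seeds)
    ratios = [r.means[treatment] / r.means[reference] for r in recoveries]
    n_runs = sum(r.n_runs for r in recoveries)
    return float(np.mean(ratios)), n_runs


def baseline_ratio_recovery(
    scenario_a: ScenarioConfig,
    scenario_b: ScenarioConfig,
    condition: str,
    base_seed: int,
    n_seeds: int = 10,
) -> tuple[float, int]:
    """Mean over seeds of the A/B ratio of recovered means in one condition.

    Both scenarios are quantified against the same per-seed calibration
    batch (they would be measured in the same analytical batch).
    """
    seeds = child_seeds(base_seed, 2 * n_seeds)
    curves = [calibration_curve_for_seed(seeds[2 * k + 1])
              for k in range(n_seeds)]
    rec_a = condition_means(scenario_a, base_seed, n_seeds, curves=curves)
    rec_b = condition_means(scenario_b, base_seed, n_seeds, curves=curves)
    ratios = [a.means[condition] / b.means[condition]
              for a, b in zip(rec_a, rec_b)]
    n_runs = sum(r.n_runs for r in rec_a + rec_b)
    return float(np.mean(ratios)), n_runs


def intracellular_recovery(
    scenario: ScenarioConfig,
    condition: str,
    base_seed: int,
    n_seeds: int = 10,
) -> tuple[float, int]:
    """Mean over seeds of the recovered intracellular concentration in mM."""
    recoveries = condition_means(scenario, base_seed, n_seeds)
    mm = [r.means[condition] / scenario.cell_volume_pl for r in recoveries]
    n_runs = sum(r.n_runs for r in recoveries)
    return float(np.mean(mm)), n_runs
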