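#!/usr/bin/env python
"""Quantify cysteinolic acid per cell and compare salinity conditions.

Fits the external calibration from the simulated dilution series, inverts
it for every run of the xenic and axenic experiments, normalizes to
fmol/cell, and runs one-way ANOVA with Tukey HSD across the three
salinity conditions of each culture type.  The headline numbers are the
long-term fold changes (~2.4x xenic, ~2.6x axenic) and the elevated
axenic baseline (~1.5x).
"""

import sys
from pathlib import Path

import pandas as pd

from osmoquant.pipeline import PipelineConfig, stage_quantify, stage_stats

BASE = Path(__file__).resolve().parent.parent
SCRATCH = BASE / "scratch" / "analysis"
RESULTS = BASE / "results"


def main() -> int:
    RESULTS.mkdir(exist_ok=True)
    quant_tables, comparison_tables = [], []
    for scenario in ("tw_xenic", "tw_axenic"):
        indir = SCRATCH / scenario
        if not indir.exists():
            print("run 01_simulate_experiments.py first", file=sys.stderr)
            return 1
        config = PipelineConfig(outdir=str(indir))
        metadata = pd.read_csv(indir / "metadata.csv")
        run_paths = [indir / "runs" / name for name in metadata["path"]]
        calibration = pd.read_csv(indir / "calibration.csv")
        quant = stage_quantify(run_paths, metadata, calibration, config, indir)
        quant.insert(0, "culture", scenario)
        quant_tables.append(quant)
        comparisons = stage_stats(quant, indir)
        comparisons.insert(0, "culture", scenario)
        comparison_tables.append(comparisons)

        means = quant.groupby("condition", sort=False)["per_cell_fmol"].mean()
        print(f"{scenario}: " + ", ".join(
            f"{c} = {v:.1f} fmol/cell" for c, v in means.items()))
        for _, row in comparisons.iterrows():
            print(f"  {row['reference']} -> {row['treatment']}: "
                  f"{row['fold_change']:.2f}x (Tukey p = {row['tukey_p']:.3g}, "
                  f"{row['label']})")

    pd.concat(quant_tables).to_csv(RESULTS / "salinity_quant.csv", index=False)
    pd.concat(comparison_tables).to_csv(
        RESULTS / "salinity_comparisons.csv", index=False)
    print(f"-> {RESULTS / 'salinity_quant.csv'}")
    print(f"-> {RESULTS / 'salinity_comparisons.csv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
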