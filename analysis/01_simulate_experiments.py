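#!/usr/bin/env python
"""Simulate the salinity experiments and a calibration batch.

Generates the xenic and axenic *T. weissflogii* salinity experiments
(3 conditions x 3 biological replicates each, 10% biological CV) plus an
external calibration dilution series for cysteinolic acid, and writes the
runs where the later stages pick them up.  Everything is seeded, so the
whole analysis chain is reproducible end to end.
"""

import sys
from pathlib import Path

import pandas as pd

from osmoquant.pipeline import PipelineConfig, stage_simulate
from osmoquant.recovery import child_seeds

BASE = Path(__file__).resolve().parent.parent
SCRATCH = BASE / "scratch" / "analysis"
SEED = 1


def main() -> None:
    seeds = child_seeds(SEED, 2)
    for scenario, seed in (("tw_xenic", seeds[0]), ("tw_axenic", seeds[1])):
        outdir = SCRATCH / scenario
        outdir.mkdir(parents=True, exist_ok=True)
        config = PipelineConfig(outdir=str(outdir), seed=seed,
                                scenario=scenario)
        run_paths, cal_path = stage_simulate(config, outdir)
        meta = pd.read_csv(outdir / "metadata.csv")
        print(f"{scenario}: {len(run_paths)} runs "
              f"({meta['condition'].nunique()} conditions x "
              f"{meta['replicate'].max()} replicates), "
              f"calibration series -> {cal_path.name}")
    print(f"runs under {SCRATCH}")


if __name__ == "__main__":
    sys.exit(main())
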