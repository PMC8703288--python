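#!/usr/bin/env python
"""Mine the simulated xenic experiment for salinity-up-regulated features.

Detects chromatographic features in every run, attaches M+1/M+2
isotopologue envelopes, and screens 35 PSU against the long-term 50 PSU
condition (fold change >= 1.5, Welch p <= 0.05).  The expected outcome
mirrors the discovery narrative: a single candidate, carrying the
+1.9958 Da sulfur isotope signature, at the m/z of protonated
cysteinolic acid (156.0325).
"""

import sys
from pathlib import Path

import pandas as pd

from osmoquant.pipeline import PipelineConfig, stage_screen

BASE = Path(__file__).resolve().parent.parent
SCRATCH = BASE / "scratch" / "analysis"
RESULTS = BASE / "results"


def main() -> int:
    indir = SCRATCH / "tw_xenic"
    if not indir.exists():
        print("run 01_simulate_experiments.py first", file=sys.stderr)
        return 1
    RESULTS.mkdir(exist_ok=True)
    config = PipelineConfig(outdir=str(indir))
    metadata = pd.read_csv(indir / "metadata.csv")
    run_paths = [indir / "runs" / name for name in metadata["path"]]
    candidates = stage_screen(run_paths, metadata, config, indir)
    candidates.to_csv(RESULTS / "candidates.csv", index=False)
    print(f"{len(candidates)} up-regulated candidate(s):")
    for _, row in candidates.iterrows():
        print(f"  m/z {row['mz']:.5f} @ {row['rt_min']:.2f} min  "
              f"fold change {row['fold_change']:.2f}  p = {row['p_value']:.3g}  "
              f"sulfur signature: {'yes' if row['sulfur_flag'] else 'no'}")
    print(f"-> {RESULTS / 'candidates.csv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
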