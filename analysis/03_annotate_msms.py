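#!/usr/bin/env python
"""Explain the candidate's MS/MS fragments by neutral-loss combinations.

Annotates the published MS/MS peaks of the m/z 156.0323 candidate against
the cysteinolic acid formula (C3H9NO4S, [M+H]+): the 138.02196 fragment
is the water loss, and 56.04979 is the combined loss of water and the
sulfonic group (H2O + H2SO3), leaving the C3H6N+ iminium ion — the
structural evidence that the candidate is a sulfonate.
"""

import sys
from pathlib import Path

import pandas as pd

from osmoquant.chem import M_PLUS_H
from osmoquant.msms import annotate_fragments
from osmoquant.pipeline import DEMO_MSMS_PEAKS
from osmoquant.scenarios import CYSTEINOLIC_ACID

BASE = Path(__file__).resolve().parent.parent
RESULTS = BASE / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    assignments = annotate_fragments(
        CYSTEINOLIC_ACID.formula, M_PLUS_H, list(DEMO_MSMS_PEAKS))
    table = pd.DataFrame([{
        "observed_mz": a.observed_mz,
        "assignment": a.label,
        "theoretical_mz": a.theoretical_mz,
        "error_ppm": a.error_ppm,
    } for a in assignments])
    table.to_csv(RESULTS / "msms_assignments.csv", index=False)
    for _, row in table.iterrows():
        print(f"  {row['observed_mz']:<10} -> {row['assignment']:<16} "
              f"theory {row['theoretical_mz']:.5f}  "
              f"error {row['error_ppm']:+.2f} ppm")
    print(f"-> {RESULTS / 'msms_assignments.csv'}")


if __name__ == "__main__":
    sys.exit(main())
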