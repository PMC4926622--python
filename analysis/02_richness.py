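#!/usr/bin/env python
"""Richness stage: screen every predictor with linear/quadratic/cubic fits,
prune each predictor set (A = log area, E = environment, S = spatial
position) by backward stepwise elimination, and partition the explained
variance into unique and shared fractions.

Reads results/synthetic/ (run 01_simulate.py first); writes
results/richness.{json,csv}.
"""

import argparse
from pathlib import Path

from betascape.core_io import read_occurrences, read_site_table
from betascape.pipeline import PipelineConfig, _richness_stage


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    occ = read_occurrences(args.data / "occurrences.csv")
    table = read_site_table(args.data / "site_table.csv").align_to(occ)
    config = PipelineConfig(seed=0)
    res = _richness_stage(occ, table, config, args.out)

    part = res["partition"]
    print("set-model variance (%, unadjusted R^2):")
    for key in ("A", "E", "S", "A+E+S"):
        print(f"  {key:>5}: {part.source_r2[key]:5.1f}")
    print("fractions (% of variance):")
    for key in ("E", "S", "E&S", "residual"):
        print(f"  {key:>8}: {part.fractions[key]:5.1f}")
    print(f"tables written to {args.out}/richness.csv and .json")


if __name__ == "__main__":
    main()
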