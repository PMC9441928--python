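#!/usr/bin/env python
"""Step 2 — run the full analysis pipeline on the generated study.

Sequences every stage: derived anatomical traits, genotype means, drought
response statistics (plasticity, GCV, ANOVA effect sizes, correlations),
performance grouping (1-SD well-watered biomass filter + 50% reduction
split), within-experiment PAM clustering with silhouette-based k selection,
cross-experiment rank integration into integrated phenotype groups, and
allometric scaling fits per group.

Usage: python analysis/02_run_analysis.py [--data DIR] [--out DIR] [--g N]
"""

import argparse
from pathlib import Path

from rootpheno.pipeline import PipelineConfig, run_pipeline

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results/analysis"))
parser.add_argument("--g", type=int, default=6, help="number of integrated groups")
args = parser.parse_args()

config = PipelineConfig(
    input_table=str(args.data / "plants.csv"),
    output_dir=str(args.out),
    G=args.g,
)
out = run_pipeline(config)
print(f"pipeline outputs in {out} (see manifest.json for stages and file hashes)")
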