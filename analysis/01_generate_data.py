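#!/usr/bin/env python
"""Step 1 — generate the synthetic multi-environment drought study.

Produces the plant-level phenotype table for four trials with contrasting
drought severities (two greenhouse, two rainout shelter), plus a truth file
recording each genotype's latent archetype.  The truth file is used only to
evaluate the analysis afterwards — no downstream stage reads it.

Usage: python analysis/01_generate_data.py [--seed N] [--out DIR]
"""

import argparse
from pathlib import Path

from rootpheno.simulate import default_config, generate_dataset
from rootpheno.traits import write_results

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results/data"))
args = parser.parse_args()

config = default_config(args.seed)
table, truth = generate_dataset(config)
args.out.mkdir(parents=True, exist_ok=True)
write_results(table, args.out / "plants.csv")
write_results(truth, args.out / "truth.csv")

n_geno = truth.groupby("experiment")["genotype"].nunique()
print(f"seed {args.seed}: {len(table)} plants across {len(config.experiments)} experiments")
for exp in config.experiments:
    red = 100 * (1 - exp.treatment_effect.get("biomass", 1.0))
    print(f"  {exp.name}: {n_geno[exp.name]} genotypes x {exp.n_reps} reps, "
          f"configured biomass reduction {red:.0f}%, depth proxy {exp.depth_proxy}")
print(f"wrote {args.out / 'plants.csv'} and {args.out / 'truth.csv'}")
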