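#!/usr/bin/env python
"""Step 3 — narrative summary of the analysis outputs.

Reads the pipeline CSVs and prints the study's headline results: drought
severity per experiment, selected cluster counts with silhouette support,
performance-group sizes, integrated phenotype groups and their drought
biomass ranks, and the allometric scaling classifications.  When the truth
file is available it also scores how well clustering recovered the latent
archetypes.

Usage: python analysis/03_summarize_findings.py [--analysis DIR] [--data DIR]
"""

import argparse
from pathlib import Path

import pandas as pd

from rootpheno.stats import percent_reduction

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--analysis", type=Path, default=Path("results/analysis"))
parser.add_argument("--data", type=Path, default=Path("results/data"))
args = parser.parse_args()

means = pd.read_csv(args.analysis / "genotype_means.csv")
diag = pd.read_csv(args.analysis / "cluster_diagnostics.csv")
perf = pd.read_csv(args.analysis / "performance_groups.csv")
geno_groups = pd.read_csv(args.analysis / "genotype_integrated_groups.csv")
allometry = pd.read_csv(args.analysis / "allometry.csv")

print("=== Drought severity (equal-weight genotype means) ===")
for exp in sorted(means["experiment"].unique()):
    bio = percent_reduction(means, "biomass", exp)
    line = f"  {exp}: shoot biomass -{bio:.1f}%"
    if not means[(means['experiment'] == exp) & (means['trait'] == 'nodal_root_number')].empty:
        nod = percent_reduction(means, "nodal_root_number", exp)
        line += f", nodal roots -{nod:.1f}%"
    print(line)

print("\n=== Performance groups (1-SD WW biomass filter, 50% reduction split) ===")
for exp, sub in perf.groupby("experiment"):
    counts = sub["group"].value_counts()
    print(f"  {exp}: best {counts.get('best', 0)}, worst {counts.get('worst', 0)}, "
          f"excluded {counts.get('excluded', 0)}")

print("\n=== Within-experiment clustering (PAM, average-silhouette k) ===")
for exp, sub in diag.groupby("experiment"):
    sel = sub[sub["selected"]].iloc[0]
    print(f"  {exp}: k = {int(sel['k'])} (avg silhouette {sel['avg_silhouette']:.3f})")

print("\n=== Integrated phenotype groups (group 1 = best drought biomass rank) ===")
for g, sub in geno_groups.groupby("group"):
    members = ", ".join(f"{e}:c{c}" for (e, c) in
                        sorted(set(zip(sub["experiment"], sub["cluster"]))))
    print(f"  group {g}: {len(sub)} genotypes from clusters {members}")

print("\n=== Allometric scaling (drought treatment, per integrated group) ===")
sig = allometry[(allometry["treatment"] == "D") & allometry["significant"]]
for _, row in sig.iterrows():
    print(f"  group {row['group']}: {row['y_trait']} ~ {row['x_trait']}^"
          f"{row['alpha']:.2f} ({row['classification']}, adj R2 {row['adj_r2']:.2f}, "
          f"n {int(row['n'])})")

truth_path = args.data / "truth.csv"
if truth_path.exists():
    truth = pd.read_csv(truth_path)
    merged = geno_groups.merge(truth, on=["experiment", "genotype"])
    tab = pd.crosstab(merged["group"], merged["archetype"])
    purity = (tab.max(axis=1) / tab.sum(axis=1))
    print("\n=== Archetype composition of integrated groups ===")
    print(tab.to_string())
    print(f"  mean group purity: {purity.mean():.2f}")
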