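"""Cross-experiment integration of cluster trait rankings.

Trait central values are ranked within each experiment (rank 1 = greatest),
normalized to [0, 1] so experiments with different cluster counts are
comparable, and clusters with similar rank profiles across experiments are
grouped into integrated phenotypes by average-linkage agglomeration — a
reproducible, auditable stand-in for grouping rank heatmaps by eye.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance

__all__ = [
    "RankMatrix",
    "IntegratedGrouping",
    "cluster_central_values",
    "rank_clusters",
    "rank_profile_distance",
    "group_integrated",
    "rank_heatmap",
]


@dataclass
class RankMatrix:
    """Cluster × trait ordinal ranks, experiment-qualified.

    ``ranks`` is indexed by (experiment, cluster); entries are integer ranks
    with 1 = greatest central value, ties sharing the minimum rank.
    ``k_by_experiment`` records how many clusters each experiment produced,
    which the [0, 1] normalization needs.
    """

    ranks: pd.DataFrame
    k_by_experiment: dict[str, int]
    central_stat: str = "mean"

    def normalized(self) -> pd.DataFrame:
        """Ranks mapped to (rank − 1)/(k − 1) ∈ [0, 1]; 0 for k = 1."""
        out = self.ranks.astype(float).copy()
        for exp, k in self.k_by_experiment.items():
            rows = out.index.get_level_values("experiment") == exp
            # multiply/shift forms both preserve missing (unranked) traits
            out.loc[rows] = out.loc[rows] * 0.0 if k <= 1 else (out.loc[rows] - 1.0) / (k - 1.0)
        return out

    def append(self, other: "RankMatrix") -> "RankMatrix":
        if other.central_stat != self.central_stat:
            raise ValueError("cannot combine rank matrices with different central statistics")
        return RankMatrix(
            ranks=pd.concat([self.ranks, other.ranks]),
            k_by_experiment={**self.k_by_experiment, **other.k_by_experiment},
            central_stat=self.central_stat,
        )


@dataclass
class IntegratedGrouping:
    """Assignment of experiment-qualified clusters to integrated phenotypes."""

    assignment: dict[tuple[str, int], int]
    G: int
    linkage: str = "average"
    profiles: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(experiment=e, cluster=c, group=g) for (e, c), g in sorted(self.assignment.items())]
        return pd.DataFrame(rows)


def cluster_central_values(
    means: pd.DataFrame,
    assignments: pd.DataFrame,
    traits: Sequence[str],
    experiment: str,
    treatment: str = "D",
    central_stat: str = "mean",
) -> pd.DataFrame:
    """Per-cluster central trait values (mean or median over member units)."""
    if central_stat not in ("mean", "median"):
        raise ValueError(f"central_stat must be 'mean' or 'median', got {central_stat!r}")
    sub = means[(means["experiment"] == experiment) & (means["treatment"] == treatment)
                & (means["trait"].isin(traits))]
    wide = sub.pivot_table(index="genotype", columns="trait", values="mean", aggfunc="first")
    merged = assignments.set_index("unit").join(wide, how="inner")
    agg = merged.groupby("cluster").agg(central_stat)
    return agg.reindex(columns=[t for t in traits if t in agg.columns])


def rank_clusters(
    central_values: pd.DataFrame,
    experiment: str,
    central_stat: str = "mean",
) -> RankMatrix:
    """Rank cluster central values within one experiment, per trait.

    Rank 1 is the greatest value; tied values share the minimum rank (two
    clusters tied at the top are both rank 1 and the next is rank 3).
    Traits a cluster lacks stay missing and are masked later.
    """
    ranks = central_values.rank(ascending=False, method="min")
    ranks.index = pd.MultiIndex.from_product([[experiment], central_values.index],
                                             names=["experiment", "cluster"])
    return RankMatrix(ranks=ranks, k_by_experiment={experiment: len(central_values)},
                      central_stat=central_stat)


def rank_profile_distance(row_a: pd.Series, row_b: pd.Series) -> float:
    """Distance between two normalized rank profiles over their shared traits.

    Euclidean over the traits both profiles carry, divided by √(#shared) so
    the distance lies in [0, 1] regardless of how many traits are shared.
    Requires at least two shared traits.
    """
    shared = row_a.dropna().index.intersection(row_b.dropna().index)
    if len(shared) < 2:
        raise ValueError(f"profiles share only {len(shared)} trait(s); need >= 2")
    diff = row_a[shared].to_numpy(dtype=float) - row_b[shared].to_numpy(dtype=float)
    return float(np.sqrt((diff**2).sum()) / np.sqrt(len(shared)))


def group_integrated(
    rank_matrix: RankMatrix,
    G: int = 6,
    biomass_trait: str = "biomass",
) -> IntegratedGrouping:
    """Group clusters across experiments into G integrated phenotypes.

    Average-linkage agglomeration on the normalized-rank profile distance,
    cut at G groups.  Groups are renumbered so group 1 has the best (lowest)
    mean normalized biomass rank — i.e. the greatest relative shoot biomass
    under drought — falling back to the all-trait mean rank when biomass was
    not ranked.  Deterministic and invariant to cluster input order (rows
    are sorted before linkage).
    """
    profiles = rank_matrix.normalized().sort_index()
    n = len(profiles)
    if G > n:
        raise ValueError(f"G={G} exceeds the number of clusters ({n})")
    if G < 1:
        raise ValueError("G must be >= 1")

    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = rank_profile_distance(profiles.iloc[i], profiles.iloc[j])
            except ValueError:
                warnings.warn(
                    f"profiles {profiles.index[i]} and {profiles.index[j]} share < 2 traits; "
                    "distance set to the maximum (1.0)", UserWarning, stacklevel=2)
                d = 1.0
            dist[i, j] = dist[j, i] = d
    condensed = scipy.spatial.distance.squareform(dist, checks=False)
    Z = scipy.cluster.hierarchy.linkage(condensed, method="average")
    raw = scipy.cluster.hierarchy.fcluster(Z, t=G, criterion="maxclust")

    # renumber: group 1 = best performers (lowest normalized biomass rank)
    key_col = profiles[biomass_trait] if biomass_trait in profiles.columns else profiles.mean(axis=1)
    order = sorted(set(raw), key=lambda g: float(key_col[raw == g].mean()))
    remap = {g: i + 1 for i, g in enumerate(order)}
    assignment = {idx: remap[g] for idx, g in zip(profiles.index, raw)}
    return IntegratedGrouping(assignment=assignment, G=len(order), profiles=profiles)


def rank_heatmap(
    rank_matrix: RankMatrix,
    grouping: IntegratedGrouping,
    csv_path: str | Path | None = None,
    plot_path: str | Path | None = None,
) -> pd.DataFrame:
    """Trait × cluster rank table ordered by integrated group, plus a heatmap.

    Columns are experiment-qualified clusters ordered by group id; rows are
    traits; cells hold the within-experiment rank.  Trait rows with no ranks
    at all are dropped with a warning.  When ``plot_path`` is given, a
    yellow (rank 1) → blue (rank k) heatmap is written.
    """
    order = sorted(grouping.assignment, key=lambda idx: (grouping.assignment[idx], idx))
    table = rank_matrix.ranks.loc[order].T
    table.columns = [f"{e}:c{c} (g{grouping.assignment[(e, c)]})" for e, c in order]
    empty = table.index[table.isna().all(axis=1)]
    if len(empty):
        warnings.warn(f"trait row(s) with no ranks dropped: {list(empty)}", UserWarning, stacklevel=2)
        table = table.drop(index=empty)
    if csv_path is not None:
        table.to_csv(csv_path, float_format="%.12g")
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(max(6, 0.6 * table.shape[1]), max(4, 0.4 * table.shape[0])))
        im = ax.imshow(table.to_numpy(dtype=float), cmap="viridis_r", aspect="auto")
        ax.set_xticks(range(table.shape[1]), table.columns, rotation=90)
        ax.set_yticks(range(table.shape[0]), table.index)
        fig.colorbar(im, ax=ax, label="rank (1 = greatest)")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return table
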