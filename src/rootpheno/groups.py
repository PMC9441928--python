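"""Bulked-segregant style grouping of genotypes by drought performance.

Genotypes within an experiment are first filtered on well-watered shoot
biomass so the comparison groups start from similar plant size, then split
into best and worst drought performers at 50% biomass reduction.  Group
contrasts for any trait use Welch two-sample t tests within treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .stats import significance_stars

__all__ = ["PerformanceGrouping", "filter_by_ww_biomass", "split_best_worst", "compare_groups"]


@dataclass
class PerformanceGrouping:
    """Best/worst performance split of genotypes within one experiment."""

    experiment: str
    retained: frozenset[str]
    excluded: frozenset[str]
    best: frozenset[str] = field(default_factory=frozenset)
    worst: frozenset[str] = field(default_factory=frozenset)
    sd_multiplier: float = 1.0
    split_threshold: float = 50.0
    reductions: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.retained | self.excluded):
            group = ("best" if g in self.best else "worst" if g in self.worst
                     else "retained" if g in self.retained else "excluded")
            rows.append(dict(experiment=self.experiment, genotype=g, group=group,
                             biomass_reduction_pct=self.reductions.get(g, np.nan)))
        return pd.DataFrame(rows)


def filter_by_ww_biomass(
    means: pd.DataFrame,
    experiment: str,
    trait: str = "biomass",
    sd_multiplier: float = 1.0,
    two_sided: bool = True,
) -> PerformanceGrouping:
    """Filter out genotypes whose well-watered biomass is atypical.

    Genotypes whose WW genotype-mean biomass deviates from the grand mean of
    genotype means by more than ``sd_multiplier`` × SD (n−1, computed over
    genotype means) are excluded.  Two-sided by default, so both unusually
    large and unusually small plants are removed and the retained set is
    size-matched; ``two_sided=False`` removes only the large ones.

    Guarantees max |deviation| among retained ≤ sd_multiplier × SD (two-
    sided mode).  Requires ≥ 3 genotypes with WW biomass; errors if the
    filter would exclude everything.
    """
    sub = means[(means["experiment"] == experiment) & (means["trait"] == trait)
                & (means["treatment"] == "WW")]
    ww = sub.set_index("genotype")["mean"]
    if len(ww) < 3:
        raise ValueError(f"need at least 3 genotypes with WW {trait} in {experiment}, got {len(ww)}")
    center = ww.mean()
    sd = ww.std(ddof=1)
    dev = ww - center
    if two_sided:
        keep = dev.abs() <= sd_multiplier * sd
    else:
        keep = dev <= sd_multiplier * sd
    retained = frozenset(ww.index[keep])
    excluded = frozenset(ww.index[~keep])
    if not retained:
        raise ValueError(f"WW biomass filter excluded every genotype in {experiment}")
    return PerformanceGrouping(experiment=experiment, retained=retained, excluded=excluded,
                               sd_multiplier=sd_multiplier)


def split_best_worst(
    means: pd.DataFrame,
    grouping: PerformanceGrouping,
    trait: str = "biomass",
    threshold: float = 50.0,
    ties_to_best: bool = True,
) -> PerformanceGrouping:
    """Split retained genotypes at the biomass-reduction threshold.

    Per-genotype drought reduction is 100·(x̄_WW − x̄_D)/x̄_WW; genotypes
    below the threshold (default 50%) are "best", above it "worst".  A
    reduction of exactly the threshold goes to best by default (configurable);
    negative reductions (growth under drought) are always best.  Genotypes
    missing either treatment mean are left out of both groups with a warning.
    """
    sub = means[(means["experiment"] == grouping.experiment) & (means["trait"] == trait)]
    wide = sub.pivot_table(index="genotype", columns="treatment", values="mean", aggfunc="first")
    best, worst, reductions = set(), set(), {}
    skipped = []
    for g in sorted(grouping.retained):
        if g not in wide.index or pd.isna(wide.loc[g].get("WW")) or pd.isna(wide.loc[g].get("D")):
            skipped.append(g)
            continue
        ww, d = wide.loc[g, "WW"], wide.loc[g, "D"]
        red = 100.0 * (ww - d) / ww
        reductions[g] = float(red)
        if red < threshold or (ties_to_best and red == threshold):
            best.add(g)
        else:
            worst.add(g)
    if skipped:
        warnings.warn(f"{len(skipped)} retained genotype(s) missing a treatment mean: {skipped}",
                      UserWarning, stacklevel=2)
    if not worst:
        warnings.warn(f"no genotype exceeded {threshold}% reduction in {grouping.experiment}; "
                      "worst group empty", UserWarning, stacklevel=2)
    if not best:
        warnings.warn(f"every genotype exceeded {threshold}% reduction in {grouping.experiment}; "
                      "best group empty", UserWarning, stacklevel=2)
    return PerformanceGrouping(
        experiment=grouping.experiment, retained=grouping.retained, excluded=grouping.excluded,
        best=frozenset(best), worst=frozenset(worst),
        sd_multiplier=grouping.sd_multiplier, split_threshold=threshold, reductions=reductions,
    )


def compare_groups(
    means: pd.DataFrame,
    grouping: PerformanceGrouping,
    trait: str,
) -> pd.DataFrame:
    """Welch t-tests between best and worst groups, within each treatment.

    Returns one row per treatment with t, two-sided p, group means, group
    sizes and the conventional significance stars (+, *, **, *** at
    0.1/0.05/0.01/0.001).  Identical groups give t = 0 and p = 1.
    """
    sub = means[(means["experiment"] == grouping.experiment) & (means["trait"] == trait)]
    rows = []
    for trt, grp in sub.groupby("treatment"):
        by_geno = grp.set_index("genotype")["mean"]
        a = by_geno[by_geno.index.isin(grouping.best)].to_numpy(dtype=float)
        b = by_geno[by_geno.index.isin(grouping.worst)].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(
                f"both groups need n >= 2 for {trait} under {trt} "
                f"(best n={len(a)}, worst n={len(b)})"
            )
        if np.allclose(a, a.mean()) and np.allclose(b, b.mean()) and np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = scipy.stats.ttest_ind(a, b, equal_var=False)
        rows.append(dict(experiment=grouping.experiment, trait=trait, treatment=trt,
                         mean_best=a.mean(), mean_worst=b.mean(), n_best=len(a), n_worst=len(b),
                         t=float(t), p=float(p), stars=significance_stars(float(p))))
    return pd.DataFrame(rows)
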