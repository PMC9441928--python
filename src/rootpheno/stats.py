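"""Treatment-response statistics over genotype means and plant tables.

Covers drought plasticity, percent treatment responses, genetic coefficients
of variation (GCV), fixed-effects ANOVA with η² effect sizes, and trait
correlation matrices flagged at a configurable significance level.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "plasticity",
    "percent_reduction",
    "gcv",
    "anova_effect_sizes",
    "correlation_matrix",
    "correlation_wide",
    "significance_stars",
]

#: p-value cut-points and their conventional annotations
_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "+"))


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    for cut, stars in _STAR_LEVELS:
        if p < cut:
            return stars
    return "ns"


def _pivot_treatments(means: pd.DataFrame, trait: str) -> pd.DataFrame:
    sub = means[means["trait"] == trait]
    wide = sub.pivot_table(
        index=["experiment", "genotype"], columns="treatment", values="mean", aggfunc="first"
    )
    return wide


def plasticity(means: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Drought plasticity per genotype: 100·(x̄_D − x̄_W)/x̄_W.

    Signed percent change of the genotype mean under drought relative to
    well-watered.  Genotypes observed under only one treatment are skipped;
    a zero well-watered mean makes the index undefined (NaN, warned).
    Scale-invariant: rescaling the trait by any positive constant leaves the
    value unchanged.
    """
    wide = _pivot_treatments(means, trait)
    if "WW" not in wide.columns or "D" not in wide.columns:
        return pd.DataFrame(columns=["experiment", "genotype", "trait", "plasticity"])
    wide = wide.dropna(subset=["WW", "D"])
    zero_ww = wide["WW"] == 0
    if zero_ww.any():
        warnings.warn(
            f"plasticity undefined for {int(zero_ww.sum())} genotype(s) with zero "
            f"well-watered mean of {trait}",
            UserWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(zero_ww, np.nan, 100.0 * (wide["D"] - wide["WW"]) / wide["WW"])
    out = wide.reset_index()[["experiment", "genotype"]]
    out["trait"] = trait
    out["plasticity"] = values
    return out


def percent_reduction(means: pd.DataFrame, trait: str, experiment: str) -> float:
    """Percent reduction of a trait by drought within one experiment.

    100·(mean_WW − mean_D)/mean_WW, where each treatment mean averages
    genotype means with equal weights.  Negative values indicate an increase
    under drought and are reported signed.
    """
    sub = means[(means["trait"] == trait) & (means["experiment"] == experiment)]
    by_trt = sub.groupby("treatment")["mean"].mean()
    if "WW" not in by_trt.index or "D" not in by_trt.index:
        raise ValueError(f"both treatments required for {trait} in {experiment}")
    if by_trt["WW"] == 0:
        warnings.warn(f"zero well-watered mean for {trait} in {experiment}", UserWarning, stacklevel=2)
        return float("nan")
    return float(100.0 * (by_trt["WW"] - by_trt["D"]) / by_trt["WW"])


def gcv(
    data: pd.DataFrame,
    trait: str,
    scope: str = "among_genotypes",
    mu_scope: str = "grand",
) -> pd.DataFrame:
    """Genetic coefficient of variation, 100·σ/μ, within or among genotypes.

    ``scope='among_genotypes'``: σ is the n−1 SD of genotype means within
    each experiment × treatment.  ``scope='within_genotype'``: σ is the SD
    of replicate values within each genotype (one row per genotype);
    requires a plant-level table.  μ defaults to the grand mean of the trait
    within the experiment × treatment (``mu_scope='grand'``); with
    ``mu_scope='local'`` the within-genotype mean is used instead.

    Scopes with fewer than two observations yield a missing (NaN) GCV.
    """
    if scope not in ("among_genotypes", "within_genotype"):
        raise ValueError(f"unknown scope {scope!r}")
    is_means = {"trait", "mean"}.issubset(data.columns)

    rows = []
    if scope == "among_genotypes":
        if is_means:
            sub = data[data["trait"] == trait]
            values = sub.rename(columns={"mean": "value"})
        else:
            from .traits import genotype_means

            values = genotype_means(data, traits=[trait]).rename(columns={"mean": "value"})
        for (exp, trt), grp in values.groupby(["experiment", "treatment"]):
            mu = grp["value"].mean()
            sigma = grp["value"].std(ddof=1) if len(grp) >= 2 else np.nan
            rows.append(
                dict(scope=scope, experiment=exp, treatment=trt, genotype="", trait=trait,
                     sigma=sigma, mu=mu, n=len(grp),
                     gcv=100.0 * sigma / mu if mu != 0 else np.nan)
            )
    else:
        if is_means:
            raise ValueError("within-genotype GCV requires a plant-level table")
        long = data[["experiment", "genotype", "treatment", trait]].dropna(subset=[trait])
        grand = long.groupby(["experiment", "treatment"])[trait].mean()
        for (exp, geno, trt), grp in long.groupby(["experiment", "genotype", "treatment"]):
            sigma = grp[trait].std(ddof=1) if len(grp) >= 2 else np.nan
            mu = grand.loc[(exp, trt)] if mu_scope == "grand" else grp[trait].mean()
            rows.append(
                dict(scope=scope, experiment=exp, treatment=trt, genotype=geno, trait=trait,
                     sigma=sigma, mu=mu, n=len(grp),
                     gcv=100.0 * sigma / mu if mu != 0 else np.nan)
            )
    return pd.DataFrame(rows)


def _is_balanced(table: pd.DataFrame, factors: Sequence[str], response: str) -> bool:
    counts = table.dropna(subset=[response]).groupby(list(factors), observed=True).size()
    full = 1
    for f in factors:
        full *= table[f].nunique()
    return len(counts) == full and counts.nunique() == 1


def anova_effect_sizes(
    table: pd.DataFrame,
    trait: str,
    factors: Sequence[str] = ("treatment", "genotype"),
) -> pd.DataFrame:
    """Fixed-effects crossed ANOVA with η² (%) per term.

    Fits the fully crossed model over the given factors by OLS and reports
    df, sum of squares, F, p and η² = 100·SS_term/SS_total for every term
    plus the residual.  Sequential (type I) sums of squares are used on
    balanced data, type II otherwise.  Interaction terms whose design cells
    are empty are dropped with a warning.  A constant response yields zero
    η² everywhere and undefined F.
    """
    data = table.dropna(subset=[trait]).copy()
    data = data.rename(columns={trait: "_y"})
    if data.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least two levels")

    # drop the interaction when the crossed design has empty cells
    full_cells = 1
    for f in factors:
        full_cells *= data[f].nunique()
    has_all_cells = len(data.groupby(list(factors), observed=True).size()) == full_cells
    if has_all_cells:
        formula = "_y ~ " + " * ".join(f"C({f})" for f in factors)
    else:
        warnings.warn(
            "design has empty cells; interaction term(s) dropped", UserWarning, stacklevel=2
        )
        formula = "_y ~ " + " + ".join(f"C({f})" for f in factors)

    ss_total = float(((data["_y"] - data["_y"].mean()) ** 2).sum())
    fit = smf.ols(formula, data=data).fit()
    if ss_total == 0:
        terms = _term_names(factors, interactions=has_all_cells)
        out = pd.DataFrame(
            dict(term=terms + ["Residual"], df=np.nan, sum_sq=0.0, F=np.nan, p=np.nan, eta_sq=0.0)
        )
        out["trait"] = trait
        return out

    typ = 1 if _is_balanced(data, factors, "_y") else 2
    anova = sm.stats.anova_lm(fit, typ=typ)

    out = anova.rename(
        columns={"PR(>F)": "p", "df": "df", "sum_sq": "sum_sq", "F": "F"}
    ).reset_index(names="term")
    out["term"] = out["term"].str.replace(r"C\((\w+)\)", r"\1", regex=True)
    out["eta_sq"] = 100.0 * out["sum_sq"] / ss_total
    out["stars"] = out["p"].map(lambda p: significance_stars(p) if not np.isnan(p) else "")
    out["trait"] = trait
    return out[["trait", "term", "df", "sum_sq", "F", "p", "eta_sq", "stars"]]


def _term_names(factors: Sequence[str], interactions: bool) -> list[str]:
    names = list(factors)
    if interactions and len(factors) >= 2:
        from itertools import combinations

        for r in range(2, len(factors) + 1):
            names += [":".join(c) for c in combinations(factors, r)]
    return names


def correlation_matrix(
    means: pd.DataFrame,
    traits: Iterable[str],
    treatment: str = "D",
    experiment: str | None = None,
    alpha: float = 0.1,
    min_n: int = 3,
) -> pd.DataFrame:
    """Pairwise Pearson correlations among trait genotype-means.

    Uses pairwise-complete observations (genotypes within the experiment and
    treatment); pairs with fewer than ``min_n`` complete observations are
    reported with missing r.  Two-sided p-values come from the exact t test
    of the correlation; ``significant`` flags p ≤ alpha (raw, unadjusted).
    Long format, one row per unordered pair including the diagonal.
    """
    traits = list(traits)
    sub = means[means["treatment"] == treatment]
    if experiment is not None:
        sub = sub[sub["experiment"] == experiment]
    wide = sub[sub["trait"].isin(traits)].pivot_table(
        index=["experiment", "genotype"], columns="trait", values="mean", aggfunc="first"
    )
    rows = []
    for i, ta in enumerate(traits):
        for tb in traits[i:]:
            if ta == tb:
                rows.append(dict(trait_a=ta, trait_b=tb, r=1.0, p=0.0, n=int(wide[ta].notna().sum())
                                 if ta in wide else 0, significant=True))
                continue
            if ta not in wide.columns or tb not in wide.columns:
                rows.append(dict(trait_a=ta, trait_b=tb, r=np.nan, p=np.nan, n=0, significant=False))
                continue
            pair = wide[[ta, tb]].dropna()
            n = len(pair)
            if n < min_n:
                rows.append(dict(trait_a=ta, trait_b=tb, r=np.nan, p=np.nan, n=n, significant=False))
                continue
            r, p = scipy.stats.pearsonr(pair[ta], pair[tb])
            rows.append(dict(trait_a=ta, trait_b=tb, r=float(r), p=float(p), n=n,
                             significant=bool(p <= alpha)))
    return pd.DataFrame(rows)


def correlation_wide(corr_long: pd.DataFrame) -> pd.DataFrame:
    """Symmetric wide-format r matrix from the long correlation table."""
    traits = sorted(set(corr_long["trait_a"]) | set(corr_long["trait_b"]))
    mat = pd.DataFrame(np.nan, index=traits, columns=traits)
    for row in corr_long.itertuples():
        mat.loc[row.trait_a, row.trait_b] = row.r
        mat.loc[row.trait_b, row.trait_a] = row.r
    return mat
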