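"""Allometric log–log scaling of trait pairs with isometry classification.

The scaling exponent alpha is the OLS slope of log(y) on log(x); it is
invariant to the logarithm base and to multiplicative rescaling of either
trait.  Exponents are classified against dimensional expectations: a linear
or count trait growing isometrically with mass scales as mass^(1/3), an area
as mass^(2/3), with a ±0.15 band around each.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .traits import GeometryClass

__all__ = [
    "AllometryFit",
    "ISOMETRIC_EXPONENTS",
    "ISOMETRY_BAND",
    "fit_allometry",
    "classify_alpha",
    "allometry_table",
]

#: isometric expectation a0 per dimensional class of the y trait.  Percent
#: traits follow the linear expectation (percent aerenchyma is classified
#: against 0.33); pure ratios carry no expectation.
ISOMETRIC_EXPONENTS: dict[GeometryClass, float | None] = {
    GeometryClass.LINEAR: 0.33,
    GeometryClass.COUNT: 0.33,
    GeometryClass.PERCENT: 0.33,
    GeometryClass.AREA: 0.67,
    GeometryClass.RATIO: None,
}

ISOMETRY_BAND = 0.15


@dataclass
class AllometryFit:
    """OLS fit of log(y) on log(x) for one trait pair / group / treatment."""

    y_trait: str
    x_trait: str
    group: str
    treatment: str
    alpha: float
    intercept: float
    adj_r2: float
    p: float
    n: int
    classification: str = ""

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def fit_allometry(
    x,
    y,
    log_base: float = 10.0,
    y_trait: str = "",
    x_trait: str = "",
    group: str = "",
    treatment: str = "",
    sma: bool = False,
) -> AllometryFit | None:
    """Fit the scaling exponent between two positive-valued traits.

    Ordinary least squares of log(y) on log(x); alpha is the slope,
    adj R² = 1 − (1 − R²)(n − 1)/(n − 2), and p is the two-sided t test of
    slope ≠ 0.  Nonpositive observations are dropped with a warning; fewer
    than 3 remaining points yield no fit (None).  ``sma=True`` returns the
    standardized-major-axis slope sign(r)·SD(logy)/SD(logx) instead, for
    sensitivity analysis only.

    A constant y gives alpha = 0 with p = 1; the slope is identical for any
    logarithm base (only the intercept changes, reported in the requested
    base).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} nonpositive/missing observation(s) dropped before log fit",
                      UserWarning, stacklevel=2)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        warnings.warn(f"only {n} usable observations; no allometric fit", UserWarning, stacklevel=2)
        return None
    lx = np.log(x) / math.log(log_base)
    ly = np.log(y) / math.log(log_base)

    if np.allclose(ly, ly[0]):
        return AllometryFit(y_trait, x_trait, group, treatment,
                            alpha=0.0, intercept=float(ly[0]), adj_r2=0.0, p=1.0, n=n)
    res = scipy.stats.linregress(lx, ly)
    r2 = res.rvalue**2
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    alpha = float(res.slope)
    if sma:
        alpha = float(np.sign(res.rvalue) * np.std(ly, ddof=1) / np.std(lx, ddof=1))
    return AllometryFit(y_trait, x_trait, group, treatment,
                        alpha=alpha, intercept=float(res.intercept),
                        adj_r2=float(adj_r2), p=float(res.pvalue), n=n)


def classify_alpha(
    fit: AllometryFit,
    y_geometry: GeometryClass | str,
    band: float = ISOMETRY_BAND,
    p_threshold: float = 0.05,
    a0: float | None = None,
) -> str:
    """Classify a fitted exponent against its isometric expectation.

    Non-significant slopes (p > ``p_threshold``) are "ns".  Otherwise the
    fit is isometric when |alpha − a0| ≤ band, hyperallometric above the
    band, hypoallometric below it, with a0 = 0.33 for linear/count/percent
    traits and 0.67 for areas (overridable via ``a0``).  Every significant
    fit maps to exactly one of the three classes.
    """
    geometry = GeometryClass(y_geometry)
    if a0 is None:
        a0 = ISOMETRIC_EXPONENTS[geometry]
    if a0 is None:
        raise ValueError(f"no isometric expectation for geometry class {geometry.value!r}; pass a0")
    if not np.isfinite(fit.alpha):
        raise ValueError("alpha must be finite")
    # band edges are inclusive; the epsilon keeps e.g. |0.18 - 0.33| <= 0.15
    # true despite binary floating point
    eps = 1e-9
    if fit.p > p_threshold:
        cls = "ns"
    elif fit.alpha > a0 + band + eps:
        cls = "hyperallometric"
    elif fit.alpha < a0 - band - eps:
        cls = "hypoallometric"
    else:
        cls = "isometric"
    fit.classification = cls
    return cls


#: the standard trait pairs examined: root traits against shoot dry biomass,
#: plus metaxylem vessel area against root cross-sectional area
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("nodal_root_number", "biomass"),
    ("RXSA", "biomass"),
    ("MXA", "biomass"),
    ("MXA", "RXSA"),
    ("percAA", "biomass"),
)


def allometry_table(
    means: pd.DataFrame,
    grouping,
    dictionary,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    treatments: Iterable[str] = ("WW", "D"),
    log_base: float = 10.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Allometric fits per (trait pair, integrated group, treatment).

    Pools genotype means across the experiments contributing to each
    integrated group, fits log(y) ~ log(x), classifies the exponent by the
    y trait's dimensional class, and returns one row per fit with adj R²,
    alpha, p, n, classification and a significance flag.  Groups with fewer
    than three usable observations for a pair are skipped with a warning.

    ``grouping`` may be an :class:`~rootpheno.integrate.IntegratedGrouping`
    together with cluster assignments joined beforehand; here it is a
    DataFrame mapping (experiment, genotype) → group.
    """
    if not {"experiment", "genotype", "group"}.issubset(grouping.columns):
        raise ValueError("grouping must have experiment, genotype and group columns")
    rows = []
    for (y_trait, x_trait) in pairs:
        for g, members in grouping.groupby("group"):
            keys = members[["experiment", "genotype"]]
            for trt in treatments:
                sub = means[(means["treatment"] == trt) & means["trait"].isin([x_trait, y_trait])]
                wide = sub.merge(keys, on=["experiment", "genotype"]).pivot_table(
                    index=["experiment", "genotype"], columns="trait", values="mean", aggfunc="first"
                )
                if x_trait not in wide.columns or y_trait not in wide.columns:
                    continue
                pairdata = wide[[x_trait, y_trait]].dropna()
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    fit = fit_allometry(pairdata[x_trait], pairdata[y_trait], log_base=log_base,
                                        y_trait=y_trait, x_trait=x_trait, group=str(g), treatment=trt)
                if fit is None:
                    warnings.warn(f"no fit for {y_trait}~{x_trait}, group {g}, {trt} (n too small)",
                                  UserWarning, stacklevel=2)
                    continue
                classify_alpha(fit, dictionary[y_trait].geometry_class, p_threshold=p_threshold)
                row = fit.to_dict()
                row["significant"] = fit.p <= p_threshold
                rows.append(row)
    return pd.DataFrame(rows)
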