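"""Derived root anatomical and architectural traits.

All functions are vectorised over numpy arrays / pandas Series and return
NaN where a quantity is undefined (zero denominators, geometry violations),
emitting a warning rather than raising, so a single bad plant never aborts a
batch run.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConductanceParams",
    "living_tissue_area",
    "percent_aerenchyma",
    "axial_conductance",
    "nodal_root_angle",
    "deep_root_count",
    "deep_root_proportion",
    "metaxylem_ratios",
    "augment_table",
]

#: dynamic viscosity of water at 25 °C, Pa·s
WATER_VISCOSITY_25C = 8.9e-4


@dataclass(frozen=True)
class ConductanceParams:
    """Hagen–Poiseuille parameters for axial conductance per root.

    ``viscosity`` is the dynamic viscosity of xylem sap in Pa·s (default:
    water at 25 °C).  Vessel areas are in mm², so the conductance comes out
    in mm⁴·Pa⁻¹·s⁻¹: volumetric flow (mm³/s) per unit pressure gradient
    (Pa/mm) along the root axis.
    """

    viscosity: float = WATER_VISCOSITY_25C

    def __post_init__(self) -> None:
        if not self.viscosity > 0:
            raise ValueError("viscosity must be positive")


def living_tissue_area(rxsa, aa, mxa, total_metaxylem: bool = False, mxv=None):
    """Living tissue area: cross-sectional area minus air space and vessel lumen.

    LTA = RXSA − AA − MXA, subtracting the single (mean) vessel area.  With
    ``total_metaxylem=True`` the total vessel lumen MXA·MXV is subtracted
    instead (requires ``mxv``).  A negative result is geometrically
    impossible and is retained but flagged with a warning so the offending
    plants can be audited.
    """
    rxsa = np.asarray(rxsa, dtype=float)
    aa = np.asarray(aa, dtype=float)
    mxa = np.asarray(mxa, dtype=float)
    vessel_lumen = mxa * np.asarray(mxv, dtype=float) if total_metaxylem else mxa
    if total_metaxylem and mxv is None:
        raise ValueError("total_metaxylem=True requires vessel counts (mxv)")
    lta = rxsa - aa - vessel_lumen
    n_neg = int(np.sum(np.asarray(lta) < 0))
    if n_neg:
        warnings.warn(
            f"living tissue area negative for {n_neg} observation(s); "
            "check RXSA/AA/MXA consistency",
            UserWarning,
            stacklevel=2,
        )
    return lta if lta.ndim else float(lta)


def percent_aerenchyma(aa, tca):
    """Percent aerenchyma area: AA/TCA × 100; undefined (NaN) when TCA = 0."""
    aa = np.asarray(aa, dtype=float)
    tca = np.asarray(tca, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(tca > 0, aa / tca * 100.0, np.nan)
    return out if out.ndim else float(out)


def axial_conductance(mxa, mxv, params: ConductanceParams = ConductanceParams()):
    """Theoretical axial hydraulic conductance per root, Hagen–Poiseuille.

    Each of the MXV vessels is treated as a cylindrical pipe of
    cross-sectional area MXA (only a central per-vessel area is measured),
    so radius r = √(MXA/π) and

        K = MXV · π r⁴ / (8η) = MXV · MXA² / (8πη)

    in mm⁴·Pa⁻¹·s⁻¹.  The r⁴ law makes K homogeneous of degree 2 in MXA and
    degree 1 in MXV; zero vessels or zero area give K = 0.
    """
    mxa = np.asarray(mxa, dtype=float)
    mxv = np.asarray(mxv, dtype=float)
    k = mxv * mxa**2 / (8.0 * math.pi * params.viscosity)
    return k if k.ndim else float(k)


def nodal_root_angle(root_length, ring_height: float = 7.5):
    """Root emergence angle from the soil surface, degrees.

    The excavation ring's height (default 7.5 cm) is the side opposite the
    angle and the measured root length the hypotenuse, so
    angle = arcsin(ring_height / length).  Lengths shorter than the ring
    height are geometrically impossible and return NaN with a warning.
    Steeper roots (closer to vertical) have larger angles; a root exactly as
    long as the ring is vertical (90°).
    """
    length = np.asarray(root_length, dtype=float)
    bad = length < ring_height
    if np.any(bad):
        warnings.warn(
            f"{int(np.sum(bad))} root length(s) shorter than the ring height "
            f"({ring_height} cm); angle undefined",
            UserWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        ratio = np.where(bad, np.nan, ring_height / length)
        angle = np.degrees(np.arcsin(ratio))
    return angle if angle.ndim else float(angle)


def deep_root_count(angles, threshold: float = 30.0) -> int:
    """Number of roots steeper than ``threshold`` degrees (strict inequality)."""
    angles = np.asarray(list(angles), dtype=float)
    if angles.size == 0:
        return 0
    return int(np.sum(angles > threshold))


def deep_root_proportion(length_by_depth: dict[tuple[float, float], float]) -> float:
    """Proportion of total root length found 20–40 cm below the soil surface.

    ``length_by_depth`` maps 10-cm depth bins ``(lo, hi)`` of a 0–40 cm soil
    core to root length in that bin; bins are half-open [lo, hi) except the
    deepest, which is closed.  Undefined (NaN) when the core holds no root
    length at all.
    """
    total = 0.0
    deep = 0.0
    for (lo, hi), length in length_by_depth.items():
        if length < 0:
            raise ValueError(f"negative root length in bin ({lo}, {hi})")
        total += length
        if lo >= 20.0:
            deep += length
    if total == 0:
        warnings.warn("soil core contains no root length; deep-root proportion undefined",
                      UserWarning, stacklevel=2)
        return float("nan")
    return deep / total


def metaxylem_ratios(mxa, mxv, rxsa, tsa) -> dict[str, np.ndarray | float]:
    """Metaxylem size and number normalised by root and stele area.

    Returns the four standard ratios MXA.RXSA, MXA.TSA, MXV.RXSA, MXV.TSA;
    each is NaN where its denominator is zero.
    """
    mxa = np.asarray(mxa, dtype=float)
    mxv = np.asarray(mxv, dtype=float)
    rxsa = np.asarray(rxsa, dtype=float)
    tsa = np.asarray(tsa, dtype=float)

    def _div(num, den):
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(den > 0, num / den, np.nan)
        return out if out.ndim else float(out)

    return {
        "MXA.RXSA": _div(mxa, rxsa),
        "MXA.TSA": _div(mxa, tsa),
        "MXV.RXSA": _div(mxv, rxsa),
        "MXV.TSA": _div(mxv, tsa),
    }


def augment_table(
    table: pd.DataFrame,
    params: ConductanceParams = ConductanceParams(),
    lta_total_metaxylem: bool = False,
) -> pd.DataFrame:
    """Append derivable trait columns to a plant-level table.

    Original columns are untouched; each derived column is added only when
    its inputs are present and is never overwritten if already supplied.
    """
    out = table.copy()
    cols = out.columns

    def _maybe(name, value):
        if name not in cols:
            out[name] = value

    if {"RXSA", "AA", "MXA"}.issubset(cols):
        mxv = out["MXV"] if lta_total_metaxylem and "MXV" in cols else None
        _maybe("LTA", living_tissue_area(out["RXSA"], out["AA"], out["MXA"],
                                         total_metaxylem=lta_total_metaxylem, mxv=mxv))
    if {"AA", "TCA"}.issubset(cols):
        _maybe("percAA", percent_aerenchyma(out["AA"], out["TCA"]))
    if {"MXA", "MXV"}.issubset(cols):
        _maybe("axial_conductance", axial_conductance(out["MXA"], out["MXV"], params))
    if {"MXA", "MXV", "RXSA", "TSA"}.issubset(cols):
        for name, values in metaxylem_ratios(out["MXA"], out["MXV"], out["RXSA"], out["TSA"]).items():
            _maybe(name, values)
    return out
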