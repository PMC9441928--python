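"""Tidy phenotype tables, the trait dictionary, and genotype-level summaries.

The unit of raw data is one plant: a row keyed by (experiment, genotype,
treatment, replicate) carrying named trait values in the units of the trait
dictionary.  Every downstream stage — plasticity, GCV, performance grouping,
clustering, allometry — operates on genotype means computed here.

Tables are plain :class:`pandas.DataFrame` objects validated against a
:class:`TraitDictionary`; there is no bespoke container class.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GeometryClass",
    "TraitCategory",
    "TraitDefinition",
    "TraitDictionary",
    "DEFAULT_TRAITS",
    "KEY_COLUMNS",
    "TREATMENTS",
    "ValidationError",
    "read_table",
    "validate_table",
    "genotype_means",
    "write_results",
    "read_results",
]

KEY_COLUMNS = ["experiment", "genotype", "treatment", "replicate"]
TREATMENTS = ("WW", "D")

#: accepted spellings on read; emitted canonically as WW / D
_TREATMENT_SYNONYMS = {
    "ww": "WW",
    "w": "WW",
    "well-watered": "WW",
    "well watered": "WW",
    "well_watered": "WW",
    "control": "WW",
    "d": "D",
    "drought": "D",
    "drought-stress": "D",
    "stress": "D",
}


class GeometryClass(str, enum.Enum):
    """Dimensional class of a trait, which sets its isometric expectation.

    Linear and count traits are expected to scale with mass to the 1/3
    power, areas to the 2/3 power.  Ratios carry no isometric expectation;
    percentages follow the linear expectation (percent aerenchyma is
    classified against 0.33 in the allometry stage).
    """

    LINEAR = "linear"
    AREA = "area"
    COUNT = "count"
    RATIO = "ratio"
    PERCENT = "percent"


class TraitCategory(str, enum.Enum):
    ANATOMICAL = "anatomical"
    ARCHITECTURAL = "architectural"
    SHOOT = "shoot"


@dataclass(frozen=True)
class TraitDefinition:
    """One entry of the trait dictionary."""

    name: str
    units: str
    geometry_class: GeometryClass
    category: TraitCategory

    def __post_init__(self) -> None:
        object.__setattr__(self, "geometry_class", GeometryClass(self.geometry_class))
        object.__setattr__(self, "category", TraitCategory(self.category))


class TraitDictionary(Mapping[str, TraitDefinition]):
    """Immutable name → :class:`TraitDefinition` mapping with YAML I/O."""

    def __init__(self, definitions: Iterable[TraitDefinition]):
        defs = list(definitions)
        names = [d.name for d in defs]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate trait names in dictionary: {dup}")
        self._defs = {d.name: d for d in defs}

    def __getitem__(self, name: str) -> TraitDefinition:
        return self._defs[name]

    def __iter__(self):
        return iter(self._defs)

    def __len__(self) -> int:
        return len(self._defs)

    def subset(self, names: Iterable[str]) -> "TraitDictionary":
        return TraitDictionary(self._defs[n] for n in names)

    def to_yaml(self, path: str | Path) -> None:
        payload = [
            {
                "name": d.name,
                "units": d.units,
                "geometry_class": d.geometry_class.value,
                "category": d.category.value,
            }
            for d in self._defs.values()
        ]
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TraitDictionary":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(TraitDefinition(**entry) for entry in payload)


#: canonical trait dictionary: root cross-section anatomy, metaxylem ratios,
#: architecture and shoot traits, in the field's standard abbreviations
DEFAULT_TRAITS = TraitDictionary(
    [
        TraitDefinition("RXSA", "mm^2", GeometryClass.AREA, TraitCategory.ANATOMICAL),
        TraitDefinition("LTA", "mm^2", GeometryClass.AREA, TraitCategory.ANATOMICAL),
        TraitDefinition("TSA", "mm^2", GeometryClass.AREA, TraitCategory.ANATOMICAL),
        TraitDefinition("TCA", "mm^2", GeometryClass.AREA, TraitCategory.ANATOMICAL),
        TraitDefinition("AA", "mm^2", GeometryClass.AREA, TraitCategory.ANATOMICAL),
        TraitDefinition("percAA", "%", GeometryClass.PERCENT, TraitCategory.ANATOMICAL),
        TraitDefinition("MXA", "mm^2", GeometryClass.AREA, TraitCategory.ANATOMICAL),
        TraitDefinition("MXV", "count", GeometryClass.COUNT, TraitCategory.ANATOMICAL),
        TraitDefinition("MXA.RXSA", "dimensionless", GeometryClass.RATIO, TraitCategory.ANATOMICAL),
        TraitDefinition("MXA.TSA", "dimensionless", GeometryClass.RATIO, TraitCategory.ANATOMICAL),
        TraitDefinition("MXV.RXSA", "mm^-2", GeometryClass.RATIO, TraitCategory.ANATOMICAL),
        TraitDefinition("MXV.TSA", "mm^-2", GeometryClass.RATIO, TraitCategory.ANATOMICAL),
        TraitDefinition("axial_conductance", "mm^4 Pa^-1 s^-1", GeometryClass.RATIO, TraitCategory.ANATOMICAL),
        TraitDefinition("nodal_root_number", "count", GeometryClass.COUNT, TraitCategory.ARCHITECTURAL),
        TraitDefinition("root_depth", "cm", GeometryClass.LINEAR, TraitCategory.ARCHITECTURAL),
        TraitDefinition("root_angle", "degrees", GeometryClass.LINEAR, TraitCategory.ARCHITECTURAL),
        TraitDefinition("deep_root_count", "count", GeometryClass.COUNT, TraitCategory.ARCHITECTURAL),
        TraitDefinition("deep_root_prop", "proportion", GeometryClass.RATIO, TraitCategory.ARCHITECTURAL),
        TraitDefinition("biomass", "g", GeometryClass.LINEAR, TraitCategory.SHOOT),
        TraitDefinition("tillers", "count", GeometryClass.COUNT, TraitCategory.SHOOT),
    ]
)


class ValidationError(ValueError):
    """A phenotype table violates a structural or range invariant."""


def _canonical_treatment(value: object) -> str:
    key = str(value).strip().lower()
    if key not in _TREATMENT_SYNONYMS:
        raise ValidationError(
            f"unrecognised treatment value {value!r}; expected one of "
            f"{sorted(set(_TREATMENT_SYNONYMS))}"
        )
    return _TREATMENT_SYNONYMS[key]


def validate_table(
    table: pd.DataFrame,
    dictionary: TraitDictionary = DEFAULT_TRAITS,
    permissive: bool = False,
) -> pd.DataFrame:
    """Validate and canonicalise a plant-level phenotype table.

    Checks key completeness and uniqueness, treatment spellings, trait-name
    membership in the dictionary, numeric trait cells, and per-class range
    invariants (areas/lengths/counts nonnegative, percentages within
    [0, 100], counts integral).  Returns a canonicalised copy; row order is
    preserved and missing cells stay missing.

    With ``permissive=True`` unknown trait columns are kept but not checked.
    """
    missing_keys = [c for c in KEY_COLUMNS if c not in table.columns]
    if missing_keys:
        raise ValidationError(f"missing key columns: {missing_keys}")

    out = table.copy()
    out["treatment"] = [_canonical_treatment(v) for v in out["treatment"]]
    for col in ("experiment", "genotype", "replicate"):
        out[col] = out[col].astype(str)

    dup = out.duplicated(subset=KEY_COLUMNS, keep=False)
    if dup.any():
        first = tuple(out.loc[dup.idxmax(), KEY_COLUMNS])
        raise ValidationError(f"duplicate (experiment, genotype, treatment, replicate) tuple: {first}")

    trait_cols = [c for c in out.columns if c not in KEY_COLUMNS]
    unknown = [c for c in trait_cols if c not in dictionary]
    if unknown and not permissive:
        raise ValidationError(
            f"unknown trait columns {unknown}; pass permissive=True to keep them unchecked"
        )

    for col in trait_cols:
        if col in dictionary:
            try:
                out[col] = pd.to_numeric(out[col], errors="raise")
            except (ValueError, TypeError) as exc:
                raise ValidationError(f"non-numeric value in trait column {col!r}: {exc}") from exc
            vals = out[col].dropna()
            gc = dictionary[col].geometry_class
            if gc in (GeometryClass.AREA, GeometryClass.LINEAR, GeometryClass.COUNT) and (vals < 0).any():
                raise ValidationError(f"negative values in nonnegative trait {col!r}")
            if gc is GeometryClass.PERCENT and ((vals < 0) | (vals > 100)).any():
                bad = vals[(vals < 0) | (vals > 100)].iloc[0]
                raise ValidationError(f"percentage trait {col!r} outside [0, 100]: {bad}")
            if gc is GeometryClass.COUNT and (vals != np.round(vals)).any():
                raise ValidationError(f"non-integer values in count trait {col!r}")
    return out


def read_table(
    path: str | Path,
    dictionary: TraitDictionary = DEFAULT_TRAITS,
    permissive: bool = False,
) -> pd.DataFrame:
    """Read a delimiter-separated plant-level phenotype table and validate it."""
    table = pd.read_csv(path)
    return validate_table(table, dictionary, permissive=permissive)


def trait_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in KEY_COLUMNS]


def genotype_means(table: pd.DataFrame, traits: Iterable[str] | None = None) -> pd.DataFrame:
    """Per (experiment, genotype, treatment, trait) sample mean, SD and n.

    Only non-missing replicate values enter each summary; keys with no
    observations for a trait are omitted.  The sample SD uses the n−1
    denominator; a single replicate yields sd = 0 by convention (flagged in
    the ``single_rep`` column) so that plasticity and GCV stay computable.
    Invariant to replicate row order.
    """
    traits = list(traits) if traits is not None else trait_columns(table)
    long = table.melt(
        id_vars=["experiment", "genotype", "treatment"],
        value_vars=traits,
        var_name="trait",
        value_name="value",
    ).dropna(subset=["value"])
    grouped = long.groupby(["experiment", "genotype", "treatment", "trait"], sort=True)["value"]
    means = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    means["single_rep"] = means["n"] == 1
    means.loc[means["single_rep"], "sd"] = 0.0
    return means


# ---------------------------------------------------------------------------
# result I/O — deterministic CSV with ≥ 12 significant digits


_FLOAT_FORMAT = "%.12g"


def write_results(obj, path: str | Path) -> None:
    """Write an analysis result to CSV deterministically.

    DataFrames are written with 12 significant digits and no index, so
    ``read_results`` round-trips values.  Cluster models and other composite
    results expose their own ``to_csv``-style writers and are dispatched to
    them.
    """
    path = Path(path)
    if hasattr(obj, "to_csv_pair"):  # composite results (e.g. cluster models)
        obj.to_csv_pair(path)
        return
    if isinstance(obj, pd.Series):
        obj = obj.to_frame()
    if not isinstance(obj, pd.DataFrame):
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    obj.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def warn_flagged(message: str) -> None:
    """Route data-quality flags through the warnings machinery."""
    warnings.warn(message, UserWarning, stacklevel=3)
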