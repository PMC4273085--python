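"""Core data structures for stratified injury-burden tables.

Burden estimates (incident cases, deaths, years of life lost, years lived
with disability) are carried in long format: one row per stratum, where a
stratum is an age group x sex x epidemiologic region x category cell.  A
table's categories are either external causes of injury (mechanism: road
injury, falls, ...) or natures of injury (lesion: fracture, burn, ...),
never a mix; fatal burden is organised by cause and nonfatal burden by
nature, linked through row-stochastic cause-to-nature allocation matrices.

Regions nest into super-regions through a :class:`RegionMap`.  Age groups
are closed-open intervals labelled by their lower bound, and the standard
life table is keyed by the same labels so that years of life lost can be
computed as deaths times remaining life expectancy without midpoint
ambiguity.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "ValidationError",
    "KEY_COLUMNS",
    "VALUE_COLUMNS",
    "SEXES",
    "AXES",
    "DEFAULT_NOT_AMENABLE",
    "AmenabilityMap",
    "RegionMap",
    "LifeTable",
    "CauseNatureMatrix",
    "BurdenTable",
    "read_burden_table",
    "write_burden_table",
    "aggregate_to_super_region",
]

#: Columns that identify a stratum.
KEY_COLUMNS = ("age_group", "sex", "region", "category")
#: Burden quantities a table may carry (a given axis needs only a subset).
VALUE_COLUMNS = ("cases", "deaths", "yll", "yld")
SEXES = frozenset({"male", "female"})
AXES = frozenset({"cause", "nature"})

#: External causes treated as not addressable by a basic surgical package.
DEFAULT_NOT_AMENABLE = frozenset(
    {
        "drowning",
        "poisoning",
        "self_harm",
        "venomous_animal_contact",
        "intentional_other",
    }
)


class SchemaError(ValueError):
    """A required column or field is missing or malformed."""


class ValidationError(ValueError):
    """Values violate a domain invariant (negative counts, deaths > cases...)."""


# ---------------------------------------------------------------------------
# Configuration maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmenabilityMap:
    """Classification of external causes as surgically amenable or not.

    The default non-amenable set covers drowning, poisoning, self-harm,
    venomous animal contact and other intentional injury; every cause not
    listed is treated as amenable.  Override via :meth:`from_mapping` or a
    YAML config file.
    """

    not_amenable: frozenset[str] = DEFAULT_NOT_AMENABLE

    def is_amenable(self, cause: str) -> bool:
        return cause not in self.not_amenable

    def amenable_mask(self, causes: pd.Series | Iterable[str]) -> np.ndarray:
        """Boolean mask, True where the cause is amenable."""
        arr = pd.Series(list(causes), dtype=object)
        return ~arr.isin(self.not_amenable).to_numpy()

    @classmethod
    def default(cls) -> "AmenabilityMap":
        return cls()

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "AmenabilityMap":
        """Build from ``cause -> {"amenable", "not_amenable"}``."""
        bad = {v for v in mapping.values()} - {"amenable", "not_amenable"}
        if bad:
            raise SchemaError(f"unknown amenability labels: {sorted(bad)}")
        return cls(
            frozenset(c for c, v in mapping.items() if v == "not_amenable")
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AmenabilityMap":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise SchemaError(f"{path}: expected a mapping cause -> label")
        return cls.from_mapping(data)


@dataclass(frozen=True)
class RegionMap:
    """Many-to-one map from epidemiologic regions to super-regions."""

    mapping: Mapping[str, str]

    def super_region_of(self, region: str) -> str:
        try:
            return self.mapping[region]
        except KeyError:
            raise ValidationError(
                f"region {region!r} is not in the region map"
            ) from None

    def apply(self, regions: pd.Series) -> pd.Series:
        """Vectorised lookup; raises naming every unmapped region."""
        out = regions.map(self.mapping)
        if out.isna().any():
            missing = sorted(regions[out.isna()].unique())
            raise ValidationError(f"unmapped regions: {missing}")
        return out

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.mapping)

    @property
    def super_regions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.mapping.values():
            seen.setdefault(s, None)
        return tuple(seen)

    def regions_in(self, super_region: str) -> tuple[str, ...]:
        return tuple(r for r, s in self.mapping.items() if s == super_region)

    @classmethod
    def identity(cls, regions: Iterable[str]) -> "RegionMap":
        return cls({r: r for r in regions})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegionMap":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise SchemaError(f"{path}: expected a mapping region -> super_region")
        return cls({str(k): str(v) for k, v in data.items()})


@dataclass(frozen=True)
class LifeTable:
    """Standard remaining life expectancy by age group.

    ``ages`` fixes the ordering of age-group labels (ascending age);
    expectancies must be strictly positive and non-increasing with age.
    """

    ages: tuple[str, ...]
    expectancy: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [a for a in self.ages if a not in self.expectancy]
        if missing:
            raise SchemaError(f"life table missing age groups: {missing}")
        values = np.asarray([self.expectancy[a] for a in self.ages], dtype=float)
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise ValidationError("life expectancies must be positive and finite")
        if np.any(np.diff(values) > 0):
            raise ValidationError(
                "life expectancy must be non-increasing with age"
            )

    def expectancy_for(self, ages: pd.Series) -> np.ndarray:
        out = ages.map(self.expectancy)
        if out.isna().any():
            missing = sorted(ages[out.isna()].unique())
            raise ValidationError(f"age groups absent from life table: {missing}")
        return out.to_numpy(dtype=float)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LifeTable":
        for col in ("age_group", "life_expectancy"):
            if col not in frame.columns:
                raise SchemaError(f"life table missing column {col!r}")
        ages = tuple(str(a) for a in frame["age_group"])
        exp = dict(zip(ages, frame["life_expectancy"].astype(float)))
        return cls(ages, exp)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        return cls.from_frame(pd.read_csv(path, dtype={"age_group": str}))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age_group": self.ages,
             "life_expectancy": [self.expectancy[a] for a in self.ages]}
        )


class CauseNatureMatrix:
    """Row-stochastic allocation of external causes over natures of injury.

    One matrix (causes x natures, rows summing to one) per (age_group, sex)
    cell, with an optional ``("all", "all")`` fallback.  The matrices are an
    input to the analysis; they are normally estimated elsewhere from
    dual-coded hospital discharge data.
    """

    _TOL = 1e-9

    def __init__(self, matrices: Mapping[tuple[str, str], pd.DataFrame]):
        self._matrices = dict(matrices)
        for key, mat in self._matrices.items():
            values = mat.to_numpy(dtype=float)
            if np.any(values < -self._TOL) or np.any(values > 1 + self._TOL):
                raise ValidationError(
                    f"cause-nature matrix {key}: entries outside [0, 1]"
                )
            rowsums = values.sum(axis=1)
            bad = np.abs(rowsums - 1.0) > self._TOL
            if bad.any():
                rows = list(mat.index[bad])
                raise ValidationError(
                    f"cause-nature matrix {key}: rows do not sum to 1: {rows}"
                )

    def matrix_for(self, age_group: str, sex: str) -> pd.DataFrame:
        if (age_group, sex) in self._matrices:
            return self._matrices[(age_group, sex)]
        if ("all", "all") in self._matrices:
            return self._matrices[("all", "all")]
        raise ValidationError(
            f"no cause-nature matrix for ({age_group!r}, {sex!r})"
        )

    def keys(self) -> list[tuple[str, str]]:
        return list(self._matrices)


# ---------------------------------------------------------------------------
# Burden tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BurdenTable:
    """Validated long-format burden table for a single axis.

    Parameters
    ----------
    data
        One row per stratum with key columns ``age_group, sex, region,
        category`` and a subset of the value columns ``cases, deaths, yll,
        yld``.
    axis
        ``"cause"`` or ``"nature"``; which classification ``category``
        refers to.
    """

    data: pd.DataFrame = field(repr=False)
    axis: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", _validate_frame(self.data, self.axis))

    @property
    def value_columns(self) -> tuple[str, ...]:
        return tuple(c for c in VALUE_COLUMNS if c in self.data.columns)

    def total(self, column: str) -> float:
        return float(self.data[column].sum())

    def categories(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["category"].unique()))

    def regions(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["region"].unique()))


def _validate_frame(df: pd.DataFrame, axis: str) -> pd.DataFrame:
    if axis not in AXES:
        raise SchemaError(f"axis must be one of {sorted(AXES)}, got {axis!r}")
    for col in KEY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    present = [c for c in VALUE_COLUMNS if c in df.columns]
    if not present:
        raise SchemaError(
            f"table has none of the value columns {VALUE_COLUMNS}"
        )
    df = df.copy()
    if "axis" in df.columns:
        stated = set(df["axis"].unique())
        if stated - {axis}:
            raise ValidationError(
                f"table declared axis {axis!r} but contains rows with axis "
                f"{sorted(stated - {axis})} (tables never mix axes)"
            )
        df = df.drop(columns="axis")
    if "year" in df.columns:
        years = df["year"].unique()
        if len(years) > 1:
            raise ValidationError(
                f"multiple analysis years in one table: {sorted(years)}"
            )
        df = df.drop(columns="year")

    df["age_group"] = df["age_group"].astype(str)
    bad_sex = set(df["sex"].unique()) - SEXES
    if bad_sex:
        raise ValidationError(f"unknown sex labels: {sorted(bad_sex)}")

    for col in present:
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            row = df.index[values.isna()][0]
            raise ValidationError(
                f"non-numeric or missing {col!r} at "
                f"{_stratum_label(df.loc[row])}"
            )
        df[col] = values.astype(float)
        if not np.all(np.isfinite(df[col])):
            row = df.index[~np.isfinite(df[col])][0]
            raise ValidationError(
                f"non-finite {col!r} at {_stratum_label(df.loc[row])}"
            )
        if (df[col] < 0).any():
            row = df.index[df[col] < 0][0]
            raise ValidationError(
                f"negative {col!r} at {_stratum_label(df.loc[row])}"
            )

    if "deaths" in present and "cases" in present:
        bad = df["deaths"] > df["cases"]
        if bad.any():
            row = df.index[bad][0]
            raise ValidationError(
                f"deaths ({df.loc[row, 'deaths']:g}) exceed cases "
                f"({df.loc[row, 'cases']:g}) at {_stratum_label(df.loc[row])}"
            )

    dup = df.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        row = df.index[dup][0]
        raise ValidationError(f"duplicate stratum at {_stratum_label(df.loc[row])}")

    keep = list(KEY_COLUMNS) + present
    return df[keep].reset_index(drop=True)


def _stratum_label(row: pd.Series) -> str:
    return (
        f"(age_group={row['age_group']}, sex={row['sex']}, "
        f"region={row['region']}, category={row['category']})"
    )


def read_burden_table(path: str | Path, axis: str) -> BurdenTable:
    """Read a delimited burden table (``.tsv`` -> tab, else comma).

    The file must have a header naming the stratification columns; all
    validation of :class:`BurdenTable` applies, and errors carry the
    offending column name or stratum coordinates.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"age_group": str})
    return BurdenTable(df, axis)


def write_burden_table(table: BurdenTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    out = table.data.copy()
    out.insert(len(KEY_COLUMNS), "axis", table.axis)
    out.to_csv(path, sep=sep, index=False)


def aggregate_to_super_region(
    table: BurdenTable, region_map: RegionMap
) -> BurdenTable:
    """Sum counts and person-years within super-regions.

    The output reuses the ``region`` column for super-region identifiers so
    downstream operations apply unchanged.  Every additive quantity is
    conserved exactly (grand totals before == after).
    """
    df = table.data.copy()
    df["region"] = region_map.apply(df["region"])
    grouped = (
        df.groupby(list(KEY_COLUMNS), sort=True, as_index=False)[
            list(table.value_columns)
        ].sum()
    )
    return BurdenTable(grouped, table.axis)
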