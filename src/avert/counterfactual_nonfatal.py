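"""Counterfactual nonfatal burden and its reallocation to external causes.

Nonfatal injury burden (years lived with disability, YLD) is organised by
nature of injury, because disability weights attach to lesions rather than
mechanisms.  The counterfactual state for nonfatal burden is the lowest
YLD accrued per incident case warranting access to care, taken
element-wise over regions within each (age, sex, nature) cell:

    YLD' = cases_warranting_care x min over regions of (YLD per case).

Because no cause-to-nature matrix exists for the avertable component, the
avertable YLD pool of each super-region is carried back to external
causes proportionally: the region's avertable fraction A = (observed -
counterfactual) / observed, computed over natures, is applied to the
all-cause YLD total, and the resulting pool is distributed across
surgically amenable causes in proportion to their observed YLDs (causes
not amenable to surgery receive none, which redistributes their share).
A cap-and-respread pass guarantees no cause is allocated more than its
observed YLD while conserving the pool.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .data_model import (
    AmenabilityMap,
    BurdenTable,
    RegionMap,
    ValidationError,
    aggregate_to_super_region,
)

__all__ = [
    "yld_per_case_surface",
    "lowest_yld_per_case",
    "counterfactual_yld_nature",
    "avertable_fraction_by_region",
    "allocate_ylds_to_causes",
]

_CELL = ["age_group", "sex", "category"]
_KEYS = ["age_group", "sex", "region", "category"]


def yld_per_case_surface(
    nature_table: BurdenTable,
    care_warranting: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """YLD per incident case warranting care, per (age, sex, region, nature).

    ``care_warranting`` flags which natures count as warranting access to
    care; natures absent from the mapping — and all natures when it is
    omitted — are treated as warranting care.  Strata without cases are
    dropped (the per-case rate is undefined there).
    """
    if nature_table.axis != "nature":
        raise ValidationError("YLD-per-case surface requires a nature-axis table")
    for col in ("cases", "yld"):
        if col not in nature_table.data.columns:
            raise ValidationError(f"nature table lacks required column {col!r}")
    df = nature_table.data
    if care_warranting is not None:
        keep = df["category"].map(lambda n: care_warranting.get(n, True))
        df = df.loc[keep]
    df = df.loc[df["cases"] > 0].copy()
    df["yld_per_case"] = df["yld"] / df["cases"]
    return df.reset_index(drop=True)


def lowest_yld_per_case(surface: pd.DataFrame) -> pd.DataFrame:
    """Element-wise minimum YLD per case over regions, per (age, sex, nature).

    Cells present in no region are simply absent from the output;
    downstream they contribute zero avertable burden.
    """
    out = (
        surface.groupby(_CELL)["yld_per_case"]
        .agg(["min", "size"])
        .reset_index()
        .rename(columns={"min": "yld_per_case_lowest", "size": "n_regions"})
    )
    return out


def counterfactual_yld_nature(
    surface: pd.DataFrame,
    lowest: pd.DataFrame,
    region_map: RegionMap | None = None,
) -> pd.DataFrame:
    """Counterfactual YLD per stratum: cases x lowest per-case YLD.

    When ``region_map`` is given the result is aggregated to super-region
    level (summing observed and counterfactual person-years).
    """
    merged = surface.merge(
        lowest[_CELL + ["yld_per_case_lowest"]], on=_CELL, how="left", validate="m:1"
    )
    if merged["yld_per_case_lowest"].isna().any():
        missing = (
            merged.loc[merged["yld_per_case_lowest"].isna(), _CELL]
            .drop_duplicates()
            .to_dict("records")
        )
        raise ValidationError(f"no cross-region minimum for cells: {missing[:10]}")
    merged["yld_prime"] = merged["cases"] * merged["yld_per_case_lowest"]
    if region_map is not None:
        merged["region"] = region_map.apply(merged["region"])
        merged = merged.groupby(_KEYS, as_index=False)[
            ["cases", "yld", "yld_prime"]
        ].sum()
    return merged


def avertable_fraction_by_region(
    nature_cf: pd.DataFrame,
    *,
    granularity: str = "region",
) -> pd.DataFrame:
    """Avertable fraction A = (observed - counterfactual) / observed YLD.

    Computed over nature-level totals at ``granularity``: ``"region"``
    (one fraction per super-region, the default — this is what makes every
    amenable cause in a region show the same avertable-YLD percentage) or
    ``"region_age_sex"`` for cell-level fractions.
    """
    if granularity == "region":
        keys = ["region"]
    elif granularity == "region_age_sex":
        keys = ["region", "age_group", "sex"]
    else:
        raise ValidationError(f"unknown granularity {granularity!r}")
    totals = nature_cf.groupby(keys, as_index=False)[["yld", "yld_prime"]].sum()
    zero = totals["yld"] == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} region cells have zero observed YLD; "
            "their avertable fraction is set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(
            totals["yld"] > 0,
            (totals["yld"] - totals["yld_prime"]) / totals["yld"],
            0.0,
        )
    totals["fraction"] = np.clip(frac, 0.0, 1.0)
    return totals.rename(
        columns={"yld": "yld_observed", "yld_prime": "yld_counterfactual"}
    )


def _proportional_allocation(pool: float, observed: pd.Series) -> pd.Series:
    """Distribute ``pool`` across causes proportionally to ``observed``,
    capping each allocation at its observed value and re-spreading any
    excess over the remaining causes (at most one pass per cause)."""
    alloc = pd.Series(0.0, index=observed.index)
    remaining = float(pool)
    open_set = observed[observed > 0].index.tolist()
    for _ in range(len(open_set) + 1):
        if remaining <= 0 or not open_set:
            break
        weights = observed[open_set]
        share = remaining * weights / weights.sum()
        headroom = observed[open_set] - alloc[open_set]
        over = share > headroom + 1e-12
        if not over.any():
            alloc[open_set] += share
            remaining = 0.0
            break
        capped = [c for c in open_set if over[c]]
        alloc[capped] = observed[capped]
        remaining -= float(headroom[capped].sum())
        open_set = [c for c in open_set if not over[c]]
    if remaining > 1e-9 * max(1.0, float(pool)):
        raise ValidationError(
            "avertable YLD pool exceeds total observed YLD of amenable causes; "
            "cannot redistribute"
        )
    return alloc


def allocate_ylds_to_causes(
    fractions: pd.DataFrame,
    cause_ylds: BurdenTable | pd.DataFrame,
    amenability: AmenabilityMap,
    *,
    region_map: RegionMap | None = None,
) -> pd.DataFrame:
    """Allocate each region's avertable YLD pool to amenable causes.

    Parameters
    ----------
    fractions
        Output of :func:`avertable_fraction_by_region` (region-level).
    cause_ylds
        Cause-axis burden table (or frame) with observed YLDs covering all
        causes, amenable and not; aggregated via ``region_map`` if given.
    amenability
        Causes flagged not amenable receive zero avertable YLD.

    Returns one row per (region, cause) with observed, avertable and
    counterfactual YLD.  The total allocated equals the pool
    (A x all-cause YLD) exactly up to rounding; an amenable-YLD total of
    zero combined with a positive pool is an error.
    """
    if isinstance(cause_ylds, BurdenTable):
        if region_map is not None:
            cause_ylds = aggregate_to_super_region(cause_ylds, region_map)
        cause_df = cause_ylds.data
    else:
        cause_df = cause_ylds
    if "yld" not in cause_df.columns:
        raise ValidationError("cause table lacks required column 'yld'")

    totals = cause_df.groupby(["region", "category"], as_index=False)["yld"].sum()
    frac = fractions.set_index("region")["fraction"]

    out_frames = []
    for region, grp in totals.groupby("region"):
        grp = grp.set_index("category")
        a = float(frac.get(region, 0.0))
        pool = a * float(grp["yld"].sum())
        amenable = pd.Index(
            [c for c in grp.index if amenability.is_amenable(c)]
        )
        alloc = pd.Series(0.0, index=grp.index)
        if pool > 0:
            if len(amenable) == 0 or grp.loc[amenable, "yld"].sum() <= 0:
                raise ValidationError(
                    f"region {region!r}: positive avertable YLD pool but no "
                    "amenable cause with observed YLD to receive it"
                )
            alloc[amenable] = _proportional_allocation(pool, grp.loc[amenable, "yld"])
        frame = pd.DataFrame(
            {
                "region": region,
                "category": grp.index,
                "yld_observed": grp["yld"].to_numpy(),
                "yld_avertable": alloc.to_numpy(),
            }
        )
        out_frames.append(frame)
    out = pd.concat(out_frames, ignore_index=True)
    out["yld_counterfactual"] = out["yld_observed"] - out["yld_avertable"]
    return out
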