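"""Counterfactual case-fatality rates and avertable fatal burden.

The counterfactual state is full access to quality basic surgical care.
For fatal burden it is operationalised per (age, sex, cause) cell as the
lowest case-fatality rate observed across epidemiologic regions — after
removing the part of fatality attributable to deaths occurring before
hospital arrival, which no surgical system can avert.

An observed case-fatality rate CFR is decomposed, given the prehospital
death proportion pi (share of deaths occurring before arrival), as

    CFR = d + (1 - d) * h,    d = CFR * pi,

where ``d`` is the prehospital death rate per incident case and ``h`` the
in-hospital case-fatality rate among cases arriving alive.  The
counterfactual replaces ``h`` with the element-wise minimum ``h*`` across
regions while keeping the target region's own ``d``:

    CFR' = d + (1 - d) * h*.

Counterfactual deaths are incident cases times CFR', counterfactual years
of life lost are counterfactual deaths times standard remaining life
expectancy, and avertable burden is observed minus counterfactual, floored
at zero and forced to zero for causes not amenable to surgery.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data_model import (
    AmenabilityMap,
    BurdenTable,
    LifeTable,
    RegionMap,
    ValidationError,
    aggregate_to_super_region,
)

__all__ = [
    "decompose_cfr",
    "recompose_cfr",
    "cfr_surface",
    "counterfactual_cfr",
    "counterfactual_deaths",
    "counterfactual_yll",
    "avertable_fatal",
]

_CELL = ["age_group", "sex", "category"]
_KEYS = ["age_group", "sex", "region", "category"]


def decompose_cfr(cfr, prehosp):
    """Split an observed CFR into prehospital and in-hospital components.

    Returns ``(d, h)`` with ``d = cfr * pi`` the prehospital death rate per
    incident case and ``h = cfr * (1 - pi) / (1 - cfr * pi)`` the
    in-hospital CFR among cases arriving alive.  Accepts scalars or
    arrays; the recomposition ``d + (1 - d) * h`` returns ``cfr`` exactly
    up to rounding.
    """
    cfr = np.asarray(cfr, dtype=float)
    pi = np.asarray(prehosp, dtype=float)
    if np.any((cfr < 0) | (cfr > 1)):
        raise ValidationError("cfr must lie in [0, 1]")
    if np.any((pi <= 0) | (pi >= 1)):
        raise ValidationError("prehospital proportion must lie in (0, 1)")
    d = cfr * pi
    with np.errstate(invalid="ignore"):
        h = np.where(d < 1.0, cfr * (1.0 - pi) / (1.0 - d), 1.0)
    if cfr.ndim == 0:
        return float(d), float(h)
    return d, h


def recompose_cfr(d, h):
    """Inverse of :func:`decompose_cfr`: overall CFR from components."""
    d = np.asarray(d, dtype=float)
    h = np.asarray(h, dtype=float)
    out = d + (1.0 - d) * h
    return float(out) if out.ndim == 0 else out


def cfr_surface(table: BurdenTable) -> pd.DataFrame:
    """Observed CFR per stratum; strata without incident cases are dropped
    (they contribute no burden either way)."""
    if table.axis != "cause":
        raise ValidationError("CFR surface requires a cause-axis table")
    for col in ("cases", "deaths"):
        if col not in table.data.columns:
            raise ValidationError(f"cause table lacks required column {col!r}")
    df = table.data.loc[table.data["cases"] > 0].copy()
    df["cfr"] = df["deaths"] / df["cases"]
    return df.reset_index(drop=True)


def attach_prehospital(surface: pd.DataFrame, pi: pd.DataFrame) -> pd.DataFrame:
    """Merge prehospital proportions onto a CFR surface.

    ``pi`` needs a ``pi`` column plus any subset of the stratum keys
    (typically region and sex); the merge uses whichever key columns are
    present, so a region x sex table broadcasts over ages and causes.
    """
    if "pi" not in pi.columns:
        raise ValidationError("prehospital table must have a 'pi' column")
    on = [c for c in _KEYS if c in pi.columns]
    if not on:
        if len(pi) != 1:
            raise ValidationError(
                "prehospital table without key columns must be a single row"
            )
        merged = surface.copy()
        merged["pi"] = float(pi["pi"].iloc[0])
        return merged
    merged = surface.merge(pi[on + ["pi"]], on=on, how="left", validate="m:1")
    if merged["pi"].isna().any():
        missing = (
            merged.loc[merged["pi"].isna(), on].drop_duplicates().to_dict("records")
        )
        raise ValidationError(f"no prehospital proportion for strata: {missing[:10]}")
    bad = (merged["pi"] <= 0) | (merged["pi"] >= 1)
    if bad.any():
        raise ValidationError("prehospital proportions must lie in (0, 1)")
    return merged


def counterfactual_cfr(
    table: BurdenTable,
    pi: pd.DataFrame,
    region_map: RegionMap,
    *,
    target_regions: list[str] | None = None,
) -> pd.DataFrame:
    """Counterfactual CFR per (age, sex, super-region, cause).

    Region-level observed CFRs are decomposed with each region's own
    prehospital proportion; the in-hospital component is minimised
    element-wise over all regions sharing an (age, sex, cause) cell; the
    target super-region's aggregate CFR is then recomposed with its own
    prehospital death rate and the minimal in-hospital rate.  The target's
    own (aggregated) in-hospital rate participates in the minimum, so
    CFR' never exceeds the observed CFR.

    Cells observed in a single region only yield CFR' equal to the
    observed CFR (zero avertable); a warning reports how many.

    Returns a frame keyed by (age_group, sex, region, category) — region
    holding super-region identifiers — with columns ``cases, deaths, cfr,
    pi, d, h, h_star, cfr_prime``.
    """
    surface = cfr_surface(table)
    surface = attach_prehospital(surface, pi)
    d, h = decompose_cfr(surface["cfr"].to_numpy(), surface["pi"].to_numpy())
    surface["d"] = d
    surface["h"] = h

    cell = surface.groupby(_CELL)["h"].agg(["min", "size"]).reset_index()
    cell = cell.rename(columns={"min": "h_star", "size": "n_regions"})
    singletons = int((cell["n_regions"] == 1).sum())
    if singletons:
        warnings.warn(
            f"{singletons} (age, sex, cause) cells have data from a single "
            "region; their counterfactual CFR equals the observed CFR",
            stacklevel=2,
        )

    # Aggregate to super-region: sum cases/deaths, death-weighted pi.
    agg = surface.copy()
    agg["region"] = region_map.apply(agg["region"])
    agg["prehosp_deaths"] = agg["deaths"] * agg["pi"]
    out = (
        agg.groupby(_KEYS, as_index=False)[["cases", "deaths", "prehosp_deaths"]]
        .sum()
    )
    out["cfr"] = out["deaths"] / out["cases"]
    with np.errstate(invalid="ignore"):
        out["pi"] = np.where(
            out["deaths"] > 0, out["prehosp_deaths"] / out["deaths"], 0.0
        )
    out = out.drop(columns="prehosp_deaths")
    out["d"] = out["cfr"] * out["pi"]
    with np.errstate(invalid="ignore", divide="ignore"):
        own_h = np.where(
            out["d"] < 1.0,
            out["cfr"] * (1.0 - out["pi"]) / (1.0 - out["d"]),
            1.0,
        )
    out["h"] = own_h
    out = out.merge(cell[_CELL + ["h_star", "n_regions"]], on=_CELL, how="left")
    # The super-region aggregate in-hospital rate joins the minimum: a
    # weighted aggregate can in principle dip below every member region's
    # value only through the pi weighting, and the counterfactual must
    # never exceed what the region already achieves.
    out["h_star"] = np.minimum(out["h_star"], out["h"])
    out["cfr_prime"] = recompose_cfr(out["d"].to_numpy(), out["h_star"].to_numpy())
    out["cfr_prime"] = np.minimum(out["cfr_prime"], out["cfr"])

    if target_regions is not None:
        out = out[out["region"].isin(target_regions)].reset_index(drop=True)
    return out


def _aligned_merge(
    left: pd.DataFrame, right: pd.DataFrame, columns: list[str], what: str
) -> pd.DataFrame:
    merged = left.merge(right[_KEYS + columns], on=_KEYS, how="left", validate="1:1")
    if merged[columns[0]].isna().any():
        missing = (
            merged.loc[merged[columns[0]].isna(), _KEYS]
            .drop_duplicates()
            .to_dict("records")
        )
        raise ValidationError(f"misaligned strata, missing {what}: {missing[:10]}")
    return merged


def counterfactual_deaths(
    cases: pd.DataFrame, cfr_prime: pd.DataFrame
) -> pd.DataFrame:
    """Counterfactual deaths = incident cases x counterfactual CFR.

    ``cases`` and ``cfr_prime`` are stratum-keyed frames with ``cases``
    and ``cfr_prime`` columns respectively; strata must align one-to-one
    (missing keys are reported).
    """
    merged = _aligned_merge(
        cases[_KEYS + ["cases"]], cfr_prime, ["cfr_prime"], "cfr_prime"
    )
    merged["deaths_prime"] = merged["cases"] * merged["cfr_prime"]
    return merged


def counterfactual_yll(
    deaths_prime: pd.DataFrame, life_table: LifeTable
) -> pd.DataFrame:
    """Counterfactual YLL = counterfactual deaths x standard life expectancy."""
    out = deaths_prime.copy()
    out["yll_prime"] = out["deaths_prime"] * life_table.expectancy_for(
        out["age_group"]
    )
    return out


def avertable_fatal(
    observed: BurdenTable,
    counterfactual: pd.DataFrame,
    amenability: AmenabilityMap,
    *,
    region_map: RegionMap | None = None,
) -> pd.DataFrame:
    """Avertable deaths and YLL: observed minus counterfactual per stratum.

    ``observed`` must already be at the same regional resolution as
    ``counterfactual`` (pass ``region_map`` to aggregate it here).
    Rounding negatives within a relative 1e-9 band are clamped to zero;
    larger negatives indicate an invariant violation and raise.  Causes
    not amenable to surgery get zero avertable burden by construction.
    """
    if region_map is not None:
        observed = aggregate_to_super_region(observed, region_map)
    obs = observed.data[_KEYS + ["cases", "deaths", "yll"]]
    merged = obs.merge(
        counterfactual[_KEYS + ["deaths_prime", "yll_prime"]],
        on=_KEYS,
        how="left",
        validate="1:1",
    )
    # Strata without counterfactual values carry no cases (skipped cells):
    # they contribute zero avertable burden.
    no_cf = merged["deaths_prime"].isna()
    if (merged.loc[no_cf, "cases"] > 0).any():
        missing = (
            merged.loc[no_cf & (merged["cases"] > 0), _KEYS]
            .drop_duplicates()
            .to_dict("records")
        )
        raise ValidationError(
            f"counterfactual missing for strata with cases: {missing[:10]}"
        )
    merged.loc[no_cf, "deaths_prime"] = merged.loc[no_cf, "deaths"]
    merged.loc[no_cf, "yll_prime"] = merged.loc[no_cf, "yll"]

    amenable = amenability.amenable_mask(merged["category"])
    merged.loc[~amenable, "deaths_prime"] = merged.loc[~amenable, "deaths"]
    merged.loc[~amenable, "yll_prime"] = merged.loc[~amenable, "yll"]

    for obs_col, cf_col, out_col in (
        ("deaths", "deaths_prime", "deaths_avertable"),
        ("yll", "yll_prime", "yll_avertable"),
    ):
        avert = merged[obs_col] - merged[cf_col]
        tol = 1e-9 * np.maximum(1.0, merged[obs_col])
        bad = avert < -tol
        if bad.any():
            rows = merged.loc[bad, _KEYS].to_dict("records")
            raise ValidationError(
                f"counterfactual {obs_col} exceeds observed beyond rounding "
                f"tolerance at {rows[:10]}"
            )
        merged[out_col] = np.maximum(avert, 0.0)
        # keep the counterfactual consistent with the clamp
        merged[cf_col] = merged[obs_col] - merged[out_col]

    return merged.rename(
        columns={
            "deaths": "deaths_observed",
            "yll": "yll_observed",
            "deaths_prime": "deaths_counterfactual",
            "yll_prime": "yll_counterfactual",
        }
    )
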