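"""Packaged fixture of published avertable-burden estimates.

The packaged CSV transcribes a published table of surgically avertable
deaths, YLLs, YLDs and DALYs for six low- and middle-income super-regions
by six amenable external causes, together with the printed avertable
percentages and the row/column totals (coded ``region == "all"`` /
``cause == "all"``).

The underlying observed burden is not published cell by cell, so where an
observed denominator is needed it is reconstructed as
``avertable / (percent / 100)`` from the printed percentage — a
fixture-only path whose precision is limited by the whole-percent
rounding of the source.  Margin rows must be used for region-level
denominators: the printed table omits non-amenable causes, so summing
reconstructed cells understates a region's all-injury burden.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .reporting import STATES, AvertableResult, round_half_up

__all__ = [
    "load_published",
    "published_cells",
    "published_margins",
    "published_result",
    "reconstruct_observed",
    "overall_proportion_pct",
    "consistency_report",
]

FIXTURE_REGIONS = (
    "east_europe_central_asia",
    "sub_saharan_africa",
    "north_africa_middle_east",
    "south_asia",
    "east_asia_pacific",
    "latin_america_caribbean",
)
FIXTURE_CAUSES = (
    "road_injury",
    "other_transport",
    "falls",
    "fire_heat_hot_substances",
    "unintentional_other",
    "interpersonal_violence",
)


def load_published() -> pd.DataFrame:
    """Full fixture: cells plus margin rows (region or cause == "all")."""
    with resources.files("avert").joinpath("data/published_avertable.csv").open() as fh:
        return pd.read_csv(fh)


def published_cells(df: pd.DataFrame | None = None) -> pd.DataFrame:
    df = load_published() if df is None else df
    return df[(df["region"] != "all") & (df["cause"] != "all")].reset_index(drop=True)


def published_margins(df: pd.DataFrame | None = None, margin: str = "region") -> pd.DataFrame:
    """Margin rows: ``margin="region"`` gives per-region all-cause totals,
    ``"cause"`` per-cause all-region totals, ``"grand"`` the single total."""
    df = load_published() if df is None else df
    if margin == "region":
        sel = (df["cause"] == "all") & (df["region"] != "all")
    elif margin == "cause":
        sel = (df["region"] == "all") & (df["cause"] != "all")
    elif margin == "grand":
        sel = (df["region"] == "all") & (df["cause"] == "all")
    else:
        raise ValueError(f"unknown margin {margin!r}")
    return df[sel].reset_index(drop=True)


def reconstruct_observed(df: pd.DataFrame) -> pd.DataFrame:
    """Add an ``observed`` column = avertable / (percent / 100)."""
    out = df.copy()
    out["observed"] = out["avertable"] / (out["percent"] / 100.0)
    return out


def published_result() -> AvertableResult:
    """The fixture cells as an :class:`AvertableResult` grid.

    Observed values per cell are reconstructed from the printed cell
    percentages; counterfactual = observed - avertable.  Only the six
    amenable causes are present (the source omits non-amenable causes),
    so region-margin proportions computed from this grid are avertable
    shares of *amenable* burden, not of all injuries.
    """
    cells = reconstruct_observed(published_cells())
    wide = cells.pivot_table(
        index=["region", "cause"],
        columns="outcome",
        values=["avertable", "observed"],
    )
    rows = {}
    for outcome in ("deaths", "yll", "yld", "daly"):
        rows[f"{outcome}_avertable"] = wide[("avertable", outcome)]
        rows[f"{outcome}_observed"] = wide[("observed", outcome)]
        rows[f"{outcome}_counterfactual"] = (
            wide[("observed", outcome)] - wide[("avertable", outcome)]
        )
    grid = pd.DataFrame(rows).reset_index().rename(columns={"cause": "category"})
    # printed YLL/YLD/DALY cells carry independent rounding; rebuild DALY
    # from its components so the additivity invariant holds exactly
    for state in STATES:
        grid[f"daly_{state}"] = grid[f"yll_{state}"] + grid[f"yld_{state}"]
    return AvertableResult(grid)


def overall_proportion_pct(outcome: str) -> float:
    """Overall avertable percentage for one outcome across regions.

    Numerator: sum of printed per-region avertable totals.  Denominator:
    per-region observed totals reconstructed from the printed region
    percentages (the only route that includes non-amenable causes).
    Returned as whole percent, half-up.
    """
    margins = reconstruct_observed(published_margins(margin="region"))
    margins = margins[margins["outcome"] == outcome]
    return round_half_up(
        100.0 * margins["avertable"].sum() / margins["observed"].sum(), 0
    )


def consistency_report() -> dict:
    """Internal-consistency checks of the transcribed fixture.

    Verifies that cell sums reproduce the printed margins (within the
    rounding of the source) and that YLL + YLD reproduces the printed
    DALY cell by cell.
    """
    df = load_published()
    cells = published_cells(df)
    report: dict[str, float | bool] = {}

    def margin_gap(margin: str, keys: list[str]) -> float:
        sums = cells.groupby(keys + ["outcome"])["avertable"].sum()
        printed = published_margins(df, margin).set_index(keys + ["outcome"])["avertable"]
        return float(np.abs(sums - printed.reindex(sums.index)).max())

    report["max_region_margin_gap"] = margin_gap("region", ["region"])
    report["max_cause_margin_gap"] = margin_gap("cause", ["cause"])
    pivot = cells.pivot_table(
        index=["region", "cause"], columns="outcome", values="avertable"
    )
    report["max_daly_additivity_gap"] = float(
        np.abs(pivot["yll"] + pivot["yld"] - pivot["daly"]).max()
    )
    report["ok"] = (
        report["max_region_margin_gap"] <= 3
        and report["max_cause_margin_gap"] <= 3
        and report["max_daly_additivity_gap"] <= 2
    )
    return report
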