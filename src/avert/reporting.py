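"""Assembly of avertable DALYs, summary proportions, and report output.

Disability-adjusted life years (DALYs) combine fatal and nonfatal burden:
DALY = YLL + YLD for each of the observed, counterfactual and avertable
states.  This module merges the fatal (deaths/YLL by cause) and nonfatal
(YLD by cause after proportional reallocation) results into one grid per
(super-region, cause), computes avertable proportions at any margin, and
produces headline summaries with presentation rounding (0.1 million
person-years, whole percent, half-up) kept strictly out of computation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import ValidationError

__all__ = [
    "OUTCOMES",
    "STATES",
    "AvertableResult",
    "HeadlineSummary",
    "assemble_dalys",
    "avertable_proportions",
    "headline",
    "write_report",
    "round_half_up",
]

OUTCOMES = ("deaths", "yll", "yld", "daly")
STATES = ("observed", "counterfactual", "avertable")
_GRID = ["region", "category"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _millions(x: float) -> float:
    return round_half_up(x / 1e6, 1)


def _pct(x: float) -> float:
    return round_half_up(100.0 * x, 0)


@dataclass(frozen=True)
class AvertableResult:
    """Observed / counterfactual / avertable burden per (region, cause).

    ``data`` holds one row per cell with columns ``{outcome}_{state}`` for
    every outcome in deaths, yll, yld, daly and state in observed,
    counterfactual, avertable.  DALY additivity (daly = yll + yld within
    each state) is enforced at construction.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        for col in _GRID:
            if col not in df.columns:
                raise ValidationError(f"result grid missing column {col!r}")
        for outcome in OUTCOMES:
            for state in STATES:
                col = f"{outcome}_{state}"
                if col not in df.columns:
                    raise ValidationError(f"result grid missing column {col!r}")
        for state in STATES:
            lhs = df[f"daly_{state}"]
            rhs = df[f"yll_{state}"] + df[f"yld_{state}"]
            tol = 1e-9 * np.maximum(1.0, np.abs(rhs))
            if (np.abs(lhs - rhs) > tol).any():
                raise ValidationError(
                    f"DALY additivity violated in state {state!r}"
                )
        object.__setattr__(
            self, "data", df.sort_values(_GRID).reset_index(drop=True)
        )

    def totals(self, state: str = "avertable") -> dict[str, float]:
        return {
            outcome: float(self.data[f"{outcome}_{state}"].sum())
            for outcome in OUTCOMES
        }

    def by_region(self) -> pd.DataFrame:
        cols = [f"{o}_{s}" for o in OUTCOMES for s in STATES]
        return self.data.groupby("region", as_index=False)[cols].sum()

    def by_cause(self) -> pd.DataFrame:
        cols = [f"{o}_{s}" for o in OUTCOMES for s in STATES]
        return self.data.groupby("category", as_index=False)[cols].sum()


def assemble_dalys(
    fatal: pd.DataFrame, nonfatal: pd.DataFrame
) -> AvertableResult:
    """Merge fatal (deaths/YLL) and nonfatal (YLD) results into DALYs.

    ``fatal`` carries ``deaths_*`` and ``yll_*`` columns, ``nonfatal``
    carries ``yld_*`` columns, both keyed by (region, category); age and
    sex dimensions, if present, are summed out first.  A cause present on
    one side only is treated as zero burden on the other, with a warning.
    """
    fatal_cols = [f"{o}_{s}" for o in ("deaths", "yll") for s in STATES]
    yld_cols = [f"yld_{s}" for s in STATES]
    f = fatal.groupby(_GRID, as_index=False)[fatal_cols].sum()
    n = nonfatal.groupby(_GRID, as_index=False)[yld_cols].sum()

    merged = f.merge(n, on=_GRID, how="outer", indicator=True)
    lopsided = merged["_merge"] != "both"
    if lopsided.any():
        cells = merged.loc[lopsided, _GRID].to_dict("records")
        warnings.warn(
            f"{int(lopsided.sum())} region-cause cells present in only one "
            f"of fatal/nonfatal inputs (treated as zero): {cells[:5]}",
            stacklevel=2,
        )
    merged = merged.drop(columns="_merge").fillna(0.0)
    for state in STATES:
        merged[f"daly_{state}"] = merged[f"yll_{state}"] + merged[f"yld_{state}"]
    return AvertableResult(merged)


def avertable_proportions(
    result: AvertableResult, by: str = "cell"
) -> pd.DataFrame:
    """Avertable / observed per outcome at the requested margin.

    ``by`` is one of ``cell``, ``region``, ``cause``, ``overall``.
    Cells with zero observed burden get a missing (NaN) proportion —
    undefined, never reported as zero.  Because each margin sums both
    numerator and denominator before dividing, margins commute with
    aggregation.
    """
    if by == "cell":
        df = result.data.copy()
    elif by == "region":
        df = result.by_region()
    elif by == "cause":
        df = result.by_cause()
    elif by == "overall":
        cols = [f"{o}_{s}" for o in OUTCOMES for s in STATES]
        df = result.data[cols].sum().to_frame().T
    else:
        raise ValidationError(f"unknown margin {by!r}")
    for outcome in OUTCOMES:
        obs = df[f"{outcome}_observed"]
        with np.errstate(invalid="ignore", divide="ignore"):
            prop = np.where(obs > 0, df[f"{outcome}_avertable"] / obs, np.nan)
        df[f"{outcome}_avertable_proportion"] = prop
    return df


@dataclass(frozen=True)
class HeadlineSummary:
    """Rounded headline statistics for presentation.

    Burden totals are reported in millions to one decimal, proportions in
    whole percent (both half-up); argmax rankings are over unrounded
    values with lexicographic tie-breaking and an explicit tie flag.
    """

    totals_avertable: dict[str, float]
    totals_avertable_million: dict[str, float]
    proportions_pct: dict[str, float]
    top_region_by_avertable_daly: str
    top_region_by_proportion: str
    top_cause_by_avertable_daly: str
    top_cause_by_proportion: str
    ties: dict[str, bool]

    def to_dict(self) -> dict:
        return {
            "totals_avertable": self.totals_avertable,
            "totals_avertable_million": self.totals_avertable_million,
            "proportions_pct": self.proportions_pct,
            "top_region_by_avertable_daly": self.top_region_by_avertable_daly,
            "top_region_by_proportion": self.top_region_by_proportion,
            "top_cause_by_avertable_daly": self.top_cause_by_avertable_daly,
            "top_cause_by_proportion": self.top_cause_by_proportion,
            "ties": self.ties,
        }


def _argmax_lex(df: pd.DataFrame, key_col: str, value_col: str) -> tuple[str, bool]:
    if not len(df):
        return "", False
    values = df[value_col].to_numpy(dtype=float)
    finite = np.where(np.isnan(values), -np.inf, values)
    best = finite.max()
    winners = sorted(df.loc[finite == best, key_col])
    return winners[0], len(winners) > 1


def headline(result: AvertableResult) -> HeadlineSummary:
    """Totals, rankings and rounded presentation values."""
    totals = result.totals("avertable")
    overall = avertable_proportions(result, by="overall").iloc[0]
    regions = avertable_proportions(result, by="region")
    causes = avertable_proportions(result, by="cause")

    top_region, tie_r = _argmax_lex(regions, "region", "daly_avertable")
    top_region_p, tie_rp = _argmax_lex(
        regions, "region", "daly_avertable_proportion"
    )
    top_cause, tie_c = _argmax_lex(causes, "category", "daly_avertable")
    top_cause_p, tie_cp = _argmax_lex(
        causes, "category", "daly_avertable_proportion"
    )

    return HeadlineSummary(
        totals_avertable=totals,
        totals_avertable_million={o: _millions(v) for o, v in totals.items()},
        proportions_pct={
            o: _pct(overall[f"{o}_avertable_proportion"])
            for o in OUTCOMES
            if np.isfinite(overall[f"{o}_avertable_proportion"])
        },
        top_region_by_avertable_daly=top_region,
        top_region_by_proportion=top_region_p,
        top_cause_by_avertable_daly=top_cause,
        top_cause_by_proportion=top_cause_p,
        ties={
            "region_by_avertable_daly": tie_r,
            "region_by_proportion": tie_rp,
            "cause_by_avertable_daly": tie_c,
            "cause_by_proportion": tie_cp,
        },
    )


def write_report(
    result: AvertableResult,
    summary: HeadlineSummary,
    out_dir: str | Path,
    *,
    plots: bool = False,
) -> list[Path]:
    """Write the full result grid (CSV) and headline summary (JSON).

    Output is deterministic: rows sorted, floats via repr, JSON keys
    sorted — identical inputs yield byte-identical files.  With
    ``plots=True`` a stacked-bar summary figure is also written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    csv_path = out_dir / "avertable_result.csv"
    cols = _GRID + [f"{o}_{s}" for o in OUTCOMES for s in STATES]
    grid = result.data[cols].sort_values(_GRID)
    csv_path.write_text(grid.to_csv(index=False, lineterminator="\n"))
    written.append(csv_path)

    json_path = out_dir / "headline.json"
    json_path.write_text(
        json.dumps(summary.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    written.append(json_path)

    if plots and len(result.data):
        written.append(_summary_plot(result, out_dir))
    return written


def _summary_plot(result: AvertableResult, out_dir: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    regions = result.by_region()
    fig, ax = plt.subplots(figsize=(8, 4.5))
    x = np.arange(len(regions))
    avert = regions["daly_avertable"] / 1e6
    nonavert = regions["daly_counterfactual"] / 1e6
    ax.bar(x, avert, label="avertable")
    ax.bar(x, nonavert, bottom=avert, label="non-avertable")
    ax.set_xticks(x)
    ax.set_xticklabels(regions["region"], rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("DALYs (millions)")
    ax.legend()
    fig.tight_layout()
    path = out_dir / "avertable_dalys_by_region.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
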