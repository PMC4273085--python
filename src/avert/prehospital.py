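"""Pooling of prehospital-death proportions across studies.

A share of fatal injury cases dies before reaching any hospital; those
deaths cannot be averted by surgical care, so counterfactual case-fatality
rates must be adjusted for the proportion reaching hospital alive.  Study
level data (prehospital deaths / all deaths) are sparse — available for a
handful of countries — and have to be pooled and extrapolated to regions
without data.

This module implements that pooling as a logit-scale random-effects
meta-regression: study proportions are logit-transformed with delta-method
variances, between-study heterogeneity is estimated by the
DerSimonian-Laird moment estimator generalised to a regression design, and
fixed-effect covariates capture super-region, sex, and study age.
Super-region effects use sum-to-zero coding so the intercept is a global
mean; predictions for regions with no data fall back to that global
intercept plus the remaining covariate effects.
"""

from __future__ import annotations

import json
import math
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_model import RegionMap, SchemaError, ValidationError

__all__ = [
    "StudyRecord",
    "PrehospitalModel",
    "PrehospitalPredictor",
    "fit_prehospital_model",
    "fit_prehospital_models",
    "read_study_records",
]

#: Predictions are clamped to the open interval (EPS, 1 - EPS).
EPS = 1e-6

#: Sex is coded +1/2 (male) vs -1/2 (female); "both" sits at the intercept.
_SEX_CODE = {"male": 0.5, "female": -0.5, "both": 0.0}


@dataclass(frozen=True)
class StudyRecord:
    """One study-level observation of the prehospital death proportion.

    ``events`` is the number of deaths occurring before hospital arrival
    out of ``total`` injury deaths observed by the study.
    """

    events: int
    total: int
    region: str
    sex: str = "both"
    age_mid: float = 30.0
    cause_group: str = "all"
    source_id: str | None = None

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValidationError(f"study {self.source_id}: total must be > 0")
        if not 0 <= self.events <= self.total:
            raise ValidationError(
                f"study {self.source_id}: events must lie in [0, total]"
            )
        if self.sex not in _SEX_CODE:
            raise ValidationError(
                f"study {self.source_id}: sex must be male/female/both"
            )

    @property
    def proportion(self) -> float:
        return self.events / self.total


def read_study_records(path: str | Path) -> list[StudyRecord]:
    """Read study records from CSV (events, total, region, sex, age_mid,
    cause_group, source_id; the last four optional)."""
    df = pd.read_csv(path)
    for col in ("events", "total", "region"):
        if col not in df.columns:
            raise SchemaError(f"study-record file missing column {col!r}")
    records = []
    for _, row in df.iterrows():
        records.append(
            StudyRecord(
                events=int(row["events"]),
                total=int(row["total"]),
                region=str(row["region"]),
                sex=str(row.get("sex", "both")),
                age_mid=float(row.get("age_mid", 30.0)),
                cause_group=str(row.get("cause_group", "all")),
                source_id=str(row["source_id"]) if "source_id" in df.columns else None,
            )
        )
    return records


def _logit_outcomes(records: Sequence[StudyRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Logit-transformed proportions and delta-method variances.

    Studies with zero or all events get a 0.5 continuity correction added
    to both cells, the standard remedy for infinite logits.
    """
    y = np.empty(len(records))
    v = np.empty(len(records))
    for i, rec in enumerate(records):
        e, t = float(rec.events), float(rec.total)
        if e == 0.0 or e == t:
            e += 0.5
            t += 1.0
        y[i] = math.log(e / (t - e))
        v[i] = 1.0 / e + 1.0 / (t - e)
    return y, v


@dataclass(frozen=True)
class PrehospitalModel:
    """Fitted logit-scale random-effects model of the prehospital proportion.

    ``region_offsets`` are super-region deviations from the global
    ``intercept`` (sum-to-zero coding); ``sex_effect`` is the male-female
    contrast applied as +-1/2; ``age_slope`` multiplies ``age_mid``
    centred at ``age_center``; ``tau2`` is the between-study variance on
    the logit scale.
    """

    intercept: float
    region_offsets: Mapping[str, float] = field(default_factory=dict)
    sex_effect: float = 0.0
    age_slope: float = 0.0
    age_center: float = 0.0
    tau2: float = 0.0
    cause_group: str = "all"
    n_studies: int = 0

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValidationError("between-study variance tau2 must be >= 0")

    def linear_predictor(
        self, super_region: str | None, sex: str = "both", age_mid: float | None = None
    ) -> float:
        eta = self.intercept
        if super_region is not None:
            eta += self.region_offsets.get(super_region, 0.0)
        eta += self.sex_effect * _SEX_CODE.get(sex, 0.0)
        if age_mid is not None:
            eta += self.age_slope * (age_mid - self.age_center)
        return eta

    def predict(
        self, super_region: str | None, sex: str = "both", age_mid: float | None = None
    ) -> float:
        """Predicted proportion, clamped to (EPS, 1 - EPS)."""
        p = float(expit(self.linear_predictor(super_region, sex, age_mid)))
        return min(max(p, EPS), 1.0 - EPS)

    def summary(self) -> dict:
        return {
            "cause_group": self.cause_group,
            "intercept": self.intercept,
            "region_offsets": dict(self.region_offsets),
            "sex_effect": self.sex_effect,
            "age_slope": self.age_slope,
            "age_center": self.age_center,
            "tau2": self.tau2,
            "n_studies": self.n_studies,
            "pooled_proportion": self.predict(None),
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)


def _effects_columns(levels: Sequence[str], values: Sequence[str]) -> np.ndarray:
    """Sum-to-zero (deviation) coding: columns for all levels but the last,
    rows at the last level coded -1 across every column."""
    k = len(levels)
    index = {lev: i for i, lev in enumerate(levels)}
    X = np.zeros((len(values), k - 1))
    for row, val in enumerate(values):
        i = index[val]
        if i < k - 1:
            X[row, i] = 1.0
        else:
            X[row, :] = -1.0
    return X


def fit_prehospital_model(
    records: Sequence[StudyRecord],
    region_map: RegionMap | None = None,
    *,
    use_region: bool = True,
    use_sex: bool = True,
    use_age: bool = True,
    cause_group: str = "all",
) -> PrehospitalModel:
    """Fit the random-effects meta-regression to study records.

    With no usable covariates this reduces to the standard
    DerSimonian-Laird random-effects pooled proportion on the logit scale.
    Covariates that are constant across the records are dropped with a
    warning (they would make the design singular).

    Parameters
    ----------
    records
        Study-level observations; at least one.
    region_map
        Maps each record's region to its super-region covariate level.
        When omitted, regions are treated as their own super-regions.
    """
    records = list(records)
    if not records:
        raise ValidationError("cannot fit a model with zero study records")

    y, v = _logit_outcomes(records)
    k = len(records)

    if region_map is None:
        supers = [rec.region for rec in records]
    else:
        supers = [region_map.super_region_of(rec.region) for rec in records]
    levels = sorted(set(supers))

    columns: list[np.ndarray] = [np.ones((k, 1))]
    names: list[str] = ["intercept"]

    region_levels: list[str] = []
    if use_region and len(levels) > 1:
        columns.append(_effects_columns(levels, supers))
        names.extend(f"region[{lev}]" for lev in levels[:-1])
        region_levels = levels
    elif use_region and len(levels) == 1 and k > 1:
        pass  # single level: the intercept already carries it

    sex_codes = np.array([_SEX_CODE[rec.sex] for rec in records])
    if use_sex and len(np.unique(sex_codes)) == 1 and sex_codes[0] != 0.0:
        warnings.warn(
            "sex covariate is constant across studies; dropped from the "
            "design",
            stacklevel=2,
        )
    use_sex = use_sex and len(np.unique(sex_codes)) > 1
    if use_sex:
        columns.append(sex_codes[:, None])
        names.append("sex")

    ages = np.array([rec.age_mid for rec in records], dtype=float)
    age_center = float(ages.mean())
    use_age = use_age and len(np.unique(ages)) > 1
    if use_age:
        columns.append((ages - age_center)[:, None])
        names.append("age")

    X = np.hstack(columns)
    p = X.shape[1]
    if p > k:
        warnings.warn(
            "more coefficients than studies; dropping covariates and "
            "fitting the pooled intercept only",
            stacklevel=2,
        )
        return fit_prehospital_model(
            records, region_map,
            use_region=False, use_sex=False, use_age=False,
            cause_group=cause_group,
        )

    beta, tau2 = _dl_meta_regression(X, y, v)

    coef = dict(zip(names, beta))
    offsets: dict[str, float] = {}
    if region_levels:
        partial = [coef[f"region[{lev}]"] for lev in region_levels[:-1]]
        offsets = dict(zip(region_levels[:-1], partial))
        offsets[region_levels[-1]] = -float(np.sum(partial))

    return PrehospitalModel(
        intercept=float(coef["intercept"]),
        region_offsets=offsets,
        sex_effect=float(coef.get("sex", 0.0)),
        age_slope=float(coef.get("age", 0.0)),
        age_center=age_center if use_age else 0.0,
        tau2=float(tau2),
        cause_group=cause_group,
        n_studies=k,
    )


def _dl_meta_regression(
    X: np.ndarray, y: np.ndarray, v: np.ndarray
) -> tuple[np.ndarray, float]:
    """Weighted least squares with DerSimonian-Laird moment heterogeneity.

    Fixed-effect WLS gives the residual Q statistic; the moment estimator
    tau2 = max(0, (Q - df) / tr(P)) with P the weighted projection
    complement generalises the scalar DL formula to a regression design.
    A second WLS pass with weights 1/(v + tau2) yields the coefficients.
    """
    k, p = X.shape
    w = 1.0 / v

    def wls(weights: np.ndarray) -> np.ndarray:
        XtW = X.T * weights
        return np.linalg.solve(XtW @ X, XtW @ y)

    beta_fe = wls(w)
    resid = y - X @ beta_fe
    q = float(np.sum(w * resid**2))
    df = k - p
    if df > 0:
        XtWX_inv = np.linalg.inv((X.T * w) @ X)
        trace_correction = float(np.trace(XtWX_inv @ ((X.T * w**2) @ X)))
        denom = float(np.sum(w)) - trace_correction
        tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    else:
        tau2 = 0.0

    beta = wls(1.0 / (v + tau2))
    return beta, tau2


@dataclass(frozen=True)
class PrehospitalPredictor:
    """Dispatch between cause-specific models and an all-injury fallback.

    Pooling is cause-specific wherever enough studies report that cause
    group (``min_cause_records``); causes without their own model use the
    all-injury pool.
    """

    models: Mapping[str, PrehospitalModel]
    fallback: PrehospitalModel

    def model_for(self, cause_group: str) -> PrehospitalModel:
        return self.models.get(cause_group, self.fallback)

    def predict(
        self,
        super_region: str | None,
        sex: str = "both",
        age_mid: float | None = None,
        cause_group: str = "all",
    ) -> float:
        return self.model_for(cause_group).predict(super_region, sex, age_mid)

    def prediction_table(
        self,
        super_regions: Iterable[str],
        sexes: Iterable[str] = ("male", "female"),
        cause_groups: Iterable[str] = ("all",),
    ) -> pd.DataFrame:
        """Long-format predictions with columns region/sex[/category]/pi."""
        rows = []
        for cg in cause_groups:
            for sr in super_regions:
                for sex in sexes:
                    rows.append(
                        {
                            "region": sr,
                            "sex": sex,
                            "cause_group": cg,
                            "pi": self.predict(sr, sex, cause_group=cg),
                        }
                    )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "fallback": self.fallback.summary(),
            "cause_specific": {cg: m.summary() for cg, m in self.models.items()},
        }


def fit_prehospital_models(
    records: Sequence[StudyRecord],
    region_map: RegionMap | None = None,
    *,
    min_cause_records: int = 3,
) -> PrehospitalPredictor:
    """Fit the all-injury pool plus cause-specific models where supported."""
    records = list(records)
    fallback = fit_prehospital_model(records, region_map, cause_group="all")
    by_cause: dict[str, list[StudyRecord]] = {}
    for rec in records:
        if rec.cause_group != "all":
            by_cause.setdefault(rec.cause_group, []).append(rec)
    models = {
        cg: fit_prehospital_model(recs, region_map, cause_group=cg)
        for cg, recs in by_cause.items()
        if len(recs) >= min_cause_records
    }
    return PrehospitalPredictor(models=models, fallback=fallback)
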