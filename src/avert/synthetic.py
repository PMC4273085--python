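"""Synthetic burden-of-disease input bundles with known ground truth.

The generator emulates the statistical structure of stratified global
burden-of-disease extracts so every pipeline stage is testable without
any external data:

* in-hospital case fatality varies across regions through multiplicative
  "care gap" factors gamma_r >= 1, with one designated best region at
  gamma = 1 — so the element-wise cross-region minimum is attained by a
  known region and the true counterfactual is available in closed form;
* prehospital-death proportions are logit-normal across super-regions
  with a fixed male-female contrast, and study records are binomial draws
  around the true proportions (estimation noise enters only where the
  real analysis had an estimation step);
* YLD per incident case varies by region through factors delta_r >= 1
  (again best region at delta = 1);
* incident cases are allocated from external causes to natures of injury
  through row-stochastic matrices drawn from a symmetric Dirichlet.

Counts are expected values (continuous), not sampled: given the rates the
pipeline is deterministic, so sampling noise would only blur the
ground-truth comparison.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_model import (
    DEFAULT_NOT_AMENABLE,
    AmenabilityMap,
    BurdenTable,
    CauseNatureMatrix,
    LifeTable,
    RegionMap,
    ValidationError,
    write_burden_table,
)
from .prehospital import StudyRecord

__all__ = [
    "DEFAULT_CAUSES",
    "DEFAULT_NATURES",
    "SyntheticConfig",
    "SyntheticBundle",
    "generate_bundle",
    "simulate_study_records",
    "ground_truth_check",
    "RecoveryReport",
]

#: External causes: six surgically amenable, five not.
DEFAULT_CAUSES = (
    "road_injury",
    "other_transport",
    "falls",
    "fire_heat_hot_substances",
    "unintentional_other",
    "interpersonal_violence",
    "self_harm",
    "poisoning",
    "drowning",
    "venomous_animal_contact",
    "intentional_other",
)

#: Nature-of-injury categories (condensed from the usual 23-way list).
DEFAULT_NATURES = (
    "fracture",
    "dislocation",
    "soft_tissue_injury",
    "traumatic_brain_injury",
    "internal_injury",
    "open_wound",
    "burn",
    "crush_injury",
    "spinal_cord_lesion",
    "other_nature",
)

_SEXES = ("male", "female")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters for a synthetic input bundle.

    Defaults mirror the structure of the real analysis: 21 epidemiologic
    regions in 7 super-regions, broad age bands keyed by lower bound with
    a standard life table, care-gap factors up to 3-fold, prehospital
    proportions centred near 45% with a male excess, and up to 2-fold
    regional variation in YLD per case.
    """

    n_regions: int = 21
    n_super_regions: int = 7
    age_groups: tuple[str, ...] = ("0", "5", "15", "30", "45", "60")
    life_expectancy: tuple[float, ...] = (86.0, 81.4, 71.5, 56.7, 42.2, 27.8)
    causes: tuple[str, ...] = DEFAULT_CAUSES
    natures: tuple[str, ...] = DEFAULT_NATURES
    not_amenable: frozenset[str] = DEFAULT_NOT_AMENABLE
    base_incidence: float = 10_000.0
    base_inhosp_cfr: float = 0.05
    #: age-profile multipliers on the in-hospital CFR (len == age_groups)
    cfr_age_factors: tuple[float, ...] | None = (0.8, 0.5, 1.0, 1.1, 1.4, 2.0)
    #: male/female multipliers on the in-hospital CFR
    cfr_sex_factors: tuple[float, float] = (1.15, 0.9)
    #: per-cause multipliers (defaults drawn from the seed if None)
    cfr_cause_factors: Mapping[str, float] | None = None
    #: care-gap factors gamma_r; drawn U(1, care_gap_max) if None,
    #: region 0 always forced to gamma = 1 (the best region)
    care_gap: tuple[float, ...] | None = None
    care_gap_max: float = 3.0
    prehosp_logit_mean: float = -0.2
    prehosp_tau: float = 0.3
    prehosp_sex_gap: float = 0.25
    base_yld_per_case: float = 0.6
    yld_gap: tuple[float, ...] | None = None
    yld_gap_max: float = 2.0
    matrix_concentration: float = 5.0
    #: share of incident cases carried by surgically amenable causes;
    #: amenable mechanisms dominate injury burden, and keeping their share
    #: well above the maximum avertable fraction guarantees the avertable
    #: YLD pool always fits inside the amenable causes it is allocated to
    amenable_incidence_share: float = 0.8
    n_studies_per_stratum: int = 8
    study_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < self.n_super_regions:
            raise ValidationError("need at least one region per super-region")
        if len(self.life_expectancy) != len(self.age_groups):
            raise ValidationError("life_expectancy must match age_groups")
        if self.care_gap is not None and any(g < 1 for g in self.care_gap):
            raise ValidationError("care-gap factors must be >= 1")
        if self.yld_gap is not None and any(d < 1 for d in self.yld_gap):
            raise ValidationError("YLD-gap factors must be >= 1")


@dataclass(frozen=True)
class SyntheticBundle:
    """A complete generated input set plus its analytic ground truth.

    ``ground_truth`` holds frames keyed like pipeline outputs:
    ``fatal`` (region x cause avertable deaths/YLL), ``nonfatal_region``
    (region-level YLD totals and avertable fraction), ``yld_by_cause``
    (region x cause avertable YLD after proportional allocation) and a
    ``totals`` dict.
    """

    config: SyntheticConfig
    cause_table: BurdenTable
    nature_table: BurdenTable
    life_table: LifeTable
    region_map: RegionMap
    amenability: AmenabilityMap
    matrices: CauseNatureMatrix = field(repr=False)
    true_prehospital: pd.DataFrame = field(repr=False)
    study_records: tuple[StudyRecord, ...] = field(repr=False)
    ground_truth: dict = field(repr=False)

    def write(self, out_dir: str | Path) -> None:
        """Write the bundle as the CSV/JSON schema the pipeline reads."""
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_burden_table(self.cause_table, out / "burden_by_cause.csv")
        write_burden_table(self.nature_table, out / "burden_by_nature.csv")
        self.life_table.to_frame().to_csv(out / "life_table.csv", index=False)
        pd.DataFrame(
            {"region": self.region_map.regions,
             "super_region": [self.region_map.super_region_of(r)
                              for r in self.region_map.regions]}
        ).to_csv(out / "region_map.csv", index=False)
        self.true_prehospital.to_csv(out / "true_prehospital.csv", index=False)
        pd.DataFrame([r.__dict__ for r in self.study_records]).to_csv(
            out / "study_records.csv", index=False
        )
        truth = {
            k: (v.to_dict("records") if isinstance(v, pd.DataFrame) else v)
            for k, v in self.ground_truth.items()
        }
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))


def _region_labels(n: int) -> list[str]:
    return [f"region_{i + 1:02d}" for i in range(n)]


def _super_labels(n: int) -> list[str]:
    return [f"super_{i + 1}" for i in range(n)]


def simulate_study_records(
    n_studies: int,
    logit_mean: float,
    tau: float,
    *,
    study_size: int = 200,
    region: str = "region_01",
    seed: int = 0,
) -> list[StudyRecord]:
    """Study records with true logit-normal heterogeneity, for exercising
    the meta-regression on its own (single region, no covariates)."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_studies):
        p = float(expit(logit_mean + tau * rng.standard_normal()))
        events = int(rng.binomial(study_size, p))
        records.append(
            StudyRecord(
                events=events, total=study_size, region=region,
                source_id=f"sim_{i}",
            )
        )
    return records


def generate_bundle(config: SyntheticConfig | None = None) -> SyntheticBundle:
    """Generate a complete input bundle and its closed-form ground truth.

    Fixing the seed makes the bundle reproducible bit-for-bit.  Raises if
    the configured factors would push any observed case-fatality rate to
    one or beyond.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)

    regions = _region_labels(config.n_regions)
    supers = _super_labels(config.n_super_regions)
    # contiguous blocks of regions per super-region
    super_of = {
        r: supers[min(i * config.n_super_regions // config.n_regions,
                      config.n_super_regions - 1)]
        for i, r in enumerate(regions)
    }
    region_map = RegionMap(super_of)
    amenability = AmenabilityMap(config.not_amenable)
    life_table = LifeTable(
        config.age_groups,
        dict(zip(config.age_groups, config.life_expectancy)),
    )

    n_age = len(config.age_groups)
    n_cause = len(config.causes)
    n_nature = len(config.natures)
    n_reg = config.n_regions

    # --- regional gap factors -------------------------------------------
    if config.care_gap is not None:
        gamma = np.asarray(config.care_gap, dtype=float)
        if len(gamma) != n_reg:
            raise ValidationError("care_gap length must equal n_regions")
    else:
        gamma = rng.uniform(1.0, config.care_gap_max, n_reg)
        gamma[0] = 1.0
    if config.yld_gap is not None:
        delta = np.asarray(config.yld_gap, dtype=float)
        if len(delta) != n_reg:
            raise ValidationError("yld_gap length must equal n_regions")
    else:
        delta = rng.uniform(1.0, config.yld_gap_max, n_reg)
        delta[0] = 1.0

    # --- stratum weights for incidence ----------------------------------
    age_w = np.array([1.2, 1.0, 1.6, 1.3, 1.0, 0.9])[:n_age] if n_age <= 6 else (
        rng.lognormal(0.0, 0.3, n_age)
    )
    if len(age_w) != n_age:
        age_w = rng.lognormal(0.0, 0.3, n_age)
    sex_w = np.array([1.3, 1.0])
    cause_w = rng.lognormal(0.0, 0.5, n_cause)
    amenable_mask = np.array(
        [amenability.is_amenable(c) for c in config.causes]
    )
    if amenable_mask.any() and (~amenable_mask).any():
        share = config.amenable_incidence_share
        cause_w[amenable_mask] *= share / cause_w[amenable_mask].sum()
        cause_w[~amenable_mask] *= (1 - share) / cause_w[~amenable_mask].sum()
    region_w = rng.lognormal(0.0, 0.4, n_reg)

    # incidence[i, j, r, c]
    N = (
        config.base_incidence
        * age_w[:, None, None, None]
        * sex_w[None, :, None, None]
        * region_w[None, None, :, None]
        * cause_w[None, None, None, :]
    )

    # --- in-hospital CFR and prehospital proportions --------------------
    if config.cfr_age_factors is None:
        cfr_age = np.ones(n_age)
    else:
        cfr_age = np.asarray(config.cfr_age_factors, dtype=float)
        if len(cfr_age) != n_age:
            raise ValidationError("cfr_age_factors must match age_groups")
    cfr_sex = np.asarray(config.cfr_sex_factors, dtype=float)
    if config.cfr_cause_factors is None:
        cfr_cause = rng.lognormal(0.0, 0.3, n_cause)
    else:
        cfr_cause = np.array(
            [config.cfr_cause_factors.get(c, 1.0) for c in config.causes]
        )

    # h[i, j, r, c]: in-hospital CFR among arrivals
    h = (
        config.base_inhosp_cfr
        * cfr_age[:, None, None, None]
        * cfr_sex[None, :, None, None]
        * gamma[None, None, :, None]
        * cfr_cause[None, None, None, :]
    )

    b_super = rng.normal(0.0, config.prehosp_tau, config.n_super_regions)
    sex_code = np.array([0.5, -0.5])
    # pi[k, j]
    pi_super = expit(
        config.prehosp_logit_mean
        + config.prehosp_sex_gap * sex_code[None, :]
        + b_super[:, None]
    )
    super_index = np.array([supers.index(super_of[r]) for r in regions])
    pi_region = pi_super[super_index, :]  # [r, j]

    # observed CFR[i, j, r, c] = h / (1 - pi * (1 - h))
    pi_b = pi_region.T[None, :, :, None]  # broadcast to [i, j, r, c]
    cfr = h / (1.0 - pi_b * (1.0 - h))
    if np.any(cfr >= 1.0):
        raise ValidationError(
            "configuration produces case-fatality rates >= 1; reduce "
            "base_inhosp_cfr, the factor profiles, or care_gap_max"
        )

    deaths = N * cfr
    life = np.asarray(config.life_expectancy, dtype=float)
    yll = deaths * life[:, None, None, None]

    # --- cause-nature matrices and nonfatal burden ----------------------
    matrices: dict[tuple[str, str], pd.DataFrame] = {}
    M = np.empty((n_age, 2, n_cause, n_nature))
    for i in range(n_age):
        for j in range(2):
            M[i, j] = rng.dirichlet(
                np.full(n_nature, config.matrix_concentration), size=n_cause
            )
            matrices[(config.age_groups[i], _SEXES[j])] = pd.DataFrame(
                M[i, j], index=list(config.causes), columns=list(config.natures)
            )
    matrix_obj = CauseNatureMatrix(matrices)

    # nature cases[i, j, r, n] = sum_c N * M
    C = np.einsum("ijrc,ijcn->ijrn", N, M)
    nature_w = rng.lognormal(0.0, 0.4, n_nature)
    # ypc[i, j, r, n]: YLD per case warranting care
    ypc_base = config.base_yld_per_case * nature_w[None, None, None, :] * np.ones(
        (n_age, 2, 1, 1)
    )
    ypc = ypc_base * delta[None, None, :, None]
    yld_nature = C * ypc

    # cause-level YLD consistent with the matrices:
    # yld_cause[i,j,r,c] = N[c] * sum_n M[c,n] * ypc[n]
    yld_cause = N * np.einsum("ijcn,ijrn->ijrc", M, ypc)

    # --- long-format tables ---------------------------------------------
    idx_cause = pd.MultiIndex.from_product(
        [config.age_groups, _SEXES, regions, config.causes],
        names=["age_group", "sex", "region", "category"],
    )
    cause_df = pd.DataFrame(
        {
            "cases": N.reshape(-1),
            "deaths": deaths.reshape(-1),
            "yll": yll.reshape(-1),
            "yld": yld_cause.reshape(-1),
        },
        index=idx_cause,
    ).reset_index()
    cause_table = BurdenTable(cause_df, "cause")

    idx_nature = pd.MultiIndex.from_product(
        [config.age_groups, _SEXES, regions, config.natures],
        names=["age_group", "sex", "region", "category"],
    )
    nature_df = pd.DataFrame(
        {"cases": C.reshape(-1), "yld": yld_nature.reshape(-1)},
        index=idx_nature,
    ).reset_index()
    nature_table = BurdenTable(nature_df, "nature")

    true_pi = pd.DataFrame(
        [
            {"region": r, "sex": s, "pi": float(pi_region[ri, j])}
            for ri, r in enumerate(regions)
            for j, s in enumerate(_SEXES)
        ]
    )

    # --- study records ---------------------------------------------------
    records: list[StudyRecord] = []
    for k, sr in enumerate(supers):
        members = [r for r in regions if super_of[r] == sr]
        for j, sex in enumerate(_SEXES):
            for s in range(config.n_studies_per_stratum):
                region = members[s % len(members)]
                p = float(pi_super[k, j])
                events = int(rng.binomial(config.study_size, p))
                records.append(
                    StudyRecord(
                        events=events,
                        total=config.study_size,
                        region=region,
                        sex=sex,
                        age_mid=float(rng.uniform(20.0, 60.0)),
                        source_id=f"{sr}_{sex}_{s}",
                    )
                )

    ground_truth = _closed_form_truth(
        config, supers, super_index, amenability,
        N, cfr, pi_region, h, life, C, ypc, ypc_base, yld_cause,
    )

    return SyntheticBundle(
        config=config,
        cause_table=cause_table,
        nature_table=nature_table,
        life_table=life_table,
        region_map=region_map,
        amenability=amenability,
        matrices=matrix_obj,
        true_prehospital=true_pi,
        study_records=tuple(records),
        ground_truth=ground_truth,
    )


def _closed_form_truth(
    config: SyntheticConfig,
    supers: list[str],
    super_index: np.ndarray,
    amenability: AmenabilityMap,
    N: np.ndarray,
    cfr: np.ndarray,
    pi_region: np.ndarray,
    h: np.ndarray,
    life: np.ndarray,
    C: np.ndarray,
    ypc: np.ndarray,
    ypc_base: np.ndarray,
    yld_cause: np.ndarray,
) -> dict:
    """Ground-truth avertable burden straight from the generating rates.

    Fatal: per (age, sex, super-region, cause) the aggregate CFR is the
    case-weighted mean over member regions; the prehospital proportion is
    shared within a super-region, so the aggregate prehospital death rate
    is CFR * pi; the counterfactual in-hospital rate is the best region's
    h (gamma = 1 by construction).  Nonfatal: the avertable fraction per
    super-region follows from delta, and the cause allocation applies the
    proportional rule with cap-and-respread as an explicit loop.
    """
    n_super = config.n_super_regions
    deaths = N * cfr

    fatal_rows = []
    yld_region_rows = []
    alloc_rows = []

    amenable = np.array([amenability.is_amenable(c) for c in config.causes])

    for k, sr in enumerate(supers):
        members = super_index == k
        Nk = N[:, :, members, :].sum(axis=2)  # [i, j, c]
        Dk = deaths[:, :, members, :].sum(axis=2)
        with np.errstate(invalid="ignore"):
            cfr_k = np.where(Nk > 0, Dk / Nk, 0.0)
        pi_k = pi_region[members, :][0]  # constant within super-region
        d_k = cfr_k * pi_k[None, :, None]
        h_star = h[:, :, 0, :]  # region 0 is the designated best region
        cfr_prime = d_k + (1.0 - d_k) * h_star
        cfr_prime = np.minimum(cfr_prime, cfr_k)
        deaths_avert = Nk * (cfr_k - cfr_prime)
        deaths_avert[:, :, ~amenable] = 0.0
        yll_avert = deaths_avert * life[:, None, None]
        for c_i, cause in enumerate(config.causes):
            fatal_rows.append(
                {
                    "region": sr,
                    "category": cause,
                    "deaths_observed": float(Dk[:, :, c_i].sum()),
                    "deaths_avertable": float(deaths_avert[:, :, c_i].sum()),
                    "yll_avertable": float(yll_avert[:, :, c_i].sum()),
                }
            )

        # nonfatal: nature-level totals and avertable fraction
        obs_yld = float((C[:, :, members, :] * ypc[:, :, members, :]).sum())
        cf_yld = float((C[:, :, members, :] * ypc_base).sum())
        fraction = 0.0 if obs_yld == 0 else (obs_yld - cf_yld) / obs_yld
        yld_region_rows.append(
            {
                "region": sr,
                "yld_observed": obs_yld,
                "yld_counterfactual": cf_yld,
                "fraction": fraction,
            }
        )

        # proportional allocation to amenable causes with cap-and-respread
        cause_obs = yld_cause[:, :, members, :].sum(axis=(0, 1, 2))  # [c]
        pool = fraction * float(cause_obs.sum())
        alloc = np.zeros(len(config.causes))
        open_idx = [i for i in range(len(config.causes))
                    if amenable[i] and cause_obs[i] > 0]
        remaining = pool
        while remaining > 1e-12 and open_idx:
            weights = cause_obs[open_idx]
            share = remaining * weights / weights.sum()
            head = cause_obs[open_idx] - alloc[open_idx]
            over = share > head + 1e-12
            if not over.any():
                alloc[open_idx] += share
                remaining = 0.0
                break
            capped = [i for i, o in zip(open_idx, over) if o]
            alloc[capped] = cause_obs[capped]
            remaining -= float(
                sum(head[m] for m, o in enumerate(over) if o)
            )
            open_idx = [i for i, o in zip(open_idx, over) if not o]
        for c_i, cause in enumerate(config.causes):
            alloc_rows.append(
                {
                    "region": sr,
                    "category": cause,
                    "yld_observed": float(cause_obs[c_i]),
                    "yld_avertable": float(alloc[c_i]),
                }
            )

    fatal = pd.DataFrame(fatal_rows)
    nonfatal_region = pd.DataFrame(yld_region_rows)
    yld_by_cause = pd.DataFrame(alloc_rows)
    totals = {
        "deaths_avertable": float(fatal["deaths_avertable"].sum()),
        "yll_avertable": float(fatal["yll_avertable"].sum()),
        "yld_avertable": float(yld_by_cause["yld_avertable"].sum()),
    }
    totals["daly_avertable"] = totals["yll_avertable"] + totals["yld_avertable"]
    return {
        "fatal": fatal,
        "nonfatal_region": nonfatal_region,
        "yld_by_cause": yld_by_cause,
        "totals": totals,
    }


@dataclass(frozen=True)
class RecoveryReport:
    """Relative errors of a pipeline run against bundle ground truth."""

    max_relative_error: float
    relative_errors: dict[str, float]
    tolerance: float

    @property
    def passed(self) -> bool:
        return self.max_relative_error < self.tolerance


def _rel_err(estimate: float, truth: float) -> float:
    if truth == 0:
        return abs(estimate)
    return abs(estimate - truth) / abs(truth)


def ground_truth_check(
    bundle: SyntheticBundle,
    result,
    *,
    tolerance: float = 1e-6,
) -> RecoveryReport:
    """Compare an :class:`~avert.reporting.AvertableResult` with the
    bundle's analytic ground truth.

    Compares total avertable deaths, YLL, YLD and DALY plus per-region
    avertable deaths.  With the meta-model bypassed (true prehospital
    proportions) errors should be at numerical noise; with fitted
    proportions they reflect sampling noise in the study records.
    """
    truth = bundle.ground_truth
    errors: dict[str, float] = {}
    totals = result.totals("avertable")
    for key in ("deaths", "yll", "yld", "daly"):
        errors[f"total_{key}"] = _rel_err(
            totals[key], truth["totals"][f"{key}_avertable"]
        )
    est_region = result.by_region().set_index("region")["deaths_avertable"]
    true_region = (
        truth["fatal"].groupby("region")["deaths_avertable"].sum()
    )
    for region in true_region.index:
        errors[f"deaths_{region}"] = _rel_err(
            float(est_region.get(region, 0.0)), float(true_region[region])
        )
    max_err = max(errors.values())
    return RecoveryReport(
        max_relative_error=max_err, relative_errors=errors, tolerance=tolerance
    )
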