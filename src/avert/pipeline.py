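"""End-to-end orchestration: inputs -> avertable burden result.

Thin glue over the stage modules: fit (or bypass) the prehospital model,
build counterfactual case-fatality rates and fatal burden, build the
nonfatal counterfactual and reallocate YLDs to causes, then assemble
DALYs.  Inputs can come from a :class:`~avert.synthetic.SyntheticBundle`
or from a directory of CSV files following the same schema the bundle
writer produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .counterfactual_fatal import (
    avertable_fatal,
    counterfactual_cfr,
    counterfactual_deaths,
    counterfactual_yll,
)
from .counterfactual_nonfatal import (
    allocate_ylds_to_causes,
    avertable_fraction_by_region,
    counterfactual_yld_nature,
    lowest_yld_per_case,
    yld_per_case_surface,
)
from .data_model import (
    AmenabilityMap,
    BurdenTable,
    LifeTable,
    RegionMap,
    ValidationError,
    read_burden_table,
)
from .prehospital import StudyRecord, fit_prehospital_models, read_study_records
from .reporting import AvertableResult, assemble_dalys

__all__ = ["PipelineInputs", "PipelineOutput", "run_pipeline"]


@dataclass(frozen=True)
class PipelineInputs:
    """Everything one analysis run consumes.

    Exactly one of ``true_prehospital`` (a frame of proportions, used
    as-is) or ``study_records`` (fed to the meta-regression) must provide
    the prehospital information unless the caller selects the mode
    explicitly.
    """

    cause_table: BurdenTable
    nature_table: BurdenTable
    life_table: LifeTable
    region_map: RegionMap
    amenability: AmenabilityMap = field(default_factory=AmenabilityMap)
    true_prehospital: pd.DataFrame | None = None
    study_records: tuple[StudyRecord, ...] = ()

    @classmethod
    def from_bundle(cls, bundle) -> "PipelineInputs":
        return cls(
            cause_table=bundle.cause_table,
            nature_table=bundle.nature_table,
            life_table=bundle.life_table,
            region_map=bundle.region_map,
            amenability=bundle.amenability,
            true_prehospital=bundle.true_prehospital,
            study_records=tuple(bundle.study_records),
        )

    @classmethod
    def from_dir(cls, path: str | Path) -> "PipelineInputs":
        path = Path(path)
        region_df = pd.read_csv(path / "region_map.csv")
        region_map = RegionMap(
            dict(zip(region_df["region"], region_df["super_region"]))
        )
        amen_path = path / "amenability.yaml"
        amenability = (
            AmenabilityMap.from_yaml(amen_path)
            if amen_path.exists()
            else AmenabilityMap.default()
        )
        pi_path = path / "true_prehospital.csv"
        rec_path = path / "study_records.csv"
        return cls(
            cause_table=read_burden_table(path / "burden_by_cause.csv", "cause"),
            nature_table=read_burden_table(path / "burden_by_nature.csv", "nature"),
            life_table=LifeTable.from_csv(path / "life_table.csv"),
            region_map=region_map,
            amenability=amenability,
            true_prehospital=pd.read_csv(pi_path) if pi_path.exists() else None,
            study_records=tuple(read_study_records(rec_path))
            if rec_path.exists()
            else (),
        )


@dataclass(frozen=True)
class PipelineOutput:
    result: AvertableResult
    fractions: pd.DataFrame = field(repr=False)
    cfr_detail: pd.DataFrame = field(repr=False)
    prehospital: pd.DataFrame = field(repr=False)
    model_summary: dict | None = None


def _prehospital_table(
    inputs: PipelineInputs, mode: str
) -> tuple[pd.DataFrame, dict | None]:
    if mode == "true":
        if inputs.true_prehospital is None:
            raise ValidationError(
                "prehospital mode 'true' requires a table of proportions"
            )
        return inputs.true_prehospital, None
    if mode == "fit":
        if not inputs.study_records:
            raise ValidationError(
                "prehospital mode 'fit' requires study records"
            )
        predictor = fit_prehospital_models(
            inputs.study_records, inputs.region_map
        )
        regions = inputs.cause_table.regions()
        rows = []
        for region in regions:
            sr = inputs.region_map.super_region_of(region)
            for sex in ("male", "female"):
                rows.append(
                    {
                        "region": region,
                        "sex": sex,
                        "pi": predictor.predict(sr, sex),
                    }
                )
        return pd.DataFrame(rows), predictor.summary()
    raise ValidationError(f"unknown prehospital mode {mode!r}")


def run_pipeline(
    inputs: PipelineInputs,
    *,
    prehospital_mode: str = "fit",
    yld_granularity: str = "region",
) -> PipelineOutput:
    """Run the full avertable-burden decomposition.

    Parameters
    ----------
    prehospital_mode
        ``"fit"`` pools the study records through the meta-regression;
        ``"true"`` bypasses estimation and uses the supplied proportions
        directly (exact-recovery checks on synthetic data).
    yld_granularity
        Granularity of the avertable-YLD fraction; the default one
        fraction per super-region gives every amenable cause in a region
        the same avertable-YLD share.
    """
    pi, model_summary = _prehospital_table(inputs, prehospital_mode)

    # fatal side
    keys = ["age_group", "sex", "region", "category"]
    cfr_det = counterfactual_cfr(inputs.cause_table, pi, inputs.region_map)
    cf = counterfactual_deaths(
        cfr_det[keys + ["cases"]], cfr_det[keys + ["cfr_prime"]]
    )
    cf = counterfactual_yll(cf, inputs.life_table)
    fatal = avertable_fatal(
        inputs.cause_table, cf, inputs.amenability, region_map=inputs.region_map
    )

    # nonfatal side
    surface = yld_per_case_surface(inputs.nature_table)
    lowest = lowest_yld_per_case(surface)
    nature_cf = counterfactual_yld_nature(surface, lowest, inputs.region_map)
    fractions = avertable_fraction_by_region(
        nature_cf, granularity=yld_granularity
    )
    nonfatal = allocate_ylds_to_causes(
        fractions,
        inputs.cause_table,
        inputs.amenability,
        region_map=inputs.region_map,
    )

    result = assemble_dalys(fatal, nonfatal)
    return PipelineOutput(
        result=result,
        fractions=fractions,
        cfr_detail=cfr_det,
        prehospital=pi,
        model_summary=model_summary,
    )
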