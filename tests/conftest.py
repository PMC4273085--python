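import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from avert import (
    BurdenTable,
    PipelineInputs,
    RegionMap,
    SyntheticConfig,
    generate_bundle,
    run_pipeline,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle (21 regions, 7 super-regions, seed 0)."""
    return generate_bundle(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def bypass_output(bundle):
    """Pipeline run on the default bundle with true prehospital proportions."""
    return run_pipeline(
        PipelineInputs.from_bundle(bundle), prehospital_mode="true"
    )


@pytest.fixture()
def toy_cause_table():
    """Two regions, one age/sex cell, one cause: target has a 4x CFR gap."""
    df = pd.DataFrame(
        {
            "age_group": ["30", "30"],
            "sex": ["male", "male"],
            "region": ["target", "best"],
            "category": ["road_injury", "road_injury"],
            "cases": [1000.0, 1000.0],
            "deaths": [200.0, 50.0],
            "yll": [200.0 * 56.7, 50.0 * 56.7],
            "yld": [100.0, 100.0],
        }
    )
    return BurdenTable(df, "cause")


@pytest.fixture()
def identity_map():
    return RegionMap.identity(["target", "best"])
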