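"""Counterfactual YLDs and proportional reallocation to causes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from avert import (
    AmenabilityMap,
    BurdenTable,
    RegionMap,
    ValidationError,
    allocate_ylds_to_causes,
    avertable_fraction_by_region,
    counterfactual_yld_nature,
    lowest_yld_per_case,
    yld_per_case_surface,
)


def _surface(per_case_by_region, cases=100.0, nature="fracture"):
    rows = []
    for region, ypc in per_case_by_region.items():
        rows.append(
            {"age_group": "30", "sex": "male", "region": region,
             "category": nature, "cases": cases, "yld": cases * ypc}
        )
    df = pd.DataFrame(rows)
    return yld_per_case_surface(BurdenTable(df, "nature"))


class TestLowestYldPerCase:
    def test_minimum_of_three_regions(self):
        low = lowest_yld_per_case(_surface({"a": 0.8, "b": 0.5, "c": 1.1}))
        assert low["yld_per_case_lowest"].iloc[0] == pytest.approx(0.5)

    def test_single_region_is_its_own_minimum(self):
        low = lowest_yld_per_case(_surface({"a": 0.8}))
        assert low["yld_per_case_lowest"].iloc[0] == pytest.approx(0.8)

    def test_random_surface_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(5)
        rows = []
        for region in [f"r{i}" for i in range(5)]:
            for age in ("0", "30"):
                for nature in ("fracture", "burn"):
                    cases = rng.uniform(10, 100)
                    rows.append(
                        {"age_group": age, "sex": "male", "region": region,
                         "category": nature, "cases": cases,
                         "yld": cases * rng.uniform(0.1, 2.0)}
                    )
        surface = yld_per_case_surface(BurdenTable(pd.DataFrame(rows), "nature"))
        low = lowest_yld_per_case(surface).set_index(
            ["age_group", "sex", "category"]
        )
        for key, grp in surface.groupby(["age_group", "sex", "category"]):
            expected = min(grp["yld_per_case"])
            assert low.loc[key, "yld_per_case_lowest"] == pytest.approx(
                expected, rel=1e-12
            )

    def test_care_warranting_flag_excludes_natures(self):
        df = pd.DataFrame(
            {"age_group": ["30", "30"], "sex": ["male", "male"],
             "region": ["a", "a"], "category": ["fracture", "bruise"],
             "cases": [10.0, 10.0], "yld": [5.0, 1.0]}
        )
        surface = yld_per_case_surface(
            BurdenTable(df, "nature"), care_warranting={"bruise": False}
        )
        assert set(surface["category"]) == {"fracture"}


class TestCounterfactualYld:
    def test_cases_times_lowest(self):
        surface = _surface({"a": 0.8, "b": 0.5}, cases=200.0)
        low = lowest_yld_per_case(surface)
        out = counterfactual_yld_nature(surface, low)
        row = out.set_index("region").loc["a"]
        assert row["yld_prime"] == pytest.approx(200.0 * 0.5)

    def test_minimum_region_keeps_observed_yld(self):
        surface = _surface({"a": 0.8, "b": 0.5})
        low = lowest_yld_per_case(surface)
        out = counterfactual_yld_nature(surface, low)
        row = out.set_index("region").loc["b"]
        assert row["yld_prime"] == pytest.approx(row["yld"], rel=1e-12)


class TestAvertableFraction:
    def test_simple_ratio(self):
        cf = pd.DataFrame(
            {"age_group": ["30"], "sex": ["male"], "region": ["s1"],
             "category": ["fracture"], "cases": [1.0],
             "yld": [1000.0], "yld_prime": [800.0]}
        )
        frac = avertable_fraction_by_region(cf)
        assert frac["fraction"].iloc[0] == pytest.approx(0.20)

    def test_no_gap_means_zero_fraction(self):
        cf = pd.DataFrame(
            {"age_group": ["30"], "sex": ["male"], "region": ["s1"],
             "category": ["fracture"], "cases": [1.0],
             "yld": [1000.0], "yld_prime": [1000.0]}
        )
        assert avertable_fraction_by_region(cf)["fraction"].iloc[0] == 0.0

    def test_zero_observed_warns_and_yields_zero(self):
        cf = pd.DataFrame(
            {"age_group": ["30"], "sex": ["male"], "region": ["s1"],
             "category": ["fracture"], "cases": [0.0],
             "yld": [0.0], "yld_prime": [0.0]}
        )
        with pytest.warns(UserWarning, match="zero observed"):
            frac = avertable_fraction_by_region(cf)
        assert frac["fraction"].iloc[0] == 0.0


def _fractions(region="s1", fraction=0.2):
    return pd.DataFrame(
        {"region": [region], "yld_observed": [1.0],
         "yld_counterfactual": [1.0 - fraction], "fraction": [fraction]}
    )


def _cause_frame(ylds, region="s1"):
    return pd.DataFrame(
        [
            {"age_group": "30", "sex": "male", "region": region,
             "category": cause, "yld": yld}
            for cause, yld in ylds.items()
        ]
    )


class TestAllocation:
    def test_hand_computed_proportional_split(self):
        """A=0.2 over {X:600, Y:300, drowning:100}: pool 200 goes 2:1 to
        X and Y; the non-amenable cause gets nothing."""
        out = allocate_ylds_to_causes(
            _fractions(fraction=0.2),
            _cause_frame({"X": 600.0, "Y": 300.0, "drowning": 100.0}),
            AmenabilityMap.default(),
        )
        alloc = out.set_index("category")["yld_avertable"]
        assert alloc["X"] == pytest.approx(200.0 * 600 / 900)
        assert alloc["Y"] == pytest.approx(200.0 * 300 / 900)
        assert alloc["drowning"] == 0.0

    def test_zero_fraction_allocates_nothing(self):
        out = allocate_ylds_to_causes(
            _fractions(fraction=0.0),
            _cause_frame({"X": 600.0, "Y": 300.0}),
            AmenabilityMap.default(),
        )
        assert (out["yld_avertable"] == 0.0).all()

    def test_amenable_causes_share_one_proportion(self):
        """Uncapped proportional allocation gives every amenable cause the
        same avertable-YLD share within a region."""
        out = allocate_ylds_to_causes(
            _fractions(fraction=0.15),
            _cause_frame({"X": 500.0, "Y": 250.0, "Z": 125.0}),
            AmenabilityMap.default(),
        )
        shares = out["yld_avertable"] / out["yld_observed"]
        assert shares.nunique() == 1 or np.allclose(shares, shares.iloc[0])

    def test_full_pool_saturates_at_observed(self):
        """When the pool equals the amenable total (the capping boundary)
        every amenable cause is fully averted and nothing is lost.  With
        allocation proportional to observed YLDs the cap can never be
        exceeded below this boundary — the per-cause share ratio is
        uniform — so the cap-and-respread pass is a pure safety net."""
        causes = {"X": 100.0, "Y": 1000.0, "drowning": 900.0}
        fraction = 0.55  # pool = 1100 == X + Y
        out = allocate_ylds_to_causes(
            _fractions(fraction=fraction),
            _cause_frame(causes),
            AmenabilityMap.default(),
        )
        alloc = out.set_index("category")["yld_avertable"]
        assert alloc["X"] == pytest.approx(100.0)
        assert alloc["Y"] == pytest.approx(1000.0)
        assert alloc["drowning"] == 0.0
        assert alloc.sum() == pytest.approx(fraction * sum(causes.values()))
        assert (out["yld_avertable"] <= out["yld_observed"] + 1e-9).all()

    def test_unallocatable_pool_raises(self):
        with pytest.raises(ValidationError, match="redistribute"):
            allocate_ylds_to_causes(
                _fractions(fraction=0.5),
                _cause_frame({"drowning": 900.0, "X": 100.0}),
                AmenabilityMap.default(),
            )

    @given(
        ylds=st.lists(st.floats(1.0, 1e6), min_size=2, max_size=6),
        fraction=st.floats(0.0, 0.4),
    )
    def test_conservation_property(self, ylds, fraction):
        causes = {f"c{i}": y for i, y in enumerate(ylds)}
        out = allocate_ylds_to_causes(
            _fractions(fraction=fraction),
            _cause_frame(causes),
            AmenabilityMap.default(),
        )
        pool = fraction * sum(ylds)
        assert out["yld_avertable"].sum() == pytest.approx(pool, rel=1e-9, abs=1e-9)


def test_shared_surface_across_regions_gives_zero_fraction():
    """If every region has the same YLD-per-case surface, nothing is
    avertable anywhere."""
    surface = _surface({"a": 0.7, "b": 0.7, "c": 0.7})
    low = lowest_yld_per_case(surface)
    cf = counterfactual_yld_nature(surface, low, RegionMap.identity(["a", "b", "c"]))
    frac = avertable_fraction_by_region(cf)
    assert (frac["fraction"] == 0.0).all()
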