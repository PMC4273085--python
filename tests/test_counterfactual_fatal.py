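"""Counterfactual case-fatality rates and avertable fatal burden."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from avert import (
    AmenabilityMap,
    BurdenTable,
    LifeTable,
    RegionMap,
    ValidationError,
    avertable_fatal,
    counterfactual_cfr,
    counterfactual_deaths,
    counterfactual_yll,
    decompose_cfr,
    recompose_cfr,
)

LIFE = LifeTable(("30",), {"30": 40.0})


class TestDecomposition:
    def test_direct_arithmetic(self):
        d, h = decompose_cfr(0.2, 0.5)
        assert d == pytest.approx(0.10)
        assert h == pytest.approx(0.10 / 0.90)

    def test_everyone_reaches_hospital_limit(self):
        d, h = decompose_cfr(0.3, 1e-9)
        assert d == pytest.approx(0.0, abs=1e-9)
        assert h == pytest.approx(0.3, abs=1e-8)

    def test_recomposition_roundtrip_on_grid(self):
        cfr = np.linspace(0.0, 0.999, 100)
        pi = np.linspace(0.001, 0.999, 100)
        C, P = np.meshgrid(cfr, pi)
        d, h = decompose_cfr(C.ravel(), P.ravel())
        back = recompose_cfr(d, h)
        assert np.max(np.abs(back - C.ravel())) < 1e-12

    @given(
        cfr=st.floats(0.0, 0.999),
        pi=st.floats(1e-6, 1.0 - 1e-6),
    )
    def test_components_stay_in_unit_interval(self, cfr, pi):
        d, h = decompose_cfr(cfr, pi)
        assert 0.0 <= d <= 1.0
        assert 0.0 <= h <= 1.0
        assert recompose_cfr(d, h) == pytest.approx(cfr, abs=1e-12)

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValidationError):
            decompose_cfr(1.5, 0.5)
        with pytest.raises(ValidationError):
            decompose_cfr(0.5, 1.0)


def _pi_frame(values):
    return pd.DataFrame(
        [{"region": r, "pi": p} for r, p in values.items()]
    )


class TestCounterfactualCFR:
    def test_two_region_hand_computation(self, toy_cause_table, identity_map):
        """Target cfr=0.2, best cfr=0.05, both pi=0.5:
        h* = 0.025/0.975, CFR' = 0.1 + 0.9*h* = 0.1230769..."""
        pi = _pi_frame({"target": 0.5, "best": 0.5})
        cf = counterfactual_cfr(toy_cause_table, pi, identity_map)
        row = cf.set_index("region").loc["target"]
        assert row["h_star"] == pytest.approx(0.025 / 0.975, rel=1e-12)
        assert row["cfr_prime"] == pytest.approx(
            0.1 + 0.9 * 0.025 / 0.975, rel=1e-12
        )

    def test_identical_regions_mean_no_care_gap(self, identity_map):
        df = pd.DataFrame(
            {
                "age_group": ["30", "30"],
                "sex": ["male", "male"],
                "region": ["target", "best"],
                "category": ["falls", "falls"],
                "cases": [1000.0, 500.0],
                "deaths": [200.0, 100.0],
                "yll": [1.0, 1.0],
                "yld": [0.0, 0.0],
            }
        )
        table = BurdenTable(df, "cause")
        pi = _pi_frame({"target": 0.4, "best": 0.4})
        cf = counterfactual_cfr(table, pi, identity_map)
        assert np.allclose(cf["cfr_prime"], cf["cfr"])

    def test_lowest_region_keeps_its_own_cfr(self, toy_cause_table, identity_map):
        pi = _pi_frame({"target": 0.5, "best": 0.5})
        cf = counterfactual_cfr(toy_cause_table, pi, identity_map)
        row = cf.set_index("region").loc["best"]
        assert row["cfr_prime"] == pytest.approx(row["cfr"], rel=1e-12)

    def test_single_region_cell_warns_and_equals_observed(self):
        df = pd.DataFrame(
            {
                "age_group": ["30"],
                "sex": ["male"],
                "region": ["only"],
                "category": ["falls"],
                "cases": [100.0],
                "deaths": [20.0],
                "yll": [800.0],
                "yld": [0.0],
            }
        )
        table = BurdenTable(df, "cause")
        with pytest.warns(UserWarning, match="single"):
            cf = counterfactual_cfr(
                table, _pi_frame({"only": 0.5}), RegionMap.identity(["only"])
            )
        assert cf["cfr_prime"].iloc[0] == pytest.approx(0.2)

    def test_counterfactual_never_exceeds_observed(self, bundle, bypass_output):
        cf = bypass_output.cfr_detail
        assert (cf["cfr_prime"] <= cf["cfr"] + 1e-12).all()
        assert (cf["cfr_prime"] >= cf["d"] - 1e-12).all()

    def test_avertable_monotone_in_target_prehospital_proportion(
        self, toy_cause_table, identity_map
    ):
        """Holding observed CFRs fixed, a larger prehospital share in the
        target region leaves less for surgical care to avert."""
        averts = []
        for pi_t in (0.1, 0.3, 0.5, 0.7, 0.9):
            pi = _pi_frame({"target": pi_t, "best": 0.5})
            cf = counterfactual_cfr(toy_cause_table, pi, identity_map)
            row = cf.set_index("region").loc["target"]
            averts.append(row["cfr"] - row["cfr_prime"])
        assert all(a >= b - 1e-12 for a, b in zip(averts, averts[1:]))
        # degenerate limit: everything prehospital => nothing avertable
        pi = _pi_frame({"target": 1 - 1e-9, "best": 0.5})
        cf = counterfactual_cfr(toy_cause_table, pi, identity_map)
        row = cf.set_index("region").loc["target"]
        assert row["cfr"] - row["cfr_prime"] == pytest.approx(0.0, abs=1e-6)

    def test_avertable_monotone_in_other_regions_care_quality(self, identity_map):
        averts = []
        for best_deaths in (150.0, 100.0, 50.0, 10.0):
            df = pd.DataFrame(
                {
                    "age_group": ["30", "30"],
                    "sex": ["male", "male"],
                    "region": ["target", "best"],
                    "category": ["road_injury", "road_injury"],
                    "cases": [1000.0, 1000.0],
                    "deaths": [200.0, best_deaths],
                    "yll": [1.0, 1.0],
                    "yld": [0.0, 0.0],
                }
            )
            cf = counterfactual_cfr(
                BurdenTable(df, "cause"),
                _pi_frame({"target": 0.5, "best": 0.5}),
                identity_map,
            )
            row = cf.set_index("region").loc["target"]
            averts.append(row["cfr"] - row["cfr_prime"])
        assert all(b >= a - 1e-12 for a, b in zip(averts, averts[1:]))


class TestCounterfactualBurden:
    def test_deaths_are_cases_times_cfr_prime(self):
        keys = {
            "age_group": ["30"], "sex": ["male"],
            "region": ["s1"], "category": ["falls"],
        }
        cases = pd.DataFrame({**keys, "cases": [1000.0]})
        cfrp = pd.DataFrame({**keys, "cfr_prime": [0.05]})
        out = counterfactual_deaths(cases, cfrp)
        assert out["deaths_prime"].iloc[0] == pytest.approx(50.0)
        zero = counterfactual_deaths(
            cases, pd.DataFrame({**keys, "cfr_prime": [0.0]})
        )
        assert zero["deaths_prime"].iloc[0] == 0.0

    def test_misaligned_strata_reported(self):
        keys = {
            "age_group": ["30"], "sex": ["male"],
            "region": ["s1"], "category": ["falls"],
        }
        cases = pd.DataFrame({**keys, "cases": [1000.0]})
        cfrp = pd.DataFrame(
            {"age_group": ["45"], "sex": ["male"], "region": ["s1"],
             "category": ["falls"], "cfr_prime": [0.1]}
        )
        with pytest.raises(ValidationError, match="falls"):
            counterfactual_deaths(cases, cfrp)

    def test_yll_is_deaths_times_life_expectancy(self):
        df = pd.DataFrame(
            {"age_group": ["30"], "sex": ["male"], "region": ["s1"],
             "category": ["falls"], "deaths_prime": [50.0]}
        )
        out = counterfactual_yll(df, LIFE)
        assert out["yll_prime"].iloc[0] == pytest.approx(2000.0)

    def test_yll_missing_age_group_raises(self):
        df = pd.DataFrame(
            {"age_group": ["60"], "sex": ["male"], "region": ["s1"],
             "category": ["falls"], "deaths_prime": [1.0]}
        )
        with pytest.raises(ValidationError, match="60"):
            counterfactual_yll(df, LIFE)

    def test_mixed_age_yll_matches_brute_force_sum(self):
        rng = np.random.default_rng(11)
        ages = ["0", "15", "45"]
        life = LifeTable(tuple(ages), {"0": 80.0, "15": 66.0, "45": 38.0})
        df = pd.DataFrame(
            {
                "age_group": ages * 2,
                "sex": ["male"] * 3 + ["female"] * 3,
                "region": ["s1"] * 6,
                "category": ["falls"] * 6,
                "deaths_prime": rng.uniform(0, 100, 6),
            }
        )
        out = counterfactual_yll(df, life)
        expected = sum(
            row["deaths_prime"] * life.expectancy[row["age_group"]]
            for _, row in df.iterrows()
        )
        assert out["yll_prime"].sum() == pytest.approx(expected, rel=1e-12)


class TestAvertableFatal:
    def _observed(self, cause="road_injury", deaths=100.0):
        return BurdenTable(
            pd.DataFrame(
                {"age_group": ["30"], "sex": ["male"], "region": ["s1"],
                 "category": [cause], "cases": [1000.0],
                 "deaths": [deaths], "yll": [deaths * 40.0], "yld": [0.0]}
            ),
            "cause",
        )

    def _counterfactual(self, cause="road_injury", deaths_prime=76.0):
        return pd.DataFrame(
            {"age_group": ["30"], "sex": ["male"], "region": ["s1"],
             "category": [cause], "deaths_prime": [deaths_prime],
             "yll_prime": [deaths_prime * 40.0]}
        )

    def test_avertable_is_observed_minus_counterfactual(self):
        out = avertable_fatal(
            self._observed(), self._counterfactual(), AmenabilityMap.default()
        )
        assert out["deaths_avertable"].iloc[0] == pytest.approx(24.0)
        assert out["yll_avertable"].iloc[0] == pytest.approx(24.0 * 40.0)

    def test_non_amenable_cause_forced_to_zero(self):
        out = avertable_fatal(
            self._observed("drowning"),
            self._counterfactual("drowning", deaths_prime=10.0),
            AmenabilityMap.default(),
        )
        assert out["deaths_avertable"].iloc[0] == 0.0
        assert out["deaths_counterfactual"].iloc[0] == 100.0

    def test_counterfactual_above_observed_raises(self):
        with pytest.raises(ValidationError, match="exceeds observed"):
            avertable_fatal(
                self._observed(deaths=50.0),
                self._counterfactual(deaths_prime=60.0),
                AmenabilityMap.default(),
            )

    def test_rounding_negatives_clamped_to_zero(self):
        out = avertable_fatal(
            self._observed(deaths=100.0),
            self._counterfactual(deaths_prime=100.0 + 1e-11),
            AmenabilityMap.default(),
        )
        assert out["deaths_avertable"].iloc[0] == 0.0


def loop_oracle(bundle):
    """Naive per-stratum scalar-loop recomputation of avertable deaths."""
    df = bundle.cause_table.data
    pi = bundle.true_prehospital.set_index(["region", "sex"])["pi"]
    amen = bundle.amenability
    rmap = bundle.region_map

    h_by_cell: dict = {}
    for _, row in df.iterrows():
        if row["cases"] <= 0:
            continue
        cfr = row["deaths"] / row["cases"]
        p = pi[(row["region"], row["sex"])]
        h = cfr * (1 - p) / (1 - cfr * p)
        key = (row["age_group"], row["sex"], row["category"])
        h_by_cell.setdefault(key, []).append(h)

    agg: dict = {}
    for _, row in df.iterrows():
        sr = rmap.super_region_of(row["region"])
        key = (row["age_group"], row["sex"], sr, row["category"])
        entry = agg.setdefault(key, {"cases": 0.0, "deaths": 0.0, "pre": 0.0})
        entry["cases"] += row["cases"]
        entry["deaths"] += row["deaths"]
        entry["pre"] += row["deaths"] * pi[(row["region"], row["sex"])]

    total = 0.0
    for (age, sex, sr, cause), e in agg.items():
        if e["cases"] <= 0 or not amen.is_amenable(cause):
            continue
        cfr = e["deaths"] / e["cases"]
        p = e["pre"] / e["deaths"] if e["deaths"] > 0 else 0.0
        d = cfr * p
        own_h = cfr * (1 - p) / (1 - d) if d < 1 else 1.0
        h_star = min(min(h_by_cell[(age, sex, cause)]), own_h)
        cfr_prime = min(d + (1 - d) * h_star, cfr)
        total += e["cases"] * (cfr - cfr_prime)
    return total


def test_pipeline_equals_per_stratum_loop_oracle(bundle, bypass_output):
    """The vectorised pipeline and a naive scalar loop agree exactly."""
    expected = loop_oracle(bundle)
    got = bypass_output.result.totals("avertable")["deaths"]
    assert got == pytest.approx(expected, rel=1e-12)
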