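"""Demand engine: worked examples, roll-up conservation, model properties."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxyquant import demand
from oxyquant.domain import FacilityRecord, WardAssumptions
from oxyquant.demand import (
    caseload,
    facility_annual_need,
    load_roster,
    monthly,
    per_patient_volume,
    rollup,
    typelevel_need,
    ward_annual_need,
    write_roster,
)

# Worked-example assumption set: a neonatal ward on 1 L/min for 3 days and a
# severe-COVID adult ward on 10 L/min for 7 days.
EXAMPLE_ASSUMPTIONS = {
    "neonatal_example": WardAssumptions(
        ward_name="neonatal_example", hypoxaemia_prevalence=0.20,
        flow_rate=1.0, therapy_duration=72.0,
    ),
    "covid_example": WardAssumptions(
        ward_name="covid_example", hypoxaemia_prevalence=1.00,
        flow_rate=10.0, therapy_duration=168.0,
    ),
}


class TestPerPatientVolume:
    @pytest.mark.parametrize(
        "flow,duration,litres",
        [(1.0, 72.0, 4_320.0), (0.0, 500.0, 0.0), (10.0, 168.0, 100_800.0)],
    )
    def test_volume_is_flow_times_minutes(self, flow, duration, litres):
        assert per_patient_volume(flow, duration).litres == litres

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            per_patient_volume(-1.0, 1.0)


class TestCaseload:
    @pytest.mark.parametrize(
        "prev,beds,turnover,expected",
        [(0.20, 10, 50, 100.0), (1.00, 5, 25, 125.0), (0.0, 400, 90, 0.0)],
    )
    def test_expected_patients(self, prev, beds, turnover, expected):
        assert caseload(prev, beds, turnover).expected_patients_per_year == expected

    def test_caseload_stays_fractional(self):
        assert caseload(0.13, 7, 53).expected_patients_per_year == pytest.approx(48.23)

    @pytest.mark.parametrize("bad", [{"prevalence": 1.5}, {"occupancy": -0.1}])
    def test_out_of_range_fraction_rejected(self, bad):
        with pytest.raises(ValueError):
            caseload(bad.get("prevalence", 0.5), 10, 50, bad.get("occupancy", 1.0))

    def test_occupancy_scales_caseload(self):
        full = caseload(0.2, 10, 50, occupancy=1.0)
        half = caseload(0.2, 10, 50, occupancy=0.5)
        assert half.expected_patients_per_year == full.expected_patients_per_year / 2


class TestWardAnnualNeed:
    @pytest.mark.parametrize(
        "litres,patients,expected",
        [(4_320.0, 100.0, 432_000.0), (100_800.0, 125.0, 12_600_000.0), (9_999.0, 0.0, 0.0)],
    )
    def test_worked_examples_exact(self, litres, patients, expected):
        res = ward_annual_need(
            demand.PatientOxygenVolume(litres=litres),
            demand.HypoxaemicCaseload(expected_patients_per_year=patients),
        )
        assert res.annual_litres == expected


class TestFacilityAnnualNeed:
    def _facility(self, ward_beds):
        return FacilityRecord(
            facility_id="hf-1", facility_type="district", region="R01",
            ward_beds=ward_beds,
        )

    # worked-example turnovers: 50 for the neonatal row, 25 for the COVID row
    TYPE_50 = {"district": dict(type_name="district", facility_count=1,
                                total_beds=10, annual_bed_turnover=50.0)}

    def test_zero_prevalence_ward_contributes_nothing(self, assumptions, type_params):
        fac = self._facility({"outpatient": 40})
        res = facility_annual_need(fac, assumptions, type_params)
        assert res.annual_litres == 0.0

    def test_single_neonatal_ward_reproduces_example(self):
        from oxyquant.domain import FacilityTypeParams

        types = {"district": FacilityTypeParams(**self.TYPE_50["district"])}
        fac = self._facility({"neonatal_example": 10})
        res = facility_annual_need(fac, EXAMPLE_ASSUMPTIONS, types)
        assert res.annual_litres == 432_000.0
        assert res.expected_hypoxaemic_patients == 100.0

    def test_two_example_wards_sum(self):
        from oxyquant.domain import FacilityTypeParams

        # one facility per example row, each with its own turnover
        t50 = {"district": FacilityTypeParams(**self.TYPE_50["district"])}
        t25 = {"district": FacilityTypeParams(
            type_name="district", facility_count=1, total_beds=5,
            annual_bed_turnover=25.0)}
        neo = facility_annual_need(
            self._facility({"neonatal_example": 10}), EXAMPLE_ASSUMPTIONS, t50)
        covid = facility_annual_need(
            self._facility({"covid_example": 5}), EXAMPLE_ASSUMPTIONS, t25)
        assert neo.annual_litres + covid.annual_litres == 13_032_000.0

    def test_unknown_labels_named_in_error(self, assumptions, type_params):
        with pytest.raises(KeyError, match="'mystery_ward'"):
            facility_annual_need(
                self._facility({"mystery_ward": 5}), assumptions, type_params)
        fac = FacilityRecord(
            facility_id="hf-2", facility_type="spa", region="R01",
            ward_beds={"neonatology": 5},
        )
        with pytest.raises(KeyError, match="'spa'"):
            facility_annual_need(fac, assumptions, type_params)


class TestRollup:
    def _demands(self, litres_by_id):
        return [
            demand.DemandResult(
                grouping="facility", group_key=k, annual_litres=v,
                expected_hypoxaemic_patients=0.0,
            )
            for k, v in litres_by_id.items()
        ]

    def test_national_is_plain_sum(self):
        idx = {"a": ("district", "R01"), "b": ("district", "R02")}
        [nat] = rollup(self._demands({"a": 432_000.0, "b": 432_000.0}), "national", idx)
        assert nat.annual_litres == 864_000.0

    def test_partition_conservation_types_vs_regions(self, roster, assumptions, type_params):
        per_fac = [facility_annual_need(f, assumptions, type_params) for f in roster]
        idx = {f.facility_id: (f.facility_type, f.region) for f in roster}
        [nat] = rollup(per_fac, "national", idx)
        by_type = rollup(per_fac, "facility_type", idx)
        by_region = rollup(per_fac, "region", idx)
        assert sum(r.annual_litres for r in by_type) == pytest.approx(
            nat.annual_litres, rel=1e-12)
        assert sum(r.annual_litres for r in by_region) == pytest.approx(
            nat.annual_litres, rel=1e-12)

    def test_rollup_matches_bruteforce_oracle(self, roster, assumptions, type_params):
        """National roll-up equals a per-(facility, ward) accumulation loop."""
        expected = 0.0
        for f in roster:  # oracle: no engine calls, term-by-term
            turnover = type_params[f.facility_type].annual_bed_turnover
            for ward, beds in f.ward_beds.items():
                a = assumptions[ward]
                volume = a.flow_rate * 60.0 * a.therapy_duration
                expected += volume * a.hypoxaemia_prevalence * beds * turnover
        per_fac = [facility_annual_need(f, assumptions, type_params) for f in roster]
        idx = {f.facility_id: (f.facility_type, f.region) for f in roster}
        [nat] = rollup(per_fac, "national", idx)
        assert nat.annual_litres == pytest.approx(expected, rel=1e-6)

    def test_missing_index_entry_is_an_error(self):
        with pytest.raises(KeyError, match="missing from index"):
            rollup(self._demands({"ghost": 1.0}), "national", {})


def test_typelevel_need_scales_by_count(type_params):
    assert typelevel_need(type_params["district"], 100_000.0) == 6_700_000.0
    zero = type_params["district"].model_copy(update={"facility_count": 0})
    assert typelevel_need(zero, 1e9) == 0.0


@pytest.mark.parametrize(
    "annual,expected",
    [(12_600_000.0, 1_050_000.0), (0.0, 0.0), (432_000.0, 36_000.0)],
)
def test_monthly_is_annual_over_twelve(annual, expected):
    assert monthly(annual) == expected


# ---------------------------------------------------------------------------
# Model properties
# ---------------------------------------------------------------------------

factor = st.floats(min_value=0.0, max_value=1e3, allow_nan=False)


@settings(max_examples=200, deadline=None)
@given(
    prev=st.floats(min_value=0.0, max_value=0.5),
    beds=st.integers(min_value=0, max_value=500),
    turnover=factor,
    flow=st.floats(min_value=0.0, max_value=30.0),
    duration=st.floats(min_value=0.0, max_value=500.0),
)
def test_demand_linear_in_each_factor(prev, beds, turnover, flow, duration):
    """Doubling any single factor doubles ward demand; zero anywhere gives zero."""

    def need(p, b, t, fl, d):
        return ward_annual_need(per_patient_volume(fl, d), caseload(p, b, t)).annual_litres

    base = need(prev, beds, turnover, flow, duration)
    assert need(2 * prev, beds, turnover, flow, duration) == pytest.approx(2 * base)
    assert need(prev, 2 * beds, turnover, flow, duration) == pytest.approx(2 * base)
    assert need(prev, beds, 2 * turnover, flow, duration) == pytest.approx(2 * base)
    assert need(prev, beds, turnover, 2 * flow, duration) == pytest.approx(2 * base)
    assert need(prev, beds, turnover, flow, 2 * duration) == pytest.approx(2 * base)
    for zeroed in (
        need(0.0, beds, turnover, flow, duration),
        need(prev, 0, turnover, flow, duration),
        need(prev, beds, 0.0, flow, duration),
        need(prev, beds, turnover, 0.0, duration),
        need(prev, beds, turnover, flow, 0.0),
    ):
        assert zeroed == 0.0


def test_roster_roundtrip(tmp_path, roster):
    p = tmp_path / "roster.csv"
    write_roster(roster, p)
    reloaded = load_roster(p)
    assert [(f.facility_id, f.facility_type, f.region, f.ward_beds) for f in reloaded] == [
        (f.facility_id, f.facility_type, f.region, dict(f.ward_beds)) for f in roster
    ]


def test_roster_with_inconsistent_facility_rows_rejected():
    df = pd.DataFrame(
        [("f1", "district", "R01", "neonatology", 5),
         ("f1", "central", "R01", "maternity", 5)],
        columns=["facility_id", "facility_type", "region", "ward", "beds"],
    )
    with pytest.raises(ValueError, match="inconsistent"):
        load_roster(df)
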