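"""Oxygen demand quantification engine.

The model is a static annual expectation built from four factors:

* per-patient volume: ``flow_rate [L/min] x 60 x therapy_duration [h]`` —
  the gaseous-oxygen volume one typical hypoxaemic patient in a ward
  consumes over a full course of therapy;
* expected caseload: ``prevalence x beds x annual bed turnover x occupancy``
  — the expected number of hypoxaemic patients a ward admits per year
  (kept fractional: it is an expectation, not a count);
* ward demand: volume x caseload, summed over wards to the facility level;
* roll-ups: facility demands summed by facility type, region, or nationally.

Worked example (neonatal ward, 10 beds, turnover 50/yr): a 1 L/min flow for
3 days gives 4 320 L per patient; 20% prevalence yields 100 expected patients
per year, hence 432 000 L of oxygen annually, 36 000 L monthly.

Turnover is a facility-type property applied uniformly to every ward of the
facility, because turnover rates are reported per facility category only.
Occupancy enters as an optional multiplicative factor on caseload and
defaults to 1.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, NonNegativeFloat

from .domain import (
    DemandResult,
    FacilityRecord,
    FacilityTypeParams,
    WardAssumptions,
)

__all__ = [
    "PatientOxygenVolume",
    "HypoxaemicCaseload",
    "per_patient_volume",
    "caseload",
    "ward_annual_need",
    "facility_annual_need",
    "typelevel_need",
    "monthly",
    "rollup",
    "load_roster",
    "write_roster",
    "demand_frame",
    "write_demand",
]


class PatientOxygenVolume(BaseModel):
    """Gaseous oxygen volume (litres) for one typical hypoxaemic patient."""

    litres: NonNegativeFloat


class HypoxaemicCaseload(BaseModel):
    """Expected hypoxaemic patients per year; fractional by design."""

    expected_patients_per_year: NonNegativeFloat


def per_patient_volume(flow_rate: float, duration: float) -> PatientOxygenVolume:
    """Oxygen volume one patient needs: flow (L/min) x 60 x duration (hours)."""
    if flow_rate < 0 or duration < 0:
        raise ValueError("per_patient_volume: flow_rate and duration must be >= 0")
    return PatientOxygenVolume(litres=flow_rate * 60.0 * duration)


def caseload(
    prevalence: float,
    beds: float,
    turnover: float,
    occupancy: float = 1.0,
) -> HypoxaemicCaseload:
    """Expected hypoxaemic patients/year: prevalence x beds x turnover x occupancy."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"caseload: prevalence {prevalence} outside [0, 1]")
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError(f"caseload: occupancy {occupancy} outside [0, 1]")
    if beds < 0 or turnover < 0:
        raise ValueError("caseload: beds and turnover must be >= 0")
    return HypoxaemicCaseload(
        expected_patients_per_year=prevalence * beds * turnover * occupancy
    )


def ward_annual_need(
    volume: PatientOxygenVolume,
    load: HypoxaemicCaseload,
    ward_name: str = "ward",
) -> DemandResult:
    """Annual ward demand: per-patient volume x expected yearly caseload."""
    return DemandResult(
        grouping="ward",
        group_key=ward_name,
        annual_litres=volume.litres * load.expected_patients_per_year,
        expected_hypoxaemic_patients=load.expected_patients_per_year,
    )


def facility_annual_need(
    facility: FacilityRecord,
    assumptions: Mapping[str, WardAssumptions],
    type_params: Mapping[str, FacilityTypeParams],
    occupancy: float = 1.0,
) -> DemandResult:
    """Annual demand of one facility: sum of its ward demands.

    The facility type's annual bed turnover applies to every ward.  Unknown
    ward or facility-type labels raise with the offending label named.
    """
    try:
        params = type_params[facility.facility_type]
    except KeyError:
        raise KeyError(
            f"facility {facility.facility_id!r}: unknown facility type "
            f"{facility.facility_type!r}"
        ) from None
    annual = 0.0
    patients = 0.0
    for ward, beds in facility.ward_beds.items():
        try:
            a = assumptions[ward]
        except KeyError:
            raise KeyError(
                f"facility {facility.facility_id!r}: unknown ward {ward!r}"
            ) from None
        vol = per_patient_volume(a.flow_rate, a.therapy_duration)
        load = caseload(
            a.hypoxaemia_prevalence, beds, params.annual_bed_turnover, occupancy
        )
        res = ward_annual_need(vol, load, ward_name=ward)
        annual += res.annual_litres
        patients += res.expected_hypoxaemic_patients
    return DemandResult(
        grouping="facility",
        group_key=facility.facility_id,
        annual_litres=annual,
        expected_hypoxaemic_patients=patients,
    )


def typelevel_need(type_params: FacilityTypeParams, per_facility_annual: float) -> float:
    """Scale one representative facility's annual demand to its whole category."""
    if per_facility_annual < 0:
        raise ValueError("typelevel_need: per_facility_annual must be >= 0")
    return per_facility_annual * type_params.facility_count


def monthly(annual: DemandResult | float) -> float:
    """Monthly litres from an annual figure (annual / 12)."""
    value = annual.annual_litres if isinstance(annual, DemandResult) else float(annual)
    if value < 0:
        raise ValueError("monthly: annual demand must be >= 0")
    return value / 12.0


RollupGrouping = Literal["facility_type", "region", "national"]


def rollup(
    demands: Iterable[DemandResult],
    grouping: RollupGrouping,
    facility_index: Mapping[str, tuple[str, str]],
) -> list[DemandResult]:
    """Aggregate facility-level demands by type, region, or nationally.

    ``facility_index`` maps facility_id -> (facility_type, region).  The
    national total equals the sum over any complete partition of the same
    facility set, because aggregation is plain addition.
    """
    sums: dict[str, tuple[float, float]] = {}
    for d in demands:
        if d.grouping != "facility":
            raise ValueError(f"rollup expects facility-level demands, got {d.grouping!r}")
        try:
            ftype, region = facility_index[d.group_key]
        except KeyError:
            raise KeyError(f"rollup: facility {d.group_key!r} missing from index") from None
        if grouping == "national":
            key = "national"
        elif grouping == "facility_type":
            key = ftype
        else:
            key = region
        litres, patients = sums.get(key, (0.0, 0.0))
        sums[key] = (litres + d.annual_litres, patients + d.expected_hypoxaemic_patients)
    return [
        DemandResult(
            grouping=grouping,
            group_key=key,
            annual_litres=litres,
            expected_hypoxaemic_patients=patients,
        )
        for key, (litres, patients) in sorted(sums.items())
    ]


# ---------------------------------------------------------------------------
# Roster and demand-table I/O
# ---------------------------------------------------------------------------

ROSTER_COLUMNS = ["facility_id", "facility_type", "region", "ward", "beds"]


def load_roster(source: str | Path | pd.DataFrame) -> list[FacilityRecord]:
    """Read a long-format facility roster CSV (one row per facility-ward)."""
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in ROSTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"roster: missing required column(s) {missing}")
    records: list[FacilityRecord] = []
    for fid, grp in df.groupby("facility_id", sort=False):
        types = grp["facility_type"].unique()
        regions = grp["region"].unique()
        if len(types) != 1 or len(regions) != 1:
            raise ValueError(f"roster: facility {fid!r} has inconsistent type/region rows")
        records.append(
            FacilityRecord(
                facility_id=str(fid),
                facility_type=str(types[0]),
                region=str(regions[0]),
                ward_beds={
                    str(w): int(b) for w, b in zip(grp["ward"], grp["beds"])
                },
            )
        )
    return records


def write_roster(roster: Sequence[FacilityRecord], path: str | Path) -> None:
    rows = [
        (f.facility_id, f.facility_type, f.region, ward, beds)
        for f in roster
        for ward, beds in f.ward_beds.items()
    ]
    pd.DataFrame(rows, columns=ROSTER_COLUMNS).to_csv(path, index=False)


def demand_frame(results: Iterable[DemandResult]) -> pd.DataFrame:
    """Tabulate demand results in the standard output schema."""
    results = list(results)
    return pd.DataFrame(
        {
            "grouping": [r.grouping for r in results],
            "group_key": [r.group_key for r in results],
            "annual_litres": [r.annual_litres for r in results],
            "monthly_litres": [r.monthly_litres for r in results],
            "expected_hypoxaemic_patients": [
                r.expected_hypoxaemic_patients for r in results
            ],
        }
    )


def write_demand(results: Iterable[DemandResult], path: str | Path) -> None:
    demand_frame(results).to_csv(path, index=False)
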