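"""Synthetic facility rosters, inventories, and monthly report panels.

No facility-level dataset from the national assessment is published, so this
module generates rosters with its published structure: 99 facilities in four
hospital categories (4 general, 13 central, 15 regional, 67 district) holding
the category bed totals, spread over 10 regions.  Ward bed mixes, equipment
holdings, and monthly-report behaviour are governed by explicit, documented
parameters so that every downstream estimator can be checked against the
value it was generated from.

Construction guarantees, relied on by tests:

* facility counts per category match the configuration exactly, and category
  bed totals are conserved by largest-remainder rounding at both the
  facility and the ward split;
* the monthly stock ledger balances exactly (closing is derived);
* ``patients_given_oxygen ~ Binomial(hypoxaemic_patients, coverage)`` and
  ``patients_treatment_success ~ Binomial(patients_given_oxygen, success)``,
  so pooled indicator estimates recover the configured probabilities;
* hypoxaemic caseloads are drawn Poisson with mean equal to the facility's
  monthly expected caseload from the demand engine, tying the report stream
  to the quantification model;
* a fixed seed reproduces the entire pipeline byte-for-byte.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import demand as demand_mod
from .domain import (
    DEFAULT_REGIONS,
    DeviceCount,
    EquipmentInventory,
    FacilityRecord,
    FacilityTypeParams,
    WardAssumptions,
    default_assumptions,
    default_facility_type_params,
)
from .indicators import MonthlyReport, days_in_period

__all__ = [
    "EquipmentRates",
    "ReportParams",
    "GeneratorConfig",
    "largest_remainder",
    "generate_roster",
    "generate_inventories",
    "generate_reports",
]

#: Default ward bed shares: a plausible mix over the nine standard wards,
#: weighted toward general medicine, paediatrics, maternity and theatre.
DEFAULT_WARD_SHARES: dict[str, float] = {
    "outpatient": 0.05,
    "adult_medicine": 0.22,
    "paediatrics": 0.16,
    "neonatology": 0.06,
    "intensive_care": 0.04,
    "operating_theatre": 0.12,
    "emergency": 0.10,
    "maternity": 0.18,
    "recovery": 0.07,
}


class EquipmentRates(BaseModel):
    """Per-bed Poisson rates for device totals and functional probabilities."""

    concentrators_per_bed: float = Field(default=0.10, ge=0)
    oximeters_per_bed: float = Field(default=0.15, ge=0)
    monitors_per_bed: float = Field(default=0.08, ge=0)
    cylinders_per_bed: float = Field(default=0.02, ge=0)
    p_functional: float = Field(default=0.80, ge=0, le=1)
    cylinder_size: float = Field(default=7500.0, gt=0)


class ReportParams(BaseModel):
    """Behavioural parameters of the monthly reporting stream."""

    stockout_rate: float = Field(default=1.5, ge=0)  # events per month
    coverage_probability: float = Field(default=0.7, ge=0, le=1)
    success_probability: float = Field(default=0.75, ge=0, le=1)
    training_fraction: float = Field(default=0.65, ge=0, le=1)
    hypoxaemia_dept_probability: float = Field(default=0.6, ge=0, le=1)
    stock_flow_scale: float = Field(default=50_000.0, ge=0)  # litres/month
    loss_fraction: float = Field(default=0.02, ge=0, le=1)
    staff_per_facility: int = Field(default=20, ge=1)


class GeneratorConfig(BaseModel):
    seed: int = 0
    facility_type_params: dict[str, FacilityTypeParams] = Field(
        default_factory=default_facility_type_params
    )
    assumptions: dict[str, WardAssumptions] = Field(default_factory=default_assumptions)
    ward_shares: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_WARD_SHARES)
    )
    regions: tuple[str, ...] = DEFAULT_REGIONS
    region_weights: tuple[float, ...] | None = None
    equipment_rates: EquipmentRates = Field(default_factory=EquipmentRates)
    report_params: ReportParams = Field(default_factory=ReportParams)

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        total = sum(self.ward_shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"ward_shares must sum to 1, got {total}")
        if any(s < 0 for s in self.ward_shares.values()):
            raise ValueError("ward_shares must be non-negative")
        if self.region_weights is not None:
            if len(self.region_weights) != len(self.regions):
                raise ValueError("region_weights length must match regions")
            if any(w < 0 for w in self.region_weights) or sum(self.region_weights) <= 0:
                raise ValueError("region_weights must be non-negative, sum > 0")
        for ward in self.ward_shares:
            if ward not in self.assumptions:
                raise ValueError(f"ward_shares ward {ward!r} not in assumptions")
        return self


def largest_remainder(total: int, weights: Sequence[float]) -> list[int]:
    """Apportion an integer total over weights, conserving the total exactly.

    Each slot gets the floor of its exact share; leftover units go to the
    largest fractional remainders (ties broken by slot order).
    """
    if total < 0:
        raise ValueError("largest_remainder: total must be >= 0")
    wsum = float(sum(weights))
    if wsum <= 0:
        raise ValueError("largest_remainder: weights must sum to > 0")
    exact = [total * w / wsum for w in weights]
    floors = [int(np.floor(e)) for e in exact]
    leftover = total - sum(floors)
    order = sorted(
        range(len(weights)), key=lambda i: (exact[i] - floors[i], -i), reverse=True
    )
    for i in order[:leftover]:
        floors[i] += 1
    return floors


def generate_roster(config: GeneratorConfig) -> list[FacilityRecord]:
    """Generate a facility roster with exact category counts and bed totals.

    Beds are split evenly over the facilities of each category and over wards
    by the configured shares, both with largest-remainder rounding, so each
    category's bed total is conserved exactly.
    """
    rng = np.random.default_rng(config.seed)
    wards = list(config.ward_shares)
    shares = [config.ward_shares[w] for w in wards]
    weights = (
        np.asarray(config.region_weights, dtype=float)
        if config.region_weights is not None
        else np.ones(len(config.regions))
    )
    weights = weights / weights.sum()
    roster: list[FacilityRecord] = []
    for type_name, params in config.facility_type_params.items():
        if params.facility_count == 0:
            continue
        beds_per_facility = largest_remainder(
            params.total_beds, [1.0] * params.facility_count
        )
        regions = rng.choice(len(config.regions), size=params.facility_count, p=weights)
        for i, beds in enumerate(beds_per_facility):
            ward_alloc = largest_remainder(beds, shares)
            roster.append(
                FacilityRecord(
                    facility_id=f"{type_name}-{i + 1:03d}",
                    facility_type=type_name,
                    region=config.regions[int(regions[i])],
                    ward_beds={w: b for w, b in zip(wards, ward_alloc)},
                )
            )
    return roster


def generate_inventories(
    roster: Sequence[FacilityRecord], config: GeneratorConfig
) -> list[FacilityRecord]:
    """Attach sampled equipment inventories to a roster (returns new records)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rates = config.equipment_rates
    out: list[FacilityRecord] = []
    for f in roster:
        beds = f.total_beds()
        inv = {}
        for attr, per_bed in (
            ("oxygen_concentrators", rates.concentrators_per_bed),
            ("pulse_oximeters", rates.oximeters_per_bed),
            ("patient_monitors", rates.monitors_per_bed),
            ("oxygen_cylinders", rates.cylinders_per_bed),
        ):
            total = int(rng.poisson(per_bed * beds))
            functional = int(rng.binomial(total, rates.p_functional)) if total else 0
            inv[attr] = DeviceCount(functional=functional, total=total)
        out.append(
            f.model_copy(
                update={
                    "equipment": EquipmentInventory(
                        **inv, cylinder_size=rates.cylinder_size
                    )
                }
            )
        )
    return out


def generate_reports(
    roster: Sequence[FacilityRecord],
    config: GeneratorConfig,
    months: int = 3,
    start: str = "2023-01",
) -> list[MonthlyReport]:
    """Generate one report per facility-month with an exactly balanced ledger."""
    if months < 1:
        raise ValueError("generate_reports: months must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    rp = config.report_params
    year, month = (int(p) for p in start.split("-"))

    # Monthly expected caseload per facility, from the demand engine.
    mean_caseload = {
        f.facility_id: demand_mod.facility_annual_need(
            f, config.assumptions, config.facility_type_params
        ).expected_hypoxaemic_patients
        / 12.0
        for f in roster
    }
    dept_flag = {
        f.facility_id: bool(rng.random() < rp.hypoxaemia_dept_probability)
        for f in roster
    }
    opening = {f.facility_id: rp.stock_flow_scale * float(rng.random()) for f in roster}

    reports: list[MonthlyReport] = []
    for m in range(months):
        y, mo = year + (month - 1 + m) // 12, (month - 1 + m) % 12 + 1
        period = f"{y:04d}-{mo:02d}"
        ndays = days_in_period(period)
        for f in roster:
            fid = f.facility_id
            hypox = int(rng.poisson(mean_caseload[fid]))
            given = int(rng.binomial(hypox, rp.coverage_probability)) if hypox else 0
            success = int(rng.binomial(given, rp.success_probability)) if given else 0
            stockout = min(int(rng.poisson(rp.stockout_rate)), ndays)
            received = rp.stock_flow_scale * float(rng.random())
            available = opening[fid] + received
            consumed = available * float(rng.uniform(0.4, 0.9))
            lost = (available - consumed) * rp.loss_fraction
            closing = available - consumed - lost  # ledger identity, exact
            staff_total = rp.staff_per_facility
            staff_trained = int(rng.binomial(staff_total, rp.training_fraction))
            eq = f.equipment
            oxi_total = eq.pulse_oximeters.total
            oxi_func = eq.pulse_oximeters.functional
            resp_total = int(rng.poisson(1.0))
            resp_func = int(rng.binomial(resp_total, 0.7)) if resp_total else 0
            gen_total = int(rng.random() < 0.15)
            gen_func = int(rng.binomial(gen_total, 0.6)) if gen_total else 0
            reports.append(
                MonthlyReport(
                    facility_id=fid,
                    period=period,
                    has_hypoxaemia_dept=dept_flag[fid],
                    stockout_days=stockout,
                    oxygen_opening=opening[fid],
                    oxygen_received=received,
                    oxygen_consumed=consumed,
                    oxygen_lost=lost,
                    oxygen_closing=closing,
                    oximeters_functional=oxi_func,
                    oximeters_total=oxi_total,
                    respirators_functional=resp_func,
                    respirators_total=resp_total,
                    generators_functional=gen_func,
                    generators_total=gen_total,
                    cylinders_7500=eq.oxygen_cylinders.total,
                    staff_trained=staff_trained,
                    staff_total=staff_total,
                    hypoxaemic_patients=hypox,
                    patients_given_oxygen=given,
                    patients_treatment_success=success,
                )
            )
            opening[fid] = closing
    return reports
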