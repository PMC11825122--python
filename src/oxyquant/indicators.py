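"""Hypoxaemia-management and oxygen-use indicators from monthly facility reports.

Facilities report once a month, DHIS-2 style: stock movements of medical
oxygen (a litre-denominated ledger), equipment functionality, staffing, and
patient outcomes.  From a panel of such reports this module computes the
national indicator set: percentages of facilities with a hypoxaemia
management department, quarterly stock-out burden, device functionality,
oxygen-therapy coverage, therapeutic success, staff training, stock totals
and the cylinder census.

Two conventions apply throughout and are recorded in the machine-readable
catalogue (:data:`CATALOGUE`):

* Ratio indicators pool numerators and denominators across facilities before
  dividing — never an average of facility-level percentages — making them
  robust to facilities with tiny denominators.
* Undefined ratios (zero pooled denominator) are emitted as missing values
  with a reason, not as zeros.

The stock ledger must balance: opening + received − consumed − lost =
closing.  Violations are reported with their residual rather than silently
repaired.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, Field, NonNegativeFloat, NonNegativeInt, model_validator

__all__ = [
    "MonthlyReport",
    "IndicatorValue",
    "LedgerValidation",
    "CATALOGUE",
    "LEDGER_TOLERANCE_LITRES",
    "validate_ledger",
    "pct_with_hypoxaemia_dept",
    "mean_stockout_days",
    "proportion_functional",
    "oxygen_therapy_coverage",
    "therapeutic_success",
    "pct_staff_trained",
    "stock_total",
    "cylinder_census",
    "compute_all",
    "load_reports",
    "write_reports",
    "indicator_frame",
]

#: Absolute tolerance, in litres, for the stock-ledger identity.
LEDGER_TOLERANCE_LITRES = 1.0


def days_in_period(period: str) -> int:
    """Number of days in a 'YYYY-MM' period."""
    year, month = (int(p) for p in period.split("-"))
    return calendar.monthrange(year, month)[1]


class MonthlyReport(BaseModel):
    """One facility-month of stock, equipment, staffing and patient data."""

    facility_id: str
    period: str = Field(pattern=r"^\d{4}-\d{2}$")  # year-month
    has_hypoxaemia_dept: bool = False
    stockout_days: NonNegativeInt = 0
    oxygen_opening: NonNegativeFloat = 0.0
    oxygen_received: NonNegativeFloat = 0.0
    oxygen_consumed: NonNegativeFloat = 0.0
    oxygen_lost: NonNegativeFloat = 0.0
    oxygen_closing: NonNegativeFloat = 0.0
    oximeters_functional: NonNegativeInt = 0
    oximeters_total: NonNegativeInt = 0
    respirators_functional: NonNegativeInt = 0
    respirators_total: NonNegativeInt = 0
    generators_functional: NonNegativeInt = 0
    generators_total: NonNegativeInt = 0
    cylinders_7500: NonNegativeInt = 0
    staff_trained: NonNegativeInt = 0
    staff_total: NonNegativeInt = 0
    hypoxaemic_patients: NonNegativeInt = 0
    patients_given_oxygen: NonNegativeInt = 0
    patients_treatment_success: NonNegativeInt = 0

    @model_validator(mode="after")
    def _consistency(self) -> "MonthlyReport":
        if self.stockout_days > days_in_period(self.period):
            raise ValueError(
                f"{self.facility_id} {self.period}: stockout_days "
                f"{self.stockout_days} exceeds days in month"
            )
        for func, total in (
            ("oximeters_functional", "oximeters_total"),
            ("respirators_functional", "respirators_total"),
            ("generators_functional", "generators_total"),
        ):
            if getattr(self, func) > getattr(self, total):
                raise ValueError(f"{self.facility_id} {self.period}: {func} > {total}")
        if self.patients_given_oxygen > self.hypoxaemic_patients:
            raise ValueError(
                f"{self.facility_id} {self.period}: patients_given_oxygen exceeds "
                "hypoxaemic_patients"
            )
        if self.staff_trained > self.staff_total:
            raise ValueError(
                f"{self.facility_id} {self.period}: staff_trained exceeds staff_total"
            )
        return self


Unit = Literal["%", "days", "litres", "count"]


class IndicatorValue(BaseModel):
    indicator_id: str
    scope: str
    key: str
    period: str
    value: float | None
    unit: Unit
    status: str = "ok"  # "ok" or "missing:<reason>"

    @model_validator(mode="after")
    def _range(self) -> "IndicatorValue":
        if self.value is not None:
            if self.unit == "%" and not 0.0 <= self.value <= 100.0:
                raise ValueError(f"{self.indicator_id}: percentage outside [0, 100]")
            if self.unit in ("litres", "count") and self.value < 0:
                raise ValueError(f"{self.indicator_id}: negative {self.unit}")
        return self


@dataclass(frozen=True)
class IndicatorDef:
    """Catalogue entry: the auditable definition of one indicator."""

    indicator_id: str
    name: str
    unit: Unit
    numerator: str | None
    denominator: str | None
    aggregation: str  # pooled_ratio | facility_flag_ratio | sum | mean_quarterly_sum


#: Machine-readable indicator catalogue; definitions are this package's and
#: may be overridden by supplying a modified list to :func:`compute_all`.
CATALOGUE: tuple[IndicatorDef, ...] = (
    IndicatorDef("pct_hypoxaemia_dept", "Percentage of facilities with a hypoxaemia management department", "%", "has_hypoxaemia_dept", "facilities", "facility_flag_ratio"),
    IndicatorDef("mean_stockout_days", "Average stock-out days of medical oxygen during the quarter", "days", "stockout_days", "facilities", "mean_quarterly_sum"),
    IndicatorDef("oxygen_opening_litres", "Total medical oxygen available at the beginning of the month", "litres", "oxygen_opening", None, "sum"),
    IndicatorDef("oxygen_received_litres", "Total medical oxygen received during the month", "litres", "oxygen_received", None, "sum"),
    IndicatorDef("oxygen_consumed_litres", "Total medical oxygen consumed during the month", "litres", "oxygen_consumed", None, "sum"),
    IndicatorDef("oxygen_lost_litres", "Total medical oxygen lost or damaged during the month", "litres", "oxygen_lost", None, "sum"),
    IndicatorDef("pct_functional_oximeters", "Proportion of functioning pulse oximeters during the month", "%", "oximeters_functional", "oximeters_total", "pooled_ratio"),
    IndicatorDef("pct_facilities_with_respirator", "Proportion of facilities with functioning respirators", "%", "respirators_functional>=1", "facilities", "facility_flag_ratio"),
    IndicatorDef("pct_facilities_with_generator", "Proportion of facilities with a functioning oxygen generator", "%", "generators_functional>=1", "facilities", "facility_flag_ratio"),
    IndicatorDef("cylinders_7500_count", "Total 7500 L medical oxygen cylinders (full or empty)", "count", "cylinders_7500", None, "sum"),
    IndicatorDef("pct_staff_trained", "Proportion of health workers with capacity building in hypoxaemia management", "%", "staff_trained", "staff_total", "pooled_ratio"),
    IndicatorDef("oxygen_therapy_coverage", "Proportion of hypoxaemic patients who received oxygen therapy", "%", "patients_given_oxygen", "hypoxaemic_patients", "pooled_ratio"),
    IndicatorDef("therapeutic_success", "Therapeutic success rate among patients given oxygen", "%", "patients_treatment_success", "patients_given_oxygen", "pooled_ratio"),
)


class LedgerValidation(BaseModel):
    """Outcome of the stock-ledger identity check for one report."""

    facility_id: str
    period: str
    passed: bool
    residual_litres: float


def validate_ledger(report: MonthlyReport) -> LedgerValidation:
    """Check opening + received − consumed − lost = closing (±1 L)."""
    residual = (
        report.oxygen_opening
        + report.oxygen_received
        - report.oxygen_consumed
        - report.oxygen_lost
        - report.oxygen_closing
    )
    return LedgerValidation(
        facility_id=report.facility_id,
        period=report.period,
        passed=abs(residual) <= LEDGER_TOLERANCE_LITRES,
        residual_litres=residual,
    )


# ---------------------------------------------------------------------------
# Indicator computations (all pooling conventions live here)
# ---------------------------------------------------------------------------


def _require_reports(reports: Sequence[MonthlyReport], what: str) -> None:
    if not reports:
        raise ValueError(f"{what}: empty report collection for scope")


def _period_span(reports: Sequence[MonthlyReport]) -> str:
    periods = sorted({r.period for r in reports})
    return periods[0] if len(periods) == 1 else f"{periods[0]}..{periods[-1]}"


def _value(indicator_id, scope, key, period, value, unit, status="ok") -> IndicatorValue:
    return IndicatorValue(
        indicator_id=indicator_id, scope=scope, key=key, period=period,
        value=value, unit=unit, status=status,
    )


def pct_with_hypoxaemia_dept(
    reports: Sequence[MonthlyReport], scope: str = "national", key: str = "national"
) -> IndicatorValue:
    """Share of reporting facilities flagging a hypoxaemia management department."""
    _require_reports(reports, "pct_with_hypoxaemia_dept")
    flags: dict[str, bool] = {}
    for r in reports:
        flags[r.facility_id] = flags.get(r.facility_id, False) or r.has_hypoxaemia_dept
    pct = 100.0 * sum(flags.values()) / len(flags)
    return _value("pct_hypoxaemia_dept", scope, key, _period_span(reports), pct, "%")


def mean_stockout_days(
    reports: Sequence[MonthlyReport],
    quarter: Sequence[str],
    scope: str = "national",
    key: str = "national",
    missing_month: Literal["exclude", "zero"] = "exclude",
) -> IndicatorValue:
    """Mean over facilities of summed stock-out days across a quarter's months.

    Facilities missing any of the quarter's months are excluded by default
    (``missing_month='zero'`` instead counts absent months as zero days);
    the policy applied is recorded in the value's status field.
    """
    months = set(quarter)
    by_facility: dict[str, dict[str, int]] = {}
    for r in reports:
        if r.period in months:
            by_facility.setdefault(r.facility_id, {})[r.period] = r.stockout_days
    sums = []
    for fid, per_month in by_facility.items():
        if missing_month == "exclude" and set(per_month) != months:
            continue
        sums.append(sum(per_month.values()))
    period = f"{min(months)}..{max(months)}"
    if not sums:
        return _value(
            "mean_stockout_days", scope, key, period, None, "days",
            status="missing:no facility covers the quarter",
        )
    return _value(
        "mean_stockout_days", scope, key, period, sum(sums) / len(sums), "days",
        status=f"ok;missing_month={missing_month}",
    )


Device = Literal["pulse_oximeter", "respirator", "generator"]


def proportion_functional(
    reports: Sequence[MonthlyReport],
    device: Device,
    scope: str = "national",
    key: str = "national",
    category_of: Mapping[str, str] | None = None,
) -> list[IndicatorValue]:
    """Device functionality for a scope.

    Pulse oximeters are assessed device-level: 100 x Σ functional / Σ total.
    Respirators and oxygen generators are assessed facility-level: the share
    of facilities holding at least one functional unit, optionally stratified
    by facility category via ``category_of`` (facility_id -> category label).
    """
    _require_reports(reports, "proportion_functional")
    period = _period_span(reports)
    if device == "pulse_oximeter":
        num = sum(r.oximeters_functional for r in reports)
        den = sum(r.oximeters_total for r in reports)
        if den == 0:
            return [_value(
                "pct_functional_oximeters", scope, key, period, None, "%",
                status="missing:no pulse oximeters reported",
            )]
        return [_value(
            "pct_functional_oximeters", scope, key, period, 100.0 * num / den, "%"
        )]

    field = "respirators_functional" if device == "respirator" else "generators_functional"
    indicator_id = (
        "pct_facilities_with_respirator"
        if device == "respirator"
        else "pct_facilities_with_generator"
    )
    has_device: dict[str, bool] = {}
    for r in reports:
        has_device[r.facility_id] = (
            has_device.get(r.facility_id, False) or getattr(r, field) >= 1
        )
    strata: dict[str, list[bool]] = {}
    for fid, flag in has_device.items():
        label = category_of.get(fid, "uncategorised") if category_of else key
        strata.setdefault(label, []).append(flag)
    return [
        _value(indicator_id, scope, label, period,
               100.0 * sum(flags) / len(flags), "%")
        for label, flags in sorted(strata.items())
    ]


def _pooled_ratio(
    reports: Sequence[MonthlyReport],
    indicator_id: str,
    num_field: str,
    den_field: str,
    scope: str,
    key: str,
    missing_reason: str,
) -> IndicatorValue:
    _require_reports(reports, indicator_id)
    num = sum(getattr(r, num_field) for r in reports)
    den = sum(getattr(r, den_field) for r in reports)
    period = _period_span(reports)
    if den == 0:
        return _value(indicator_id, scope, key, period, None, "%",
                      status=f"missing:{missing_reason}")
    return _value(indicator_id, scope, key, period, 100.0 * num / den, "%")


def oxygen_therapy_coverage(
    reports: Sequence[MonthlyReport], scope: str = "national", key: str = "national"
) -> IndicatorValue:
    """Pooled share of hypoxaemic patients who received oxygen therapy."""
    return _pooled_ratio(
        reports, "oxygen_therapy_coverage", "patients_given_oxygen",
        "hypoxaemic_patients", scope, key, "no hypoxaemic patients reported",
    )


def therapeutic_success(
    reports: Sequence[MonthlyReport], scope: str = "national", key: str = "national"
) -> IndicatorValue:
    """Pooled share of oxygen-treated patients with a successful outcome."""
    return _pooled_ratio(
        reports, "therapeutic_success", "patients_treatment_success",
        "patients_given_oxygen", scope, key, "no patients given oxygen",
    )


def pct_staff_trained(
    reports: Sequence[MonthlyReport], scope: str = "national", key: str = "national"
) -> IndicatorValue:
    """Pooled share of health workers trained in hypoxaemia management."""
    return _pooled_ratio(
        reports, "pct_staff_trained", "staff_trained", "staff_total",
        scope, key, "no staff reported",
    )


def stock_total(
    reports: Sequence[MonthlyReport],
    field: Literal["oxygen_opening", "oxygen_received", "oxygen_consumed", "oxygen_lost"],
    scope: str = "national",
    key: str = "national",
) -> IndicatorValue:
    """Total litres of one stock movement across the scope's reports."""
    _require_reports(reports, field)
    total = sum(getattr(r, field) for r in reports)
    return _value(
        field + "_litres", scope, key,
        _period_span(reports), total, "litres",
    )


def cylinder_census(
    reports: Sequence[MonthlyReport], scope: str = "national", key: str = "national"
) -> IndicatorValue:
    """Total 7500 L cylinders on hand, whether containing oxygen or not."""
    _require_reports(reports, "cylinder_census")
    total = sum(r.cylinders_7500 for r in reports)
    return _value(
        "cylinders_7500_count", scope, key, _period_span(reports), float(total), "count"
    )


def compute_all(
    reports: Sequence[MonthlyReport],
    scope: str = "national",
    key: str = "national",
    quarter: Sequence[str] | None = None,
    category_of: Mapping[str, str] | None = None,
) -> list[IndicatorValue]:
    """Compute the full indicator set for one scope.

    ``quarter`` (three 'YYYY-MM' periods) defaults to the panel's first three
    months when at least three are present, otherwise all its months.
    """
    _require_reports(reports, "compute_all")
    if quarter is None:
        months = sorted({r.period for r in reports})
        quarter = months[:3]
    out: list[IndicatorValue] = [
        pct_with_hypoxaemia_dept(reports, scope, key),
        mean_stockout_days(reports, quarter, scope, key),
    ]
    for field in ("oxygen_opening", "oxygen_received", "oxygen_consumed", "oxygen_lost"):
        out.append(stock_total(reports, field, scope, key))
    out.extend(proportion_functional(reports, "pulse_oximeter", scope, key))
    out.extend(proportion_functional(reports, "respirator", scope, key, category_of))
    out.extend(proportion_functional(reports, "generator", scope, key, category_of))
    out.append(cylinder_census(reports, scope, key))
    out.append(pct_staff_trained(reports, scope, key))
    out.append(oxygen_therapy_coverage(reports, scope, key))
    out.append(therapeutic_success(reports, scope, key))
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

REPORT_COLUMNS = list(MonthlyReport.model_fields)


def load_reports(source: str | Path | pd.DataFrame) -> list[MonthlyReport]:
    """Read a monthly-report panel CSV (one row per facility-month)."""
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(
        source, dtype={"facility_id": str, "period": str},
        float_precision="round_trip",
    )
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"reports: missing required column(s) {missing}")
    return [
        MonthlyReport(**{k: row[k] for k in REPORT_COLUMNS})
        for row in df.to_dict("records")
    ]


def write_reports(reports: Sequence[MonthlyReport], path: str | Path) -> None:
    # %.17g keeps litre quantities exact through a CSV round-trip
    pd.DataFrame([r.model_dump() for r in reports]).to_csv(
        path, index=False, float_format="%.17g"
    )


def indicator_frame(values: Iterable[IndicatorValue]) -> pd.DataFrame:
    values = list(values)
    return pd.DataFrame(
        {
            "indicator_id": [v.indicator_id for v in values],
            "scope": [v.scope for v in values],
            "key": [v.key for v in values],
            "period": [v.period for v in values],
            "value": [v.value for v in values],
            "unit": [v.unit for v in values],
            "status": [v.status for v in values],
        }
    )
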