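"""Domain types, default assumption registries, and validation.

The quantification model rests on three small tables of parameters:

* ward-level clinical assumptions — hypoxaemia prevalence among admitted
  patients, the typical oxygen flow rate prescribed, and the duration of
  therapy for one typical hypoxaemic case;
* facility-type parameters — how many facilities of each category exist,
  their total bed complement, and the annual bed turnover rate (admitted
  patients per bed per year);
* per-facility records — category, region, bed allocation per ward, and an
  equipment inventory.

Registries are plain mappings keyed by ward / facility-type name, validated
with pydantic and loadable from CSV or config dictionaries.  Shipped defaults
cover nine standard hospital wards and the four hospital categories of the
Cameroonian national assessment; both vocabularies are open, so user-defined
wards (e.g. a COVID treatment ward) and facility types slot in without code
changes.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Literal, Mapping, Union

import pandas as pd
from pydantic import BaseModel, Field, NonNegativeFloat, NonNegativeInt, model_validator

__all__ = [
    "WardAssumptions",
    "FacilityTypeParams",
    "DeviceCount",
    "EquipmentInventory",
    "FacilityRecord",
    "DemandResult",
    "DEFAULT_REGIONS",
    "default_assumptions",
    "default_facility_type_params",
    "load_assumptions",
    "load_facility_type_params",
    "write_assumptions",
    "write_facility_type_params",
    "mean_turnover",
    "bed_weighted_turnover",
]

#: Default administrative regions.  The arithmetic never depends on the
#: labels; real region names can be supplied wherever a region list is taken.
DEFAULT_REGIONS: tuple[str, ...] = tuple(f"R{i:02d}" for i in range(1, 11))

DEVICE_CLASSES = (
    "oxygen_concentrator",
    "pulse_oximeter",
    "patient_monitor",
    "oxygen_cylinder",
)

#: Default gaseous-oxygen capacity of one large cylinder, in litres.
DEFAULT_CYLINDER_SIZE = 7500.0


class WardAssumptions(BaseModel):
    """Clinical parameters of one ward type.

    Prevalence is stored as a fraction in [0, 1] (percent columns are divided
    by 100 on load); therapy duration is stored in hours.
    """

    ward_name: str
    hypoxaemia_prevalence: float = Field(ge=0.0, le=1.0)
    flow_rate: NonNegativeFloat  # litres per minute
    therapy_duration: NonNegativeFloat  # hours

    @model_validator(mode="after")
    def _finite(self) -> "WardAssumptions":
        for f in ("hypoxaemia_prevalence", "flow_rate", "therapy_duration"):
            if not math.isfinite(getattr(self, f)):
                raise ValueError(f"{self.ward_name}: {f} must be finite")
        return self


class FacilityTypeParams(BaseModel):
    """Per facility category: count, total beds, annual bed turnover."""

    type_name: str
    facility_count: NonNegativeInt
    total_beds: NonNegativeInt
    annual_bed_turnover: NonNegativeFloat  # patients per bed per year


class DeviceCount(BaseModel):
    """Functional / total split for one device class."""

    functional: NonNegativeInt = 0
    total: NonNegativeInt = 0

    @model_validator(mode="after")
    def _functional_le_total(self) -> "DeviceCount":
        if self.functional > self.total:
            raise ValueError(
                f"functional ({self.functional}) exceeds total ({self.total})"
            )
        return self


class EquipmentInventory(BaseModel):
    """Equipment holdings of one facility, split functional/total per class."""

    oxygen_concentrators: DeviceCount = Field(default_factory=DeviceCount)
    pulse_oximeters: DeviceCount = Field(default_factory=DeviceCount)
    patient_monitors: DeviceCount = Field(default_factory=DeviceCount)
    oxygen_cylinders: DeviceCount = Field(default_factory=DeviceCount)
    cylinder_size: float = Field(default=DEFAULT_CYLINDER_SIZE, gt=0.0)

    def functional_cylinder_litres(self) -> float:
        """Gaseous-oxygen capacity held in functional cylinders, litres."""
        return self.oxygen_cylinders.functional * self.cylinder_size


class FacilityRecord(BaseModel):
    """One health facility: category, region, ward bed allocation, equipment."""

    facility_id: str
    facility_type: str
    region: str
    ward_beds: dict[str, NonNegativeInt] = Field(default_factory=dict)
    equipment: EquipmentInventory = Field(default_factory=EquipmentInventory)

    def total_beds(self) -> int:
        return sum(self.ward_beds.values())


Grouping = Literal["ward", "facility", "facility_type", "region", "national"]


class DemandResult(BaseModel):
    """Oxygen demand at one aggregation level.

    ``monthly_litres`` is derived as ``annual_litres / 12`` — the only
    convention consistent with annual bed-turnover rates.
    """

    grouping: Grouping
    group_key: str
    annual_litres: NonNegativeFloat
    expected_hypoxaemic_patients: NonNegativeFloat

    @property
    def monthly_litres(self) -> float:
        return self.annual_litres / 12.0


# ---------------------------------------------------------------------------
# Shipped defaults
# ---------------------------------------------------------------------------

_DEFAULT_ASSUMPTION_ROWS = [
    # ward, prevalence (fraction), flow L/min, duration hours
    ("outpatient", 0.00, 5.0, 1.0),
    ("adult_medicine", 0.06, 6.0, 144.0),
    ("paediatrics", 0.10, 2.0, 72.0),
    ("neonatology", 0.20, 2.0, 72.0),
    ("intensive_care", 1.00, 6.0, 96.0),
    ("operating_theatre", 1.00, 8.0, 6.0),
    ("emergency", 0.40, 6.0, 16.0),
    ("maternity", 0.13, 5.0, 12.0),
    ("recovery", 1.00, 5.0, 6.0),
]

_DEFAULT_TYPE_ROWS = [
    # type, facility count, beds, annual bed turnover
    ("general", 4, 919, 41.0),
    ("central", 13, 2595, 96.0),
    ("regional", 15, 2487, 72.0),
    ("district", 67, 5090, 58.0),
]


def default_assumptions() -> dict[str, WardAssumptions]:
    """Built-in clinical assumption registry for the nine standard wards."""
    return {
        name: WardAssumptions(
            ward_name=name,
            hypoxaemia_prevalence=prev,
            flow_rate=flow,
            therapy_duration=dur,
        )
        for name, prev, flow, dur in _DEFAULT_ASSUMPTION_ROWS
    }


def default_facility_type_params() -> dict[str, FacilityTypeParams]:
    """Built-in facility-type registry for the four hospital categories."""
    return {
        name: FacilityTypeParams(
            type_name=name,
            facility_count=count,
            total_beds=beds,
            annual_bed_turnover=turnover,
        )
        for name, count, beds, turnover in _DEFAULT_TYPE_ROWS
    }


# ---------------------------------------------------------------------------
# Loading / writing
# ---------------------------------------------------------------------------

Source = Union[str, Path, pd.DataFrame, Mapping, None]

_DURATION_FACTORS = {"hours": 1.0, "days": 24.0}


def _as_dataframe(source: Source, required: Iterable[str], what: str) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    elif isinstance(source, Mapping):
        df = pd.DataFrame(source)
    else:
        df = pd.read_csv(source, dtype={0: str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s) {missing}")
    return df


def load_assumptions(source: Source = None) -> dict[str, WardAssumptions]:
    """Load a ward assumption registry.

    ``source`` may be a CSV path with header
    ``ward,prevalence_pct,flow_lpm,duration,duration_unit``
    (``duration_unit`` in {hours, days}), a DataFrame, or a mapping of the
    same keys.  With no source, returns the built-in defaults.  The percent
    prevalence column is converted to a fraction; day durations to hours.
    """
    if source is None:
        return default_assumptions()
    df = _as_dataframe(
        source, ["ward", "prevalence_pct", "flow_lpm", "duration", "duration_unit"],
        "assumptions",
    )
    registry: dict[str, WardAssumptions] = {}
    for i, row in df.iterrows():
        ward = str(row["ward"])
        if ward in registry:
            raise ValueError(f"assumptions row {i}: duplicate ward {ward!r}")
        unit = str(row["duration_unit"]).strip().lower()
        if unit not in _DURATION_FACTORS:
            raise ValueError(
                f"assumptions row {i} ({ward}): duration_unit must be one of "
                f"{sorted(_DURATION_FACTORS)}, got {unit!r}"
            )
        try:
            registry[ward] = WardAssumptions(
                ward_name=ward,
                hypoxaemia_prevalence=float(row["prevalence_pct"]) / 100.0,
                flow_rate=float(row["flow_lpm"]),
                therapy_duration=float(row["duration"]) * _DURATION_FACTORS[unit],
            )
        except ValueError as exc:
            raise ValueError(f"assumptions row {i} ({ward}): {exc}") from exc
    return registry


def write_assumptions(registry: Mapping[str, WardAssumptions], path: str | Path) -> None:
    """Write a registry to the assumptions CSV format (hours, percent)."""
    pd.DataFrame(
        {
            "ward": [a.ward_name for a in registry.values()],
            "prevalence_pct": [a.hypoxaemia_prevalence * 100.0 for a in registry.values()],
            "flow_lpm": [a.flow_rate for a in registry.values()],
            "duration": [a.therapy_duration for a in registry.values()],
            "duration_unit": ["hours"] * len(registry),
        }
    ).to_csv(path, index=False)


def load_facility_type_params(source: Source = None) -> dict[str, FacilityTypeParams]:
    """Load a facility-type registry.

    CSV header: ``type,facility_count,total_beds,annual_bed_turnover``.
    With no source, returns the built-in four-category defaults.
    An empty table yields an empty registry.
    """
    if source is None:
        return default_facility_type_params()
    df = _as_dataframe(
        source, ["type", "facility_count", "total_beds", "annual_bed_turnover"],
        "facility types",
    )
    registry: dict[str, FacilityTypeParams] = {}
    for i, row in df.iterrows():
        name = str(row["type"])
        if name in registry:
            raise ValueError(f"facility types row {i}: duplicate type {name!r}")
        try:
            registry[name] = FacilityTypeParams(
                type_name=name,
                facility_count=int(row["facility_count"]),
                total_beds=int(row["total_beds"]),
                annual_bed_turnover=float(row["annual_bed_turnover"]),
            )
        except ValueError as exc:
            raise ValueError(f"facility types row {i} ({name}): {exc}") from exc
    return registry


def write_facility_type_params(
    registry: Mapping[str, FacilityTypeParams], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "type": [p.type_name for p in registry.values()],
            "facility_count": [p.facility_count for p in registry.values()],
            "total_beds": [p.total_beds for p in registry.values()],
            "annual_bed_turnover": [p.annual_bed_turnover for p in registry.values()],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Registry statistics
# ---------------------------------------------------------------------------


def mean_turnover(registry: Mapping[str, FacilityTypeParams]) -> float:
    """Unweighted arithmetic mean of annual bed turnover across facility types.

    This matches the convention of averaging category-level rates directly,
    each category counting once regardless of its bed complement.
    """
    if not registry:
        raise ValueError("mean_turnover: empty facility-type registry")
    values = [p.annual_bed_turnover for p in registry.values()]
    return sum(values) / len(values)


def bed_weighted_turnover(registry: Mapping[str, FacilityTypeParams]) -> float:
    """Bed-weighted mean turnover — the average rate an admitted bed sees."""
    if not registry:
        raise ValueError("bed_weighted_turnover: empty facility-type registry")
    beds = sum(p.total_beds for p in registry.values())
    if beds == 0:
        raise ValueError("bed_weighted_turnover: registry has zero beds")
    return sum(p.annual_bed_turnover * p.total_beds for p in registry.values()) / beds
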