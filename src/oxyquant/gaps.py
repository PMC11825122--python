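"""Equipment gap analysis: coverage ratios, absolute gaps, cylinder equivalents.

Device requirements (how many concentrators, oximeters or monitors a scope
needs) come from planning norms supplied as inputs; they are never derived
from litres.  Oxygen cylinders are the exception: their requirement is
natively volumetric, so a demand volume is compared against the capacity of
functional cylinders on hand and the shortfall expressed either in litres or
as cylinder equivalents.

Gaps are clamped at zero within the scope at which they are computed; a
surplus in one region never offsets a deficit in another unless pooling is
requested explicitly.  Consequently clamped gaps are not additive across
scopes: the sum of regional clamped gaps can exceed the national clamped gap.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, NonNegativeFloat, NonNegativeInt

from .domain import DEFAULT_CYLINDER_SIZE, EquipmentInventory, FacilityRecord

__all__ = [
    "EquipmentRequirement",
    "GapReport",
    "coverage",
    "cylinder_equivalents",
    "cylinder_volume_gap",
    "equipment_gaps",
    "load_inventory",
    "write_inventory",
    "gap_frame",
]

#: Coverage value reported when a scope holds equipment it has no computed
#: requirement for (required = 0, available > 0).
SURPLUS = math.inf

Scope = Literal["facility", "region", "facility_type", "national"]
ConversionMode = Literal["exact", "procurement", "reporting"]


class EquipmentRequirement(BaseModel):
    device_class: str
    required: NonNegativeFloat
    available_functional: NonNegativeInt
    scope: Scope
    key: str


class GapReport(BaseModel):
    scope: Scope
    key: str
    device_class: str
    required: NonNegativeFloat
    available_functional: NonNegativeInt
    coverage_fraction: NonNegativeFloat
    absolute_gap: NonNegativeFloat
    volume_gap_litres: float | None = None  # cylinders only


def coverage(available: float, required: float) -> tuple[float, float]:
    """Coverage fraction and zero-clamped absolute gap.

    With no requirement and nothing on hand, coverage is vacuously 1; with
    stock but no requirement it is the ``SURPLUS`` sentinel (infinite).
    Coverage above 1 always implies a zero gap.
    """
    if available < 0 or required < 0:
        raise ValueError("coverage: counts must be >= 0")
    if required == 0:
        return (1.0 if available == 0 else SURPLUS), 0.0
    return available / required, max(required - available, 0.0)


def cylinder_equivalents(
    volume_litres: float,
    cylinder_size: float = DEFAULT_CYLINDER_SIZE,
    mode: ConversionMode = "exact",
) -> float:
    """Express an oxygen volume as a number of standard cylinders.

    ``exact`` divides; ``procurement`` takes the ceiling (you cannot buy a
    fraction of a cylinder); ``reporting`` rounds the exact quotient to three
    significant figures, the convention used for headline figures (140
    million litres in 7 500 L cylinders reads as 18 700).
    """
    if cylinder_size <= 0:
        raise ValueError("cylinder_equivalents: cylinder_size must be > 0")
    if volume_litres < 0:
        raise ValueError("cylinder_equivalents: volume must be >= 0")
    exact = volume_litres / cylinder_size
    if mode == "exact":
        return exact
    if mode == "procurement":
        return float(math.ceil(exact))
    if mode == "reporting":
        return round_sig(exact, 3)
    raise ValueError(f"cylinder_equivalents: unknown mode {mode!r}")


def round_sig(x: float, figures: int = 3) -> float:
    """Round to a number of significant figures (half away from zero)."""
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    factor = 10.0 ** (exponent - figures + 1)
    return math.floor(abs(x) / factor + 0.5) * factor * math.copysign(1.0, x)


def cylinder_volume_gap(demand_litres: float, inventory: EquipmentInventory) -> float:
    """Unmet oxygen volume after counting functional cylinder capacity."""
    if demand_litres < 0:
        raise ValueError("cylinder_volume_gap: demand must be >= 0")
    return max(demand_litres - inventory.functional_cylinder_litres(), 0.0)


def _scope_key(facility: FacilityRecord, scope: Scope) -> str:
    if scope == "facility":
        return facility.facility_id
    if scope == "region":
        return facility.region
    if scope == "facility_type":
        return facility.facility_type
    return "national"

_INVENTORY_FIELDS = {
    "oxygen_concentrator": "oxygen_concentrators",
    "pulse_oximeter": "pulse_oximeters",
    "patient_monitor": "patient_monitors",
    "oxygen_cylinder": "oxygen_cylinders",
}


def equipment_gaps(
    roster: Sequence[FacilityRecord],
    requirements: Mapping[tuple[str, str], float],
    scope: Scope,
    demand_by_key: Mapping[str, float] | None = None,
) -> list[GapReport]:
    """Compare functional stock against requirements at one declared scope.

    ``requirements`` maps (scope key, device_class) -> required count; device
    classes absent from the mapping are skipped except oxygen cylinders,
    whose requirement is derived from ``demand_by_key`` (annual litres per
    scope key) when given.  Clamping happens at this scope only.
    """
    stock: dict[tuple[str, str], int] = {}
    cyl_litres: dict[str, float] = {}
    for f in roster:
        key = _scope_key(f, scope)
        for device, attr in _INVENTORY_FIELDS.items():
            dc = getattr(f.equipment, attr)
            stock[(key, device)] = stock.get((key, device), 0) + dc.functional
        cyl_litres[key] = (
            cyl_litres.get(key, 0.0) + f.equipment.functional_cylinder_litres()
        )

    reports: list[GapReport] = []
    keys = sorted({k for k, _ in stock})
    for key in keys:
        for device in _INVENTORY_FIELDS:
            available = stock.get((key, device), 0)
            volume_gap = None
            if device == "oxygen_cylinder" and demand_by_key is not None:
                demand = demand_by_key.get(key, 0.0)
                required = demand / DEFAULT_CYLINDER_SIZE
                volume_gap = max(demand - cyl_litres.get(key, 0.0), 0.0)
            elif (key, device) in requirements:
                required = requirements[(key, device)]
            else:
                continue
            cov, gap = coverage(available, required)
            reports.append(
                GapReport(
                    scope=scope,
                    key=key,
                    device_class=device,
                    required=required,
                    available_functional=available,
                    coverage_fraction=cov,
                    absolute_gap=gap,
                    volume_gap_litres=volume_gap,
                )
            )
    return reports


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

INVENTORY_COLUMNS = ["facility_id", "device_class", "functional", "total", "cylinder_size"]


def load_inventory(
    source: str | Path | pd.DataFrame,
) -> dict[str, EquipmentInventory]:
    """Read an inventory CSV into per-facility ``EquipmentInventory`` objects."""
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in INVENTORY_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"inventory: missing required column(s) {missing}")
    out: dict[str, EquipmentInventory] = {}
    for fid, grp in df.groupby("facility_id", sort=False):
        kwargs: dict = {}
        for _, row in grp.iterrows():
            device = str(row["device_class"])
            if device not in _INVENTORY_FIELDS:
                raise ValueError(f"inventory: unknown device class {device!r}")
            kwargs[_INVENTORY_FIELDS[device]] = {
                "functional": int(row["functional"]),
                "total": int(row["total"]),
            }
            if device == "oxygen_cylinder" and "cylinder_size" in grp.columns:
                size = row["cylinder_size"]
                if pd.notna(size):
                    kwargs["cylinder_size"] = float(size)
        out[str(fid)] = EquipmentInventory(**kwargs)
    return out


def write_inventory(
    inventories: Mapping[str, EquipmentInventory], path: str | Path
) -> None:
    rows = []
    for fid, inv in inventories.items():
        for device, attr in _INVENTORY_FIELDS.items():
            dc = getattr(inv, attr)
            size = inv.cylinder_size if device == "oxygen_cylinder" else None
            rows.append((fid, device, dc.functional, dc.total, size))
    pd.DataFrame(rows, columns=INVENTORY_COLUMNS).to_csv(path, index=False)


def gap_frame(reports: Iterable[GapReport]) -> pd.DataFrame:
    reports = list(reports)
    return pd.DataFrame(
        {
            "scope": [r.scope for r in reports],
            "key": [r.key for r in reports],
            "device_class": [r.device_class for r in reports],
            "required": [r.required for r in reports],
            "available_functional": [r.available_functional for r in reports],
            "coverage": [r.coverage_fraction for r in reports],
            "absolute_gap": [r.absolute_gap for r in reports],
            "volume_gap_litres": [r.volume_gap_litres for r in reports],
        }
    )
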