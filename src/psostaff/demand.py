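"""Referral demand, FTE requirements, and the staffing-ratio planning table.

Program incidence converts to psychosocial-oncology referral demand through
the prevalence of distress: a minimum of 35% of new cancer patients are
expected to need specialized PSO services (up to 40% in the Fitch
supportive-care model; 100% models specialized clinics with automatic
referral).  The FTE requirement is referral volume divided by the per-FTE
new-patient capacity, and program totals scale the per-FTE caseload and
contact counts by the rounded FTE figure exactly as a planning table is
read: all arithmetic here is decimal with half-up rounding, two decimals
for FTE and whole numbers for patient/contact counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from ._round import to_decimal
from .capacity import CapacityResult, compute_capacity
from .errors import ZeroCapacityError
from .profiles import StaffingProfile

#: Minimum fraction of new cancer patients expected to need specialized care.
DEFAULT_REFERRAL_RATE = 0.35


class DemandSpec(BaseModel):
    """Annual new cancer cases and the referral (distress-prevalence) rate."""

    model_config = ConfigDict(extra="forbid")

    annual_new_cases: int = Field(ge=0)
    referral_rate: float = Field(default=DEFAULT_REFERRAL_RATE, ge=0, le=1)


@dataclass(frozen=True)
class FtePlan:
    """One planning-table row: demand, requirement, and program totals."""

    expected_referrals: int
    fte_required: float
    program_unique_cases: int
    program_dpcc: int


def expected_referrals(spec: DemandSpec) -> int:
    """Expected annual PSO referral volume, rounded half-up to whole patients."""
    n = to_decimal(spec.annual_new_cases) * to_decimal(spec.referral_rate)
    return int(n.quantize(Decimal(1), rounding=ROUND_HALF_UP))


def fte_required(referrals: int, capacity: CapacityResult) -> float:
    """FTE positions needed for a referral volume, half-up at two decimals."""
    if capacity.new_patient_capacity <= 0:
        raise ZeroCapacityError(
            "profile has zero new-patient capacity; increase DPC hours or "
            "reduce fixed commitments before computing an FTE ratio"
        )
    ratio = to_decimal(referrals) / to_decimal(capacity.new_patient_capacity)
    return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def program_totals(fte: float, capacity: CapacityResult) -> tuple[int, int]:
    """Program-level unique cases and DPCCs from a 2-decimal FTE figure.

    Uses the printed-precision FTE (as a planning table is read), so
    totals match what a reader recomputes from the table's own cells.
    """
    if fte < 0:
        raise ValueError("fte must be non-negative")
    f = to_decimal(fte)
    unique = (f * to_decimal(capacity.total_unique_caseload)).quantize(
        Decimal(1), rounding=ROUND_HALF_UP
    )
    dpcc = (f * to_decimal(capacity.total_dpcc)).quantize(
        Decimal(1), rounding=ROUND_HALF_UP
    )
    return int(unique), int(dpcc)


def plan(profile: StaffingProfile, spec: DemandSpec) -> FtePlan:
    """Full demand-to-staffing chain for one profile and one demand level."""
    cap = compute_capacity(profile)
    refs = expected_referrals(spec)
    fte = fte_required(refs, cap)
    unique, dpcc = program_totals(fte, cap)
    return FtePlan(
        expected_referrals=refs,
        fte_required=fte,
        program_unique_cases=unique,
        program_dpcc=dpcc,
    )


#: Planning-table column order: letters a-i with readable names.
TABLE_COLUMNS = [
    "panel",
    "a_new_cases",
    "b_referrals",
    "c_capacity_per_fte",
    "d_fte_required",
    "e_carryover_per_fte",
    "f_unique_per_fte",
    "g_dpcc_per_fte",
    "h_program_unique",
    "i_program_dpcc",
]


def build_table(
    case_volumes: list[int],
    profiles: list[StaffingProfile],
    referral_rate: float = DEFAULT_REFERRAL_RATE,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Staffing-ratio planning table: one panel per profile, one row per volume.

    Column d is always ``round2(b / c)`` — the table is internally
    consistent by construction — and columns h and i are recomputed from
    that two-decimal figure.
    """
    if not case_volumes or not profiles:
        raise ValueError("case_volumes and profiles must be non-empty")
    if labels is None:
        labels = [
            f"{p.split.dpc_fraction:.0%} DPC / {p.split.ipc_fraction:.0%} IPC, "
            f"{p.groups.groups_per_year} groups"
            for p in profiles
        ]
    rows = []
    for label, profile in zip(labels, profiles):
        cap = compute_capacity(profile)
        for cases in case_volumes:
            spec = DemandSpec(annual_new_cases=cases, referral_rate=referral_rate)
            refs = expected_referrals(spec)
            fte = fte_required(refs, cap)
            unique, dpcc = program_totals(fte, cap)
            rows.append(
                {
                    "panel": label,
                    "a_new_cases": cases,
                    "b_referrals": refs,
                    "c_capacity_per_fte": cap.new_patient_capacity,
                    "d_fte_required": fte,
                    "e_carryover_per_fte": cap.carryover_block.patients,
                    "f_unique_per_fte": cap.total_unique_caseload,
                    "g_dpcc_per_fte": cap.total_dpcc,
                    "h_program_unique": unique,
                    "i_program_dpcc": dpcc,
                }
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
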