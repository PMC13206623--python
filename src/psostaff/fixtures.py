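"""Synthetic per-contact workload-measurement logs.

A workload measurement system records one row per direct-patient-care
contact.  :func:`generate_log` emits a full synthetic fiscal year of such
records whose per-block aggregates equal the deterministic capacity model
scaled by the staffed FTE, so aggregation code and end-to-end runs can be
exercised without any real service data.  :func:`aggregate_log` recovers
an observed-capacity summary from any record list, applying the carryover
counting rule: a case opened in a prior fiscal year counts as carryover
only if the patient is actually seen again in the new fiscal year.

Log interchange format is CSV with ISO-8601 dates, one documented header.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from ._round import round_half_up_int
from .capacity import CapacityResult, compute_capacity
from .profiles import StaffingProfile

#: Default fiscal-year start (April 1; January 1 is the common alternative).
DEFAULT_FISCAL_YEAR_START = date(2025, 4, 1)

CSV_HEADER = ["patient_id", "contact_type", "duration", "date", "provider_id", "case_status"]

ContactType = Literal[
    "assessment",
    "counseling_followup",
    "instrumental",
    "group_session",
    "carryover_followup",
]


class ContactRecord(BaseModel):
    """One direct-patient-care contact in a workload-measurement log."""

    model_config = ConfigDict(extra="forbid")

    patient_id: str
    contact_type: ContactType
    duration: float = Field(gt=0, description="Contact length in hours")
    date: date
    provider_id: str
    case_status: Literal["open", "closed"]


@dataclass(frozen=True)
class WorkloadSummary:
    """Observed capacity aggregated from a contact log for one fiscal year."""

    fiscal_year_start: date
    unique_patients: int
    total_contacts: int
    total_hours: float
    contacts_by_type: dict[str, int] = field(default_factory=dict)
    carryover_cases: int = 0
    new_patients: int = 0


def scaled_block_counts(capacity: CapacityResult, fte: float) -> dict[str, int]:
    """Per-block unique-patient counts for a program staffed at ``fte``.

    Patients are rounded half-up per block; contacts follow as whole
    patients times the per-patient contact count, so a generated log is
    exactly consistent with these figures.
    """
    return {
        "group": round_half_up_int(fte * capacity.group_block.unique_patients),
        "counseling": round_half_up_int(fte * capacity.counseling_block.unique_patients),
        "instrumental": round_half_up_int(fte * capacity.instrumental_block.unique_patients),
        "carryover": round_half_up_int(fte * capacity.carryover_block.patients),
    }


def _fiscal_year_end(start: date) -> date:
    return start.replace(year=start.year + 1) - timedelta(days=1)


def generate_log(
    profile: StaffingProfile,
    fte: float,
    seed: int,
    fiscal_year_start: date = DEFAULT_FISCAL_YEAR_START,
) -> list[ContactRecord]:
    """Generate one synthetic fiscal year of contact records.

    Aggregate counts equal ``scaled_block_counts(compute_capacity(profile),
    fte)`` per block, with contact durations taken from the profile
    (counseling assessments absorb the per-patient hours in excess of the
    standard one-hour follow-ups).  Deterministic for a given seed.
    """
    if fte <= 0:
        raise ValueError("fte must be positive")
    cap = compute_capacity(profile)
    counts = scaled_block_counts(cap, fte)
    rng = np.random.default_rng(seed)
    fy_start, fy_end = fiscal_year_start, _fiscal_year_end(fiscal_year_start)
    span = (fy_end - fy_start).days

    n_providers = max(1, round_half_up_int(fte))
    providers = [f"SW{i + 1:02d}" for i in range(n_providers)]

    def _rand_date(lo_frac: float = 0.0, hi_frac: float = 0.85) -> date:
        return fy_start + timedelta(days=int(rng.integers(int(span * lo_frac), int(span * hi_frac))))

    records: list[ContactRecord] = []
    pid = 0

    def _next_pid(prefix: str) -> str:
        nonlocal pid
        pid += 1
        return f"{prefix}{pid:05d}"

    mix = profile.mix
    # individual counseling streams: one assessment then 1-h follow-ups
    for _ in range(counts["counseling"]):
        patient = _next_pid("P")
        provider = providers[int(rng.integers(n_providers))]
        first = _rand_date()
        n_contacts = mix.counseling_contacts_per_patient
        assess_h = max(mix.counseling_hours_per_patient - (n_contacts - 1) * 1.0, 0.5)
        records.append(
            ContactRecord(
                patient_id=patient, contact_type="assessment", duration=assess_h,
                date=first, provider_id=provider, case_status="open",
            )
        )
        for k in range(1, n_contacts):
            records.append(
                ContactRecord(
                    patient_id=patient, contact_type="counseling_followup", duration=1.0,
                    date=min(first + timedelta(days=7 * k), fy_end),
                    provider_id=provider,
                    case_status="closed" if k == n_contacts - 1 else "open",
                )
            )
    # instrumental/advocacy streams
    for _ in range(counts["instrumental"]):
        patient = _next_pid("P")
        provider = providers[int(rng.integers(n_providers))]
        first = _rand_date()
        n_contacts = mix.instrumental_contacts_per_patient
        assess_h = max(mix.instrumental_hours_per_patient - (n_contacts - 1) * 1.0, 0.5)
        records.append(
            ContactRecord(
                patient_id=patient, contact_type="assessment", duration=assess_h,
                date=first, provider_id=provider, case_status="open",
            )
        )
        for k in range(1, n_contacts):
            records.append(
                ContactRecord(
                    patient_id=patient, contact_type="instrumental", duration=1.0,
                    date=min(first + timedelta(days=7 * k), fy_end),
                    provider_id=provider,
                    case_status="closed" if k == n_contacts - 1 else "open",
                )
            )
    # therapeutic-group participants: one contact per attended session
    sessions = profile.groups.sessions_per_group
    fac_h = profile.groups.facilitation_hours_per_session
    for _ in range(counts["group"]):
        patient = _next_pid("G")
        provider = providers[int(rng.integers(n_providers))]
        first = _rand_date(0.0, 0.7)
        for k in range(sessions):
            records.append(
                ContactRecord(
                    patient_id=patient, contact_type="group_session", duration=fac_h,
                    date=min(first + timedelta(days=7 * k), fy_end),
                    provider_id=provider,
                    case_status="closed" if k == sessions - 1 else "open",
                )
            )
    # carryover caseload: prior-year cases seen again this fiscal year
    co = profile.carryover
    co_h = co.hours_per_patient / co.contacts_per_patient
    for _ in range(counts["carryover"]):
        patient = _next_pid("C")
        provider = providers[int(rng.integers(n_providers))]
        first = _rand_date(0.0, 0.5)
        for k in range(co.contacts_per_patient):
            records.append(
                ContactRecord(
                    patient_id=patient, contact_type="carryover_followup", duration=co_h,
                    date=min(first + timedelta(days=14 * k), fy_end),
                    provider_id=provider, case_status="open",
                )
            )
    records.sort(key=lambda r: (r.date, r.patient_id))
    return records


def aggregate_log(
    records: Sequence[ContactRecord],
    fiscal_year_start: date | None = None,
) -> WorkloadSummary:
    """Aggregate a contact log into an observed-capacity summary.

    Only contacts dated inside the fiscal year are counted, so a case
    whose contacts all precede the fiscal-year start contributes nothing
    — in particular it is *not* carryover, even if it is still open.  If
    ``fiscal_year_start`` is omitted it is inferred as the April-1-anchored
    fiscal year containing the latest record.
    """
    if not records:
        start = fiscal_year_start or DEFAULT_FISCAL_YEAR_START
        return WorkloadSummary(
            fiscal_year_start=start, unique_patients=0, total_contacts=0,
            total_hours=0.0, contacts_by_type={}, carryover_cases=0, new_patients=0,
        )
    if fiscal_year_start is None:
        latest = max(r.date for r in records)
        year = latest.year if latest.month >= 4 else latest.year - 1
        fiscal_year_start = date(year, 4, 1)
    fy_end = _fiscal_year_end(fiscal_year_start)

    in_year = [r for r in records if fiscal_year_start <= r.date <= fy_end]
    by_type: dict[str, int] = {}
    patients: set[str] = set()
    carryover: set[str] = set()
    hours = 0.0
    for r in in_year:
        by_type[r.contact_type] = by_type.get(r.contact_type, 0) + 1
        patients.add(r.patient_id)
        hours += r.duration
        if r.contact_type == "carryover_followup":
            carryover.add(r.patient_id)
    # cases opened before the fiscal year and seen again inside it are
    # carryover even if the log does not type them as such
    first_contact: dict[str, date] = {}
    for r in records:
        if r.patient_id not in first_contact or r.date < first_contact[r.patient_id]:
            first_contact[r.patient_id] = r.date
    for p in patients:
        if first_contact[p] < fiscal_year_start:
            carryover.add(p)
    return WorkloadSummary(
        fiscal_year_start=fiscal_year_start,
        unique_patients=len(patients),
        total_contacts=len(in_year),
        total_hours=hours,
        contacts_by_type=by_type,
        carryover_cases=len(carryover),
        new_patients=len(patients) - len(carryover),
    )


def write_log(records: Iterable[ContactRecord], path: str | Path) -> None:
    """Write a contact log as CSV with the documented header."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for r in records:
            writer.writerow(
                [r.patient_id, r.contact_type, r.duration, r.date.isoformat(),
                 r.provider_id, r.case_status]
            )


def read_log(path: str | Path) -> list[ContactRecord]:
    """Read a CSV contact log, validating every row."""
    records = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                records.append(ContactRecord.model_validate(row))
            except Exception as exc:
                raise ValueError(f"{path}, line {i}: invalid contact record: {exc}") from exc
    return records
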