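"""Per-FTE annual caseload capacity and direct-patient-care contacts.

The allocation cascade for one 1.0 FTE position:

1. net annual hours split into DPC and IPC by the care split;
2. therapeutic groups and the carryover caseload are fixed DPC
   commitments and are subtracted first;
3. the remaining DPC hours divide between counseling/psychotherapy and
   instrumental/advocacy work by the intervention mix's hour fractions;
4. each stream serves ``floor(hours / hours_per_patient)`` whole
   patients — fractional patients are not served, and the unbookable
   remainder is reported as ``slack_hours``, never silently dropped.

Hours are carried at full precision throughout; only patient and contact
counts are integers.  Every contact is a direct-patient-care contact
(DPCC) regardless of modality (in person, telephone, virtual).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigurationError, InfeasibleProfileError
from .hours import net_annual_hours
from .profiles import CarryoverPolicy, CareSplit, GroupProgram, InterventionMix, StaffingProfile


@dataclass(frozen=True)
class GroupBlock:
    hours: float
    unique_patients: int
    contacts: int


@dataclass(frozen=True)
class CarryoverBlock:
    patients: int
    hours: float
    contacts: int


@dataclass(frozen=True)
class InterventionBlock:
    hours_available: float
    unique_patients: int
    hours_used: float
    contacts: int


@dataclass(frozen=True)
class CapacityResult:
    """Annual outputs of one 1.0 FTE position under a staffing profile."""

    net_hours: float
    dpc_hours: float
    ipc_hours: float
    group_block: GroupBlock
    carryover_block: CarryoverBlock
    counseling_block: InterventionBlock
    instrumental_block: InterventionBlock

    @property
    def new_patient_capacity(self) -> int:
        """New patients per year: group + counseling + instrumental uniques."""
        return (
            self.group_block.unique_patients
            + self.counseling_block.unique_patients
            + self.instrumental_block.unique_patients
        )

    @property
    def total_unique_caseload(self) -> int:
        return self.new_patient_capacity + self.carryover_block.patients

    @property
    def total_dpcc(self) -> int:
        return (
            self.group_block.contacts
            + self.carryover_block.contacts
            + self.counseling_block.contacts
            + self.instrumental_block.contacts
        )

    @property
    def slack_hours(self) -> float:
        """DPC hours too fragmented to serve one more whole patient."""
        return self.dpc_hours - (
            self.group_block.hours
            + self.carryover_block.hours
            + self.counseling_block.hours_used
            + self.instrumental_block.hours_used
        )


def split_dpc(net_hours: float, split: CareSplit) -> tuple[float, float]:
    """Divide net hours into (DPC, IPC); fractional hours carry forward."""
    if net_hours <= 0:
        raise ValueError("net_hours must be positive")
    dpc = net_hours * split.dpc_fraction
    return dpc, net_hours - dpc


def group_block(groups: GroupProgram) -> GroupBlock:
    """Hours, unique patients, and contacts of the annual group program.

    Each attendee at each session counts as one contact for workload
    measurement; a zero-group program contributes nothing.
    """
    hours = groups.groups_per_year * (
        groups.prep_hours_per_group
        + groups.sessions_per_group * groups.facilitation_hours_per_session
    )
    unique = groups.groups_per_year * groups.participants_per_group
    contacts = groups.groups_per_year * groups.sessions_per_group * groups.participants_per_group
    return GroupBlock(hours=hours, unique_patients=unique, contacts=contacts)


def carryover_block(policy: CarryoverPolicy) -> CarryoverBlock:
    """Service hours and contacts owed to the prior-year carryover caseload."""
    if policy.mode == "explicit_count":
        patients = policy.explicit_count
    else:
        if policy.base_caseload is None:
            raise ConfigurationError(
                "carryover mode 'rate_of_base' requires base_caseload"
            )
        patients = math.floor(policy.rate * policy.base_caseload)
    return CarryoverBlock(
        patients=patients,
        hours=patients * policy.hours_per_patient,
        contacts=patients * policy.contacts_per_patient,
    )


def allocate_interventions(
    remaining_dpc_hours: float, mix: InterventionMix
) -> tuple[InterventionBlock, InterventionBlock]:
    """Split remaining DPC hours into counseling and instrumental blocks.

    Each stream's patient count is the floor of its hour pool divided by
    its per-patient hours; the remainder of each pool stays as slack.
    """
    if remaining_dpc_hours < 0:
        raise ValueError("remaining_dpc_hours must be non-negative")

    def _block(fraction: float, hours_pp: float, contacts_pp: int) -> InterventionBlock:
        available = remaining_dpc_hours * fraction
        patients = math.floor(available / hours_pp)
        return InterventionBlock(
            hours_available=available,
            unique_patients=patients,
            hours_used=patients * hours_pp,
            contacts=patients * contacts_pp,
        )

    counseling = _block(
        mix.counseling_hours_fraction,
        mix.counseling_hours_per_patient,
        mix.counseling_contacts_per_patient,
    )
    instrumental = _block(
        mix.instrumental_hours_fraction,
        mix.instrumental_hours_per_patient,
        mix.instrumental_contacts_per_patient,
    )
    return counseling, instrumental


def compute_capacity(
    profile: StaffingProfile, *, breaks_on_paid_days: bool = False
) -> CapacityResult:
    """Run the full allocation cascade for one 1.0 FTE position.

    Raises
    ------
    InfeasibleProfileError
        If group and carryover commitments exceed the DPC hours, naming
        the shortfall.
    """
    ledger = net_annual_hours(profile.calendar, breaks_on_paid_days=breaks_on_paid_days)
    net = ledger.net_available_hours
    dpc, ipc = split_dpc(net, profile.split)
    grp = group_block(profile.groups)
    co = carryover_block(profile.carryover)
    committed = grp.hours + co.hours
    if committed > dpc:
        raise InfeasibleProfileError(
            f"group + carryover commitments ({committed} h) exceed DPC hours "
            f"({dpc} h) by {committed - dpc} h"
        )
    counseling, instrumental = allocate_interventions(dpc - committed, profile.mix)
    return CapacityResult(
        net_hours=net,
        dpc_hours=dpc,
        ipc_hours=ipc,
        group_block=grp,
        carryover_block=co,
        counseling_block=counseling,
        instrumental_block=instrumental,
    )
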