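"""Hypothesis strategies for randomized valid model inputs."""

from __future__ import annotations

from hypothesis import strategies as st

from psostaff import (
    CarryoverPolicy,
    CareSplit,
    GroupProgram,
    InterventionMix,
    StaffingProfile,
    WorkCalendar,
)


@st.composite
def work_calendars(draw) -> WorkCalendar:
    hours_per_workday = draw(st.sampled_from([6.0, 7.0, 7.5, 8.0]))
    days_per_week = draw(st.integers(3, 5))
    weeks = draw(st.integers(45, 52))
    return WorkCalendar(
        weekly_hours=hours_per_workday * days_per_week,
        weeks_per_year=weeks,
        vacation_days=draw(st.integers(0, 25)),
        statutory_holiday_days=draw(st.integers(0, 13)),
        sick_days=draw(st.integers(0, 12)),
        education_days=draw(st.integers(0, 6)),
        daily_break_hours=draw(st.sampled_from([0.0, 0.25, 0.5])),
        hours_per_workday=hours_per_workday,
    )


@st.composite
def group_programs(draw) -> GroupProgram:
    return GroupProgram(
        groups_per_year=draw(st.integers(0, 4)),
        sessions_per_group=draw(st.integers(0, 8)),
        participants_per_group=draw(st.integers(0, 10)),
        prep_hours_per_group=draw(st.sampled_from([0.0, 1.0, 2.0, 4.0])),
        facilitation_hours_per_session=draw(st.sampled_from([0.0, 1.0, 1.5, 2.0])),
    )


@st.composite
def carryover_policies(draw) -> CarryoverPolicy:
    mode = draw(st.sampled_from(["explicit_count", "rate_of_base"]))
    return CarryoverPolicy(
        mode=mode,
        explicit_count=draw(st.integers(0, 80)),
        rate=draw(st.sampled_from([0.0, 0.1, 0.2, 0.3])),
        base_caseload=draw(st.integers(0, 400)),
        hours_per_patient=draw(st.sampled_from([1.0, 2.0, 4.0, 6.0])),
        contacts_per_patient=draw(st.integers(1, 6)),
    )


@st.composite
def intervention_mixes(draw) -> InterventionMix:
    return InterventionMix(
        counseling_hours_fraction=draw(st.sampled_from([0.0, 0.3, 0.5, 0.7, 1.0])),
        counseling_hours_per_patient=draw(st.sampled_from([2.0, 4.0, 6.0, 6.5, 8.0])),
        counseling_contacts_per_patient=draw(st.integers(1, 8)),
        instrumental_hours_per_patient=draw(st.sampled_from([1.0, 2.0, 3.0, 4.0])),
        instrumental_contacts_per_patient=draw(st.integers(1, 5)),
    )


@st.composite
def staffing_profiles(draw) -> StaffingProfile:
    return StaffingProfile(
        discipline=draw(st.sampled_from(["social work", "psychology", "dietetics"])),
        setting=draw(st.sampled_from(["tertiary", "regional", "community", "other"])),
        calendar=draw(work_calendars()),
        split=CareSplit(dpc_fraction=draw(st.sampled_from([0.5, 0.6, 0.7, 0.75, 0.8, 1.0]))),
        groups=draw(group_programs()),
        carryover=draw(carryover_policies()),
        mix=draw(intervention_mixes()),
        notes=draw(st.sampled_from(["", "generalist model"])),
    )
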