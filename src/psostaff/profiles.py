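"""Typed staffing-profile parameter model, packaged defaults, and config I/O.

A :class:`StaffingProfile` bundles everything the capacity model needs to
describe one 1.0 FTE position of a psychosocial-oncology (PSO) discipline:
the paid-hours calendar, the direct/indirect patient-care (DPC/IPC) time
split, the therapeutic-group program, the carryover-caseload policy, and
the counseling/instrumental intervention mix.  Profiles round-trip
losslessly through YAML or JSON config files and two defaults for a
social worker in a tertiary cancer center ship with the package.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigurationError, UnknownProfileError

SCHEMA_VERSION = 1


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class WorkCalendar(_StrictModel):
    """Paid-hours structure of one full-time position.

    All leave categories are expressed in days and converted to hours at
    ``hours_per_workday``.  Short/long-term disability and unpaid leaves
    are deliberately not fields: they fall outside predictable paid time
    off and are never deducted.
    """

    weekly_hours: float = Field(gt=0, description="Paid hours per week")
    weeks_per_year: float = Field(gt=0, description="Paid weeks per year")
    vacation_days: float = Field(ge=0)
    statutory_holiday_days: float = Field(ge=0)
    sick_days: float = Field(ge=0, description="Designated paid sick days per year")
    education_days: float = Field(ge=0, description="Paid professional-development days")
    daily_break_hours: float = Field(ge=0, description="Paid breaks/lunch per worked day")
    hours_per_workday: float = Field(gt=0)

    @property
    def days_per_week(self) -> float:
        """Workdays per week implied by the weekly hours; fractional for part-time."""
        return self.weekly_hours / self.hours_per_workday


class CareSplit(_StrictModel):
    """Fraction of net hours spent on direct patient care (DPC)."""

    dpc_fraction: float = Field(gt=0, le=1)

    @property
    def ipc_fraction(self) -> float:
        return 1.0 - self.dpc_fraction


class GroupProgram(_StrictModel):
    """Therapeutic-group commitments for one fiscal year.

    A closed therapeutic group runs ``sessions_per_group`` weekly sessions
    for a fixed cohort of ``participants_per_group`` patients; each
    attendee at each session is one direct-patient-care contact.
    """

    groups_per_year: int = Field(ge=0)
    sessions_per_group: int = Field(ge=0)
    participants_per_group: int = Field(ge=0)
    prep_hours_per_group: float = Field(ge=0)
    facilitation_hours_per_session: float = Field(ge=0)


class CarryoverPolicy(_StrictModel):
    """Patients carried over from the previous fiscal year.

    Two modes: ``explicit_count`` takes the carryover caseload as given;
    ``rate_of_base`` applies ``rate`` to a prior-year ``base_caseload``
    (floored, as partial patients are not served).  Each carryover patient
    receives ``hours_per_patient`` of service in ``contacts_per_patient``
    appointments.
    """

    mode: Literal["explicit_count", "rate_of_base"] = "explicit_count"
    explicit_count: int = Field(default=0, ge=0)
    rate: float = Field(default=0.0, ge=0, lt=1)
    base_caseload: int | None = Field(default=None, ge=0)
    hours_per_patient: float = Field(gt=0)
    contacts_per_patient: int = Field(gt=0)

    @model_validator(mode="after")
    def _check_mode_fields(self) -> "CarryoverPolicy":
        if self.mode == "rate_of_base" and self.base_caseload is None:
            raise ValueError(
                "carryover mode 'rate_of_base' requires base_caseload to be set"
            )
        return self


class InterventionMix(_StrictModel):
    """How remaining DPC hours divide between counseling and instrumental work.

    ``counseling_hours_fraction`` of the hours left after groups and
    carryover goes to counseling/psychotherapy; the complement goes to
    instrumental/advocacy work (practical and financial concerns).
    Per-patient hours may exceed per-patient contacts when the initial
    assessment runs longer than the standard one-hour appointment.
    """

    counseling_hours_fraction: float = Field(ge=0, le=1)
    counseling_hours_per_patient: float = Field(gt=0)
    counseling_contacts_per_patient: int = Field(gt=0)
    instrumental_hours_per_patient: float = Field(gt=0)
    instrumental_contacts_per_patient: int = Field(gt=0)

    @property
    def instrumental_hours_fraction(self) -> float:
        return 1.0 - self.counseling_hours_fraction


class StaffingProfile(_StrictModel):
    """Complete parameter set for one PSO discipline in one setting."""

    schema_version: int = SCHEMA_VERSION
    discipline: str
    setting: Literal["tertiary", "regional", "community", "other"]
    calendar: WorkCalendar
    split: CareSplit
    groups: GroupProgram
    carryover: CarryoverPolicy
    mix: InterventionMix
    notes: str = ""


# ---------------------------------------------------------------------------
# Config file I/O

def load_profile(path: str | Path) -> StaffingProfile:
    """Load and validate a profile from a YAML or JSON config file.

    Unknown keys are rejected and every field bound is enforced; the
    resulting profile equals the one that was saved, field for field.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path} does not contain a profile mapping")
    return StaffingProfile.model_validate(data)


def save_profile(profile: StaffingProfile, path: str | Path) -> None:
    """Write a profile to YAML (default) or JSON, by file suffix."""
    path = Path(path)
    data = profile.model_dump(mode="json")
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def profile_json_schema() -> dict[str, Any]:
    """JSON Schema for the profile config-file format."""
    return StaffingProfile.model_json_schema()


# ---------------------------------------------------------------------------
# Packaged defaults
#
# Reference parameterisation for a social worker in a Canadian tertiary
# cancer center, in two variants that differ only in the DPC/IPC split and
# the split-dependent carryover count.  The calendar nets to 1566 h/year;
# counseling patients average six visits (a 1.5 h assessment plus five 1 h
# follow-ups); instrumental referrals average three one-hour contacts.

_DATA_DIR = Path(__file__).parent / "data"


def _base_kwargs() -> dict[str, Any]:
    return dict(
        discipline="social work",
        setting="tertiary",
        calendar=WorkCalendar(
            weekly_hours=37.5,
            weeks_per_year=52,
            vacation_days=20,
            statutory_holiday_days=11,
            sick_days=10,
            education_days=3,
            daily_break_hours=0.25,
            hours_per_workday=7.5,
        ),
        groups=GroupProgram(
            groups_per_year=3,
            sessions_per_group=7,
            participants_per_group=8,
            prep_hours_per_group=2.0,
            facilitation_hours_per_session=1.5,
        ),
        mix=InterventionMix(
            counseling_hours_fraction=0.70,
            counseling_hours_per_patient=6.5,
            counseling_contacts_per_patient=6,
            instrumental_hours_per_patient=3.0,
            instrumental_contacts_per_patient=3,
        ),
        notes=(
            "Generalist social-work model of practice, outpatient tertiary "
            "cancer center; MSW-level scope including counseling/psychotherapy "
            "and instrumental/advocacy work."
        ),
    )


def _default_75_25() -> StaffingProfile:
    kw = _base_kwargs()
    return StaffingProfile(
        split=CareSplit(dpc_fraction=0.75),
        carryover=CarryoverPolicy(
            mode="explicit_count",
            explicit_count=60,
            hours_per_patient=4.0,
            contacts_per_patient=4,
        ),
        **kw,
    )


def _default_70_30() -> StaffingProfile:
    kw = _base_kwargs()
    return StaffingProfile(
        split=CareSplit(dpc_fraction=0.70),
        carryover=CarryoverPolicy(
            mode="explicit_count",
            explicit_count=56,
            hours_per_patient=4.0,
            contacts_per_patient=4,
        ),
        **kw,
    )


_REGISTRY = {
    "capo2022_sw_tertiary_75_25": _default_75_25,
    "capo2022_sw_tertiary_70_30": _default_70_30,
}


def registered_profiles() -> list[str]:
    """Names of the packaged default profiles."""
    return sorted(_REGISTRY)


def default_profile(name: str) -> StaffingProfile:
    """Return a packaged default profile by registered name."""
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise UnknownProfileError(
            f"unknown profile {name!r}; registered: {', '.join(registered_profiles())}"
        ) from None


def packaged_profile_path(name: str) -> Path:
    """Path of the YAML config file shipped for a registered default."""
    if name not in _REGISTRY:
        raise UnknownProfileError(
            f"unknown profile {name!r}; registered: {', '.join(registered_profiles())}"
        )
    return _DATA_DIR / f"{name}.yaml"


def resolve_profile(name_or_path: str | Path) -> StaffingProfile:
    """Accept either a registered default name or a config-file path."""
    if isinstance(name_or_path, str) and name_or_path in _REGISTRY:
        return default_profile(name_or_path)
    return load_profile(name_or_path)
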