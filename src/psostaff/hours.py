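"""Net annual available work hours for one 1.0 FTE position.

Gross paid hours (weekly hours x paid weeks) are reduced by paid time not
available for work: vacation, statutory holidays, designated sick days,
education days (each in days at the standard workday length) and daily
paid breaks/lunches.  Breaks are deducted only for days actually worked —
a day of vacation does not also lose its coffee break — unless
``breaks_on_paid_days`` is set, in which case breaks apply to every
scheduled day.  Disability and unpaid leaves are outside the model and
never deducted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InfeasibleCalendarError
from .profiles import WorkCalendar


@dataclass(frozen=True)
class HoursLedger:
    """Itemised derivation of net available hours: gross − Σ deductions = net."""

    gross_paid_hours: float
    deductions: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    @property
    def total_deductions(self) -> float:
        return sum(h for _, h in self.deductions)

    @property
    def net_available_hours(self) -> float:
        return self.gross_paid_hours - self.total_deductions


def net_annual_hours(
    calendar: WorkCalendar, *, breaks_on_paid_days: bool = False
) -> HoursLedger:
    """Convert a work calendar into an itemised net annual-hours ledger.

    Raises
    ------
    InfeasibleCalendarError
        If deductions meet or exceed gross paid hours, or no worked days
        remain after leave.
    """
    gross = calendar.weekly_hours * calendar.weeks_per_year
    scheduled_days = calendar.weeks_per_year * calendar.days_per_week
    leave_days = (
        calendar.vacation_days
        + calendar.statutory_holiday_days
        + calendar.sick_days
        + calendar.education_days
    )
    worked_days = scheduled_days - leave_days
    if worked_days <= 0:
        raise InfeasibleCalendarError(
            f"leave days ({leave_days}) consume all {scheduled_days} scheduled days"
        )
    break_days = scheduled_days if breaks_on_paid_days else worked_days

    h = calendar.hours_per_workday
    deductions = (
        ("vacation", calendar.vacation_days * h),
        ("statutory holidays", calendar.statutory_holiday_days * h),
        ("sick days", calendar.sick_days * h),
        ("education days", calendar.education_days * h),
        ("breaks and lunches", calendar.daily_break_hours * break_days),
    )
    ledger = HoursLedger(gross_paid_hours=gross, deductions=deductions)
    if ledger.net_available_hours <= 0:
        raise InfeasibleCalendarError(
            f"deductions ({ledger.total_deductions} h) meet or exceed "
            f"gross paid hours ({gross} h)"
        )
    return ledger
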