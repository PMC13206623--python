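"""Exception types raised by the staffing model."""


class PsoStaffError(Exception):
    """Base class for all package errors."""


class InfeasibleCalendarError(PsoStaffError):
    """Paid-time deductions meet or exceed gross paid hours."""


class InfeasibleProfileError(PsoStaffError):
    """Fixed commitments (groups + carryover) exceed available DPC hours."""


class UnknownProfileError(PsoStaffError, KeyError):
    """Requested packaged profile name is not registered."""


class ConfigurationError(PsoStaffError):
    """A policy is queried in a mode whose required fields are missing."""


class ZeroCapacityError(PsoStaffError, ZeroDivisionError):
    """FTE requirement requested against a profile with no new-patient capacity."""
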