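"""Sensitivity sweeps, profile comparison, and a stochastic validator.

``sweep`` varies one numeric profile parameter at a time, holding every
other field fixed, and reports the capacity and FTE-requirement curves.
``compare_profiles`` puts complete profiles side by side (the right tool
when several parameters move together, e.g. the DPC split and its
split-dependent carryover count).  ``simulate_year`` draws stochastic
referral streams and checks that the deterministic capacity model's
served-patient figures hold up under Poisson arrival noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .capacity import compute_capacity
from .demand import DEFAULT_REFERRAL_RATE, DemandSpec, expected_referrals, fte_required
from .profiles import StaffingProfile

DEFAULT_SEED = 20220101
DEFAULT_REPLICATES = 500

#: Sweepable numeric fields, keyed by leaf name -> (sub-model, field).
SWEEPABLE_PARAMETERS: dict[str, tuple[str, str]] = {
    "weekly_hours": ("calendar", "weekly_hours"),
    "weeks_per_year": ("calendar", "weeks_per_year"),
    "vacation_days": ("calendar", "vacation_days"),
    "statutory_holiday_days": ("calendar", "statutory_holiday_days"),
    "sick_days": ("calendar", "sick_days"),
    "education_days": ("calendar", "education_days"),
    "daily_break_hours": ("calendar", "daily_break_hours"),
    "hours_per_workday": ("calendar", "hours_per_workday"),
    "dpc_fraction": ("split", "dpc_fraction"),
    "groups_per_year": ("groups", "groups_per_year"),
    "sessions_per_group": ("groups", "sessions_per_group"),
    "participants_per_group": ("groups", "participants_per_group"),
    "prep_hours_per_group": ("groups", "prep_hours_per_group"),
    "facilitation_hours_per_session": ("groups", "facilitation_hours_per_session"),
    "explicit_count": ("carryover", "explicit_count"),
    "carryover_rate": ("carryover", "rate"),
    "hours_per_patient": ("carryover", "hours_per_patient"),
    "contacts_per_patient": ("carryover", "contacts_per_patient"),
    "counseling_hours_fraction": ("mix", "counseling_hours_fraction"),
    "counseling_hours_per_patient": ("mix", "counseling_hours_per_patient"),
    "counseling_contacts_per_patient": ("mix", "counseling_contacts_per_patient"),
    "instrumental_hours_per_patient": ("mix", "instrumental_hours_per_patient"),
    "instrumental_contacts_per_patient": ("mix", "instrumental_contacts_per_patient"),
}


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    values: tuple[float, ...]
    fte_curve: tuple[float, ...]
    capacity_curve: tuple[int, ...]


@dataclass(frozen=True)
class SimulationReport:
    seed: int
    replicates: int
    mean_patients_served: float
    sd_patients_served: float
    mean_dpc_hours_used: float
    utilization: float
    p_demand_unmet: float

    @property
    def se_patients_served(self) -> float:
        """Standard error of the served-patient mean across replicates."""
        return self.sd_patients_served / self.replicates**0.5


def _with_parameter(profile: StaffingProfile, parameter: str, value: float) -> StaffingProfile:
    try:
        attr, field = SWEEPABLE_PARAMETERS[parameter]
    except KeyError:
        raise KeyError(
            f"unknown parameter {parameter!r}; sweepable: "
            f"{', '.join(sorted(SWEEPABLE_PARAMETERS))}"
        ) from None
    sub = getattr(profile, attr)
    new_sub = sub.model_copy(update={field: value})
    # re-validate the updated sub-model so out-of-range sweep values fail loudly
    new_sub = type(sub).model_validate(new_sub.model_dump())
    return profile.model_copy(update={attr: new_sub})


def sweep(
    profile: StaffingProfile,
    parameter: str,
    values: list[float],
    cases: int = 2000,
    referral_rate: float = DEFAULT_REFERRAL_RATE,
) -> SensitivityResult:
    """Recompute capacity and the FTE requirement at each parameter value.

    Pure function of its inputs; the supplied profile is never mutated.
    All other profile fields are held fixed, so a sweep isolates one
    parameter's effect (compare complete profiles with
    :func:`compare_profiles` when several fields co-vary).
    """
    spec = DemandSpec(annual_new_cases=cases, referral_rate=referral_rate)
    refs = expected_referrals(spec)
    ftes, caps = [], []
    for value in values:
        cap = compute_capacity(_with_parameter(profile, parameter, value))
        caps.append(cap.new_patient_capacity)
        ftes.append(fte_required(refs, cap))
    return SensitivityResult(
        parameter=parameter,
        values=tuple(values),
        fte_curve=tuple(ftes),
        capacity_curve=tuple(caps),
    )


def compare_profiles(
    profiles: list[StaffingProfile],
    cases: int = 2000,
    referral_rate: float = DEFAULT_REFERRAL_RATE,
) -> list[float]:
    """FTE requirement of each complete profile at a common demand level."""
    spec = DemandSpec(annual_new_cases=cases, referral_rate=referral_rate)
    refs = expected_referrals(spec)
    return [fte_required(refs, compute_capacity(p)) for p in profiles]


def simulate_year(
    profile: StaffingProfile,
    demand: DemandSpec,
    fte: float,
    seed: int = DEFAULT_SEED,
    replicates: int = DEFAULT_REPLICATES,
) -> SimulationReport:
    """Stochastic referral-stream validation of the deterministic model.

    Referral arrivals over the fiscal year are a homogeneous Poisson
    process with annual mean equal to the expected referral volume
    (quarter-to-quarter fluctuations are assumed to balance out, so a
    stationary process is the appropriate null model).  Each referral is
    counseling or instrumental with probability equal to the capacity
    model's implied patient mix — the case mix the time allocation
    assumes.  Each stream is served first come, first served against the
    fte-scaled bookable capacity of that stream (floor slack cannot book
    a whole patient and is excluded); group and carryover hours are fixed
    commitments.  Identical seeds give identical reports.
    """
    if fte <= 0:
        raise ValueError("fte must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    cap = compute_capacity(profile)
    mean_arrivals = expected_referrals(demand)

    n_c = cap.counseling_block.unique_patients
    n_i = cap.instrumental_block.unique_patients
    individuals = n_c + n_i
    p_counseling = n_c / individuals if individuals else 0.0
    cap_c = fte * n_c
    cap_i = fte * n_i
    h_c = profile.mix.counseling_hours_per_patient
    h_i = profile.mix.instrumental_hours_per_patient
    committed_hours = fte * (cap.group_block.hours + cap.carryover_block.hours)
    group_served = fte * cap.group_block.unique_patients
    dpc_budget = fte * cap.dpc_hours

    rng = np.random.default_rng(seed)
    arrivals = rng.poisson(mean_arrivals, size=replicates)
    arr_c = rng.binomial(arrivals, p_counseling)
    arr_i = arrivals - arr_c

    served_c = np.minimum(arr_c, cap_c)
    served_i = np.minimum(arr_i, cap_i)
    served = group_served + served_c + served_i
    hours_used = committed_hours + served_c * h_c + served_i * h_i
    unmet = (arr_c > cap_c) | (arr_i > cap_i)

    return SimulationReport(
        seed=seed,
        replicates=replicates,
        mean_patients_served=float(served.mean()),
        sd_patients_served=float(served.std(ddof=1)) if replicates > 1 else 0.0,
        mean_dpc_hours_used=float(hours_used.mean()),
        utilization=float(hours_used.mean() / dpc_budget),
        p_demand_unmet=float(unmet.mean()),
    )
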