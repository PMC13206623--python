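# psostaff

Capacity-based staffing-ratio planning for psychosocial oncology (PSO) and
supportive-care programs.

Cancer programs rarely have a transparent way to answer "how many social
workers (or psychologists, dietitians, …) does a program seeing *N* new
cancer cases a year need?"  `psostaff` implements the published
CAPO-style staffing framework as a reusable, parameterized capacity
engine for program administrators, PSO clinical leads and health-services
researchers: from a paid-hours calendar and a discipline profile it
computes how many patients one 1.0 FTE position can serve in a fiscal
year, converts program incidence into referral demand, and returns the
required FTE ratio and program-level caseload totals.

## The model

For one full-time position:

- **Net hours.** `net = gross paid hours − (vacation + statutory holidays
  + sick + education days) × h/day − daily breaks × worked days`.
- **Care split.** `DPC = net × dpc_fraction`; the rest is indirect patient
  care (meetings, rounds, program work).
- **Fixed commitments.** Therapeutic groups
  (`groups × (prep + sessions × facilitation)` hours) and the carryover
  caseload from the previous fiscal year (`patients × hours/patient`) come
  off the DPC hours first.
- **Intervention mix.** Remaining DPC hours split into a
  counseling/psychotherapy pool and an instrumental/advocacy pool
  (`70% / 30%` by default); each pool serves
  `⌊hours / hours-per-patient⌋` whole patients. Unbookable remainders are
  reported as slack, never dropped.
- **Demand and ratio.** `referrals = cases × referral rate` (35% expected
  prevalence of distress; 100% for specialized clinics with automatic
  referral), and `FTE = referrals / per-FTE new-patient capacity`,
  rounded half-up to two decimals. Program totals scale the per-FTE
  unique-caseload and contact counts by that figure.

Every patient encounter, whatever the modality, is one direct-patient-care
contact (DPCC). A stochastic validator (Poisson referral streams served
against the fte-scaled capacity) and a synthetic workload-measurement log
generator/aggregator round out the toolkit.

## Worked example

```python
from psostaff import DemandSpec, compute_capacity, default_profile, plan

profile = default_profile("capo2022_sw_tertiary_75_25")
cap = compute_capacity(profile)
print(cap.new_patient_capacity, cap.total_unique_caseload, cap.total_dpcc)
# 209 269 1251

result = plan(profile, DemandSpec(annual_new_cases=2000, referral_rate=0.35))
print(result.expected_referrals, result.fte_required,
      result.program_unique_cases, result.program_dpcc)
# 700 3.35 901 4191
```

One social-work FTE on the packaged tertiary-center default (1566 net
hours, 75% DPC, three 8-participant therapeutic groups, 60 carryover
patients at 4 h each, 70/30 counseling/instrumental mix) sees **209 new
patients** a year — 24 in groups, 96 counseling, 89 instrumental — for a
total caseload of **269 unique patients** and **1251 contacts**. A
program registering 2000 new cancer cases refers 700 of them (35%) and
therefore needs **3.35 FTE**, a program-wide caseload of 901 unique
patients and 4191 contacts. The same chain is available from the shell:

```sh
psostaff capacity --profile capo2022_sw_tertiary_75_25
psostaff fte --profile capo2022_sw_tertiary_75_25 --cases 2000
psostaff table --profiles capo2022_sw_tertiary_75_25,capo2022_sw_tertiary_70_30 \
    --cases 2000,3000,4000,5000,6000
```

The scripts in `examples/` walk one capability each: the hour/capacity
ledger, the planning table, sensitivity sweeps, the stochastic validator,
and workload-log round-tripping.

Profiles are YAML/JSON files (schema in
`src/psostaff/data/profile.schema.json`); edit a copy of the packaged
defaults to model your own discipline, setting or calendar.

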