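# Methods

## Model and assumptions

`psostaff` treats PSO staffing as a deterministic demand–capacity
problem at annual resolution. The unit of supply is one 1.0 FTE position
described by a `StaffingProfile`; the unit of demand is one referred
patient. The core assumptions:

- **Predictable paid time only.** The hour ledger deducts vacation,
  statutory holidays, designated sick days, education days and daily paid
  breaks. Disability and unpaid leaves are excluded by design — they are
  not predictable per-position entitlements — and the model carries no
  fields for them.
- **Breaks occur on worked days.** A vacation day does not also lose its
  break. `net_annual_hours(..., breaks_on_paid_days=True)` flips this for
  organizations that budget breaks against all paid days.
- **Annual stationarity.** Within-year fluctuations (group quarters,
  referral seasonality) are assumed to balance out; there is no
  scheduling or queueing inside the year.
- **One contact ≈ one hour.** Contacts are counted regardless of
  modality; per-patient hours may exceed per-patient contacts when the
  initial assessment runs longer than one hour.
- **Whole patients.** Each intervention stream serves
  `⌊pool hours / hours per patient⌋` patients. The two floor remainders
  are reported as `slack_hours`; slack is therefore non-negative and
  strictly less than the sum of the two per-patient hour figures.
- **Allocation order.** Groups and carryover are fixed commitments
  subtracted from DPC hours before the counseling/instrumental split: a
  program owes its continuing patients and scheduled groups before it
  books new individual referrals. A profile whose commitments exceed its
  DPC hours is rejected as infeasible rather than silently truncated.

## Default parameters

Two packaged profiles describe a social worker in an outpatient tertiary
cancer center and differ only in the DPC fraction and the
(split-dependent) carryover count.

| parameter | default | notes |
|---|---|---|
| weekly hours / weeks | 37.5 h × 52 | 7.5 h workday, 5-day week → 1950 h gross |
| vacation / stat / sick / education | 20 / 11 / 10 / 3 days | Canadian health-sector norms |
| daily paid break | 0.25 h | on 216 worked days |
| **net hours** | **1566 h** | ledger-conserved to the hour |
| DPC fraction | 0.75 (variant: 0.70) | outpatient/academic settings run above the 20% IPC of inpatient units |
| groups | 3 × 7 sessions × 8 participants | 2 h prep/group + 1.5 h/session → 37.5 h, 24 patients, 168 contacts |
| carryover | 60 (variant: 56) patients | 4 h and 4 contacts each; see below |
| counseling | 70% of remaining hours, 6.5 h & 6 contacts/patient | 1.5 h assessment + five 1 h follow-ups; six visits is an average |
| instrumental | 30% of remaining hours, 3 h & 3 contacts/patient | advocacy/navigation for practical and financial needs |
| referral rate | 0.35 | expected prevalence of distress; 0.40 is the accepted ceiling, 1.0 models automatic-referral clinics |

With these defaults one FTE serves 24 group + 96 counseling + 89
instrumental = 209 new patients, 269 unique patients and 1251 contacts
(the 70/30 variant: 196 / 252 / 1175). The parameter set was chosen as a
realistic calendar and intervention breakdown consistent with that
published caseload arithmetic; the constraint set (both split variants'
patient counts and contact totals) pins the structure tightly — in
particular the ~2.2 : 1 ratio of counseling to instrumental per-patient
hours.

**Carryover.** Continuing-care data are too sparse to derive carryover
from first principles, so the defaults carry it as an explicit count
(`explicit_count` mode), which is authoritative. A `rate_of_base` mode
(`⌊rate × base⌋`) expresses the common "20% of the prior-year caseload"
rule; 60 corresponds to 20% of a notional 300-patient prior-year
caseload (56 ↔ 280), but no printed caseload figure equals that base, so
the rate form is provenance, not derivation. Because the carryover count
is split-dependent, the published 75/25-vs-70/30 comparison is a
*profile* comparison (`compare_profiles`), not a one-parameter
`sweep` of `dpc_fraction` — `sweep` deliberately holds every other field
fixed.

## Numerical choices

- Hours are carried at full float precision; only patient and contact
  counts are integers (floored at allocation, as above).
- All demand-side arithmetic runs in `decimal` with half-up rounding:
  referrals to whole patients, FTE to two decimals, program totals to
  whole patients/contacts *from the two-decimal FTE* — the table
  reproduces what a reader recomputes from its own printed cells, and
  exact halves (e.g. 8.90 × 1175 = 10457.5) round up rather than to even.
- One published planning-table cell (6000-case row, program unique cases,
  printed 2704) is inconsistent with its own column arithmetic
  (10.05 × 269 = 2703.45); the implementation keeps the consistent rule
  and reports 2703. Similarly, the published 70/30 FTE column above 2000
  cases does not equal round2(referrals ÷ capacity); the table builder
  computes the self-consistent figure and the test suite lists the
  deviating cells.
- Sweeping a parameter re-validates the modified sub-model, so
  out-of-range sweep values fail loudly rather than producing silent
  extrapolation.

## Stochastic validator

`simulate_year` checks the deterministic figures against referral-stream
noise. Arrivals are a homogeneous Poisson process with annual mean equal
to the expected referral volume (stationarity assumption above). Each
referral is counseling or instrumental with probability equal to the
capacity model's implied patient mix (96 : 89 under the default) — the
case mix the time allocation assumes — and each stream is served
first-come-first-served against `fte ×` that stream's bookable capacity;
floor slack cannot book a whole patient and is excluded. Group and
carryover hours are fixed commitments. Unserved demand is counted, not
queued into the next year (carryover is already a profile parameter).
With 500 replicates the served-patient mean agrees with
`fte × new-patient capacity` to within three standard errors whenever
demand is at or above capacity. Defaults: 500 replicates, seed 20220101;
identical seeds give bit-identical reports.

## Synthetic workload logs

`generate_log` emulates a workload-measurement export: one CSV row per
contact (patient, type, duration, ISO date, provider, open/closed
status) over one fiscal year (configurable start; April 1 default).
Block counts equal the capacity result scaled by the staffed FTE
(half-up per block), so `aggregate_log` round-trips exactly; the
aggregator also enforces the carryover counting rule — a case opened in
a prior fiscal year counts as carryover only if the patient is seen
again in the new year, and a case with no new-year contact contributes
nothing even if still open. The generator emulates record *structure*
(types, per-patient visit counts, plausible dates), not realistic
arrival clustering, no-shows, or provider-level workload imbalance, so
passing round-trip tests validate aggregation logic, not real-world
measurement quality.

## Known limitations

- A generalist model: no per-diagnosis acuity weighting; specialized
  clinics (transplant, head-and-neck, palliative) need higher per-patient
  time and their own profiles.
- No within-year scheduling, waiting-list dynamics, or staff
  absence/attrition stochastics.
- Carryover is exogenous; the model does not close the loop between this
  year's caseload and next year's carryover.
- The planning table plans each discipline independently; there is no
  joint optimization across an interdisciplinary team.

## Problem sizes

Everything is desk-scale: capacity and table computations are
microseconds; the validator's 500 × Poisson(≈700) replicates and the
1251-record synthetic log keep the full test suite and the
reproduction script to a few seconds on one CPU.
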