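schema_version: 1
discipline: social work
setting: tertiary
calendar:
  weekly_hours: 37.5
  weeks_per_year: 52.0
  vacation_days: 20.0
  statutory_holiday_days: 11.0
  sick_days: 10.0
  education_days: 3.0
  daily_break_hours: 0.25
  hours_per_workday: 7.5
split:
  dpc_fraction: 0.75
groups:
  groups_per_year: 3
  sessions_per_group: 7
  participants_per_group: 8
  prep_hours_per_group: 2.0
  facilitation_hours_per_session: 1.5
carryover:
  mode: explicit_count
  explicit_count: 60
  rate: 0.0
  base_caseload: null
  hours_per_patient: 4.0
  contacts_per_patient: 4
mix:
  counseling_hours_fraction: 0.7
  counseling_hours_per_patient: 6.5
  counseling_contacts_per_patient: 6
  instrumental_hours_per_patient: 3.0
  instrumental_contacts_per_patient: 3
notes: Generalist social-work model of practice, outpatient tertiary cancer center;
  MSW-level scope including counseling/psychotherapy and instrumental/advocacy work.
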