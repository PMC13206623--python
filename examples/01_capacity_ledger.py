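"""How many patients can one full-time social worker serve in a year?

Loads the packaged tertiary-center default (75% direct patient care,
three therapeutic groups) and walks through the hour ledger and the
capacity allocation.
"""

from psostaff import compute_capacity, default_profile, net_annual_hours

profile = default_profile("capo2022_sw_tertiary_75_25")

ledger = net_annual_hours(profile.calendar)
print("Hour ledger (one 1.0 FTE position)")
print(f"  gross paid hours        {ledger.gross_paid_hours:8.1f}")
for label, hours in ledger.deductions:
    print(f"  - {label:<21} {hours:8.1f}")
print(f"  net available hours     {ledger.net_available_hours:8.1f}")

cap = compute_capacity(profile)
print("\nCapacity allocation")
print(f"  DPC hours (75%)         {cap.dpc_hours:8.1f}")
print(f"  IPC hours (25%)         {cap.ipc_hours:8.1f}")
print(f"  groups:     {cap.group_block.hours:6.1f} h -> {cap.group_block.unique_patients:3d} patients, {cap.group_block.contacts:4d} contacts")
print(f"  carryover:  {cap.carryover_block.hours:6.1f} h -> {cap.carryover_block.patients:3d} patients, {cap.carryover_block.contacts:4d} contacts")
print(f"  counseling: {cap.counseling_block.hours_used:6.1f} h -> {cap.counseling_block.unique_patients:3d} patients, {cap.counseling_block.contacts:4d} contacts")
print(f"  instrumental:{cap.instrumental_block.hours_used:5.1f} h -> {cap.instrumental_block.unique_patients:3d} patients, {cap.instrumental_block.contacts:4d} contacts")
print(f"  slack (unbookable)      {cap.slack_hours:8.1f} h")

print(f"\nOne FTE sees {cap.new_patient_capacity} new patients/year; with the")
print(f"{cap.carryover_block.patients}-patient carryover caseload that is "
      f"{cap.total_unique_caseload} unique patients and {cap.total_dpcc} "
      "direct-patient-care contacts.")
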