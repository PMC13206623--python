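"""Round-trip a synthetic workload-measurement log.

Generates one fiscal year of per-contact records for a 1.0 FTE position,
writes it as CSV, reads it back and aggregates it — recovering the
capacity model's caseload figures, including the carryover counting rule
(prior-year cases count only if seen again in the new fiscal year).
"""

import tempfile
from pathlib import Path

from psostaff import aggregate_log, default_profile, generate_log, read_log, write_log

profile = default_profile("capo2022_sw_tertiary_75_25")
records = generate_log(profile, fte=1.0, seed=42)

path = Path(tempfile.mkdtemp()) / "workload_log.csv"
write_log(records, path)
summary = aggregate_log(read_log(path))

print(f"wrote {len(records)} contact records to {path}")
print(f"unique patients:  {summary.unique_patients}")
print(f"  new this year:  {summary.new_patients}")
print(f"  carryover:      {summary.carryover_cases}")
print(f"total contacts:   {summary.total_contacts}")
print("contacts by type:")
for contact_type, n in sorted(summary.contacts_by_type.items()):
    print(f"  {contact_type:<20} {n:5d}")
print("\nAggregation recovers the per-FTE planning figures: 269 unique "
      "patients and 1251 direct-patient-care contacts.")
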