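"""Build the staffing-ratio planning table for a range of program sizes.

One panel per profile variant, one row per annual case volume; column d
(required FTE) is expected referrals divided by per-FTE capacity, and the
program totals scale the per-FTE caseload by that two-decimal figure.
"""

from psostaff import build_table, default_profile

profiles = [
    default_profile("capo2022_sw_tertiary_75_25"),
    default_profile("capo2022_sw_tertiary_70_30"),
]
table = build_table([2000, 3000, 4000, 5000, 6000], profiles, referral_rate=0.35)
print(table.to_markdown(index=False))
print(
    "\nReading the first row: a 2000-case program refers 700 patients "
    "(35% prevalence of distress); at 209 new patients per FTE that "
    "requires 3.35 FTE, a program caseload of 901 unique patients and "
    "4191 contacts."
)
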