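"""What moves the FTE requirement?

Sweeps single parameters of the default profile, then compares the two
packaged split variants as whole profiles (the carryover caseload is
split-dependent, so the published comparison is a profile comparison,
not a one-parameter sweep).
"""

from psostaff import compare_profiles, default_profile, sweep

profile = default_profile("capo2022_sw_tertiary_75_25")

res = sweep(profile, "counseling_hours_per_patient", [5, 6, 6.5, 8, 10], cases=2000)
print("counseling hours/patient -> capacity, FTE for a 2000-case program")
for v, c, f in zip(res.values, res.capacity_curve, res.fte_curve):
    print(f"  {v:5.1f} h  ->  {c:3d} patients/FTE, {f:.2f} FTE")

res = sweep(profile, "vacation_days", [15, 20, 25, 30], cases=2000)
print("\nvacation days -> capacity, FTE")
for v, c, f in zip(res.values, res.capacity_curve, res.fte_curve):
    print(f"  {v:5.0f} d  ->  {c:3d} patients/FTE, {f:.2f} FTE")

pair = compare_profiles(
    [profile, default_profile("capo2022_sw_tertiary_70_30")], cases=2000
)
print(f"\n75/25 vs 70/30 split at 2000 cases: {pair[0]:.2f} vs {pair[1]:.2f} FTE")
print("Five points of DPC time are worth about a fifth of a position here.")
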