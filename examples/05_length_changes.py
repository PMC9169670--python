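"""Muscle length changes over the flipper beat, from the packaged table.

Loads the packaged cord-length measurements (41 muscles of a plesiosaur
fore- and hindflipper at -50 / 0 / +50 degrees of elevation), recomputes
the percentage length-change columns, screens each muscle against the
~40% physiological limit, and audits the printed derived columns.
"""

from flipperfea import table1_fixture
from flipperfea.length_change import CordMeasurement, audit_table, records_frame

table = table1_fixture()
measurements = [
    CordMeasurement(r.muscle, r.ventral_cm, r.neutral_cm, r.dorsal_cm)
    for r in table.itertuples()
]
frame = records_frame(measurements)

print(frame[["muscle", "total_pct", "physiological"]].to_string(index=False))
worst = frame.loc[frame.total_pct.idxmax()]
print(f"\nlargest total change: {worst.muscle} at {worst.total_pct:.2f}% "
      f"({'physiological' if worst.physiological else 'NOT physiological'})")

audit = audit_table(table)
bad = audit[~audit.consistent]
print(f"\naudit: {len(bad)} of {len(audit)} printed rows are internally inconsistent:")
for row in bad.itertuples():
    print(f"  {row.muscle}: {row.discrepancies}")
# A muscle whose total length change exceeds ~40% (e.g. the scapular-blade
# origin of m. deltoideus scapularis at 70.87%) demands more shortening
# than striated muscle can deliver: that attachment reconstruction can be
# rejected on physiological grounds alone.
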