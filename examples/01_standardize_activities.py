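"""Standardize a mixed-readout activity table onto oriented z-scores.

Three IC50 measurements on one target are mapped to the -log10 molar scale
(larger = more potent) and z-scored against the target's own distribution.
"""

from chemoprofile import ActivityRecord, DataType, compute_zscores, orient_records

records = orient_records(
    [
        ActivityRecord("aspirin-like", "T1", DataType.IC50, 50.0, unit="nM"),
        ActivityRecord("fragment-hit", "T1", DataType.IC50, 12_000.0, unit="nM"),
        ActivityRecord("lead", "T1", DataType.IC50, 3.0, unit="nM"),
    ]
)
records, stats = compute_zscores(records)

print(f"group: target={stats[0].target_id} type={stats[0].data_type.value} "
      f"mean={stats[0].mean:.3f} sd={stats[0].sd:.3f} n={stats[0].n}")
for r in records:
    print(f"{r.compound_id:>14}  IC50={r.value:>8.1f} nM  "
          f"p-value={r.oriented_value:.2f}  z={r.z_score:+.3f}")
print("\nA positive z means more potent than typical for this target;")
print("the 3 nM lead sits about one standard deviation above the mean.")
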