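"""Simulate a telemonitoring cohort and write it in the on-disk dialect.

Generates 3 case recordings (one exacerbation each, with a 4-day
deterioration ramp) and 4 controls, writes the per-recording telemetry CSVs,
the metadata table and the ground-truth JSON, and prints what was simulated.
"""

from pathlib import Path

import respnovel as rn

config = rn.CohortConfig(n_cases=3, n_controls=4, seed=42)
recordings, annotations = rn.generate_cohort(config)
out = rn.write_cohort(recordings, annotations, Path("scratch/example_cohort"))

print(f"wrote {len(recordings)} recordings to {out}\n")
for rec, ann in zip(recordings, annotations):
    onsets = ", ".join(str(d) for d in rec.exacerbation_onsets) or "none"
    print(
        f"{rec.recording_id}: {rec.duration_days} days, "
        f"{len(rec.samples)} telemetry rows, onsets: {onsets}"
    )
print(
    "\nEach row is one 5-minute slot of oxygen delivery; a fully used day "
    "would hold 288 rows.  Cases ramp (rate up, amplitude down, usage down) "
    "over the 4 days before their onset."
)
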