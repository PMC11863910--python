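"""Three views of one monitored day, plus the recording-selection rules.

Shows the daily summary (usage hours, mean rate/amplitude), the empirical
(rate, amplitude) distribution, and the gap-split time-series segments for a
single day, then the eligibility report and labeled test periods of the
recording.
"""

import numpy as np

import respnovel as rn

recordings, _ = rn.generate_cohort(rn.CohortConfig(n_cases=1, n_controls=0, seed=7))
rec = recordings[0]

date = rec.date_of_day(16)
day = rn.summarize_day(rec, date)
print(f"day {day.day_index} ({day.date}) of {rec.recording_id}:")
print(f"  usage          {day.usage_hours:.1f} h of oxygen therapy")
print(f"  mean rate      {day.mean_rate:.1f} breaths/min")
print(f"  mean amplitude {day.mean_amplitude:.2f} device units")
print(f"  distribution   {day.n_valid} valid (rate, amplitude) samples")
print(f"  segments       {[len(s) for s in day.segments]} (split at invalid/missing slots)")

report = rn.check_eligibility(rec)
print(f"\neligibility: {report.status} (usable onsets: {report.usable_exacerbations})")

for period in rn.extract_pre_exacerbation_periods(rec):
    idx = [rec.day_index(d) for d in period.dates]
    print(f"pre-exacerbation period: days {idx} (the up-to-4 days before onset)")

stable = rn.sample_stable_period(rec, np.random.default_rng(0))
print(f"a stable window: days {[rec.day_index(d) for d in stable.dates]} "
      "(>= day 15, before the baseline week)")
baseline = rn.select_baseline_week(rec)
print(f"baseline week: days {[d.day_index for d in baseline]} (final week before discharge)")
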