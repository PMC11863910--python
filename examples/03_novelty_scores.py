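"""Fit the six per-patient baseline models and score a pre-exacerbation window.

Trains each reference model on the baseline week of a simulated recording,
derives the limits of normality from the in-sample baseline scores, then
compares the 4-day window before an exacerbation onset (rate +4 breaths/min,
amplitude -30%, usage -2 h at full ramp) against the same calendar window of
a no-effect twin recording generated from the identical patient and seed.
"""

import numpy as np

import respnovel as rn

params = rn.sample_patient_params(np.random.default_rng(5))
effect = rn.ExacerbationEffect(
    onset_day=20, delta_rate=4.0, delta_amplitude_frac=0.3, delta_usage_hours=2.0
)
case, _ = rn.generate_recording(params, effect, 30, seed=8, recording_id="case")
twin, _ = rn.generate_recording(params, None, 30, seed=8, recording_id="twin")

baseline = rn.select_baseline_week(twin)
rng = np.random.default_rng(0)
window = range(16, 20)  # the 4 days before the day-20 onset


def max_z(rec, model, method, lim):
    zs = []
    for day_idx in window:
        day = rn.summarize_day(rec, rec.date_of_day(day_idx))
        score = rn.score_method(method, model, day)
        if score is not None:
            zs.append((score - lim.m_b) / lim.s_b)
    return max(zs)


print(f"{'method':<12}{'limits m_b':>11}{'s_b':>7}{'stable max z':>14}{'ramped max z':>14}")
for method in rn.METHODS:
    model = rn.fit_method(method, baseline, rng)
    baseline_scores = [
        s for d in baseline if (s := rn.score_method(method, model, d)) is not None
    ]
    lim = rn.compute_limits(baseline_scores)
    print(
        f"{method:<12}{lim.m_b:>11.2f}{lim.s_b:>7.2f}"
        f"{max_z(twin, model, method, lim):>14.1f}"
        f"{max_z(case, model, method, lim):>14.1f}"
    )

print(
    "\nmax z is the period statistic for n = 1: the window is flagged "
    "pre-exacerbation at threshold k when its largest day z exceeds k.  The "
    "deteriorating window stands well above its stable twin for most "
    "methods; mean breathing rate alone can miss it when ordinary day-to-day "
    "variability swamps the shift, which is why richer daily representations "
    "are worth testing."
)
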