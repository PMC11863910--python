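"""Synthetic telemonitoring cohorts with known ground truth.

No public telemonitoring dataset of this kind exists, so the pipeline is
exercised on simulated rehabilitation stays that carry the statistical
structure the detection methods assume:

* each day is a 288-slot 5-minute grid; the device emits one row per slot of
  oxygen delivery, so a fully used day yields exactly 288 records;
* usage is a single contiguous (nocturnal) session per day whose length is
  drawn from a truncated normal distribution;
* valid samples' (breathing rate, inspiratory amplitude) follow a two-state
  Gaussian hidden Markov chain stepped once per 5-minute slot;
* all patients drift toward a healthier setpoint over the stay
  (rehabilitation recovery), reaching it by the baseline week;
* cases additionally deteriorate linearly over the days before an
  exacerbation onset (rate up, amplitude down, usage down) and recover back
  to baseline before the final week;
* days go missing and samples go invalid at configurable rates.

With all effect deltas at zero, case and control recordings are statistically
exchangeable by construction (onsets are drawn so pre-onset windows occupy the
same day range as control stable windows).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .telemetry import (
    BASELINE_DAYS,
    SLOTS_PER_DAY,
    Recording,
    Sample,
)

DEFAULT_FIRST_DAY = dt.date(2021, 1, 4)
#: session flow setpoint, L/min
DEFAULT_FLOW_LPM = 2.0
#: the usage session ends at 08:00 (slot 96) when short enough
SESSION_END_SLOT = 96
#: days an exacerbation's effect takes to fade after onset (capped so the
#: baseline week is always clean)
POST_ONSET_RECOVERY_DAYS = 7


@dataclass
class PatientParams:
    """Stable-state dynamics of one simulated patient.

    ``state_means``/``state_sds`` are (2, 2) arrays over (rate, amplitude) for
    the two hidden respiratory regimes; ``transition_probs`` is the per-slot
    2x2 row-stochastic transition matrix.  ``recovery_slope`` (breaths/min per
    day) raises the rate early in the stay, decaying linearly to zero by the
    first baseline day — the rehabilitation recovery trend shared by every
    patient in the cohort.
    """

    state_means: np.ndarray
    state_sds: np.ndarray
    transition_probs: np.ndarray
    initial_probs: np.ndarray
    usage_mean_hours: float = 8.0
    usage_sd_hours: float = 0.5
    #: sd of the day-level random offset on (rate, amplitude) means — the
    #: day-to-day biological variability of daily summaries, which dominates
    #: the within-day averaging error in real telemetry
    day_sd: tuple[float, float] = (0.8, 0.05)
    p_missing_day: float = 0.05
    p_invalid_sample: float = 0.05
    recovery_slope: float = 0.04
    flow_lpm: float = DEFAULT_FLOW_LPM

    def __post_init__(self) -> None:
        self.state_means = np.asarray(self.state_means, dtype=float).reshape(2, 2)
        self.state_sds = np.asarray(self.state_sds, dtype=float).reshape(2, 2)
        self.transition_probs = np.asarray(self.transition_probs, dtype=float)
        self.initial_probs = np.asarray(self.initial_probs, dtype=float)
        if np.any(self.state_sds <= 0):
            raise ValueError("state sds must be positive")
        if not np.allclose(self.transition_probs.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial_probs.sum(), 1.0):
            raise ValueError("initial probabilities must sum to 1")
        for p in (self.p_missing_day, self.p_invalid_sample):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class ExacerbationEffect:
    """Pre-onset deterioration ramp for a simulated exacerbation.

    Over the ``ramp_days`` days before ``onset_day`` the state means shift
    linearly, reaching the full deltas on the eve of onset: breathing rate
    rises by ``delta_rate`` breaths/min, amplitude shrinks by
    ``delta_amplitude_frac`` (fraction), daily usage drops by
    ``delta_usage_hours``.  After onset the effect decays back to zero before
    the final (baseline) week.
    """

    onset_day: int
    ramp_days: int = 4
    delta_rate: float = 3.0
    delta_amplitude_frac: float = 0.2
    delta_usage_hours: float = 1.5

    def __post_init__(self) -> None:
        if self.ramp_days < 1:
            raise ValueError("ramp_days must be >= 1")
        if self.onset_day - self.ramp_days < 1:
            raise ValueError("ramp must start within the recording")

    def factor(self, day: int, baseline_start_day: int) -> float:
        """Effect intensity in [0, 1] on a given 1-based day index."""
        ramp_start = self.onset_day - self.ramp_days
        if ramp_start <= day < self.onset_day:
            return (day - ramp_start + 1) / self.ramp_days
        if day >= self.onset_day:
            recovery = min(
                POST_ONSET_RECOVERY_DAYS, baseline_start_day - self.onset_day
            )
            return max(0.0, 1.0 - (day - self.onset_day + 1) / max(recovery, 1))
        return 0.0


@dataclass
class ParamRanges:
    """Uniform sampling ranges for per-patient parameters."""

    rate_low_mean: tuple[float, float] = (14.0, 17.0)
    rate_separation: tuple[float, float] = (3.0, 5.0)
    rate_sd: tuple[float, float] = (0.8, 1.2)
    amplitude_high_mean: tuple[float, float] = (0.75, 0.95)
    amplitude_drop: tuple[float, float] = (0.10, 0.25)
    amplitude_sd: tuple[float, float] = (0.06, 0.10)
    stay_prob: tuple[float, float] = (0.90, 0.97)
    usage_mean_hours: tuple[float, float] = (7.0, 10.0)
    usage_sd_hours: tuple[float, float] = (0.4, 0.6)
    day_sd_rate: tuple[float, float] = (0.6, 1.0)
    day_sd_amplitude: tuple[float, float] = (0.04, 0.06)
    recovery_slope: tuple[float, float] = (0.02, 0.06)
    p_missing_day: float = 0.05
    p_invalid_sample: float = 0.05


@dataclass
class EffectRanges:
    """Uniform sampling ranges for exacerbation effect sizes.

    The defaults are placeholders (no published effect sizes exist for this
    setting); studies of specific regimes should set them explicitly, e.g.
    all-zero deltas for a null cohort.
    """

    ramp_days: int = 4
    delta_rate: tuple[float, float] = (2.0, 4.0)
    delta_amplitude_frac: tuple[float, float] = (0.15, 0.30)
    delta_usage_hours: tuple[float, float] = (1.0, 2.0)


@dataclass
class CohortConfig:
    n_cases: int = 10
    n_controls: int = 14
    duration_days: tuple[int, int] = (28, 42)
    seed: int = 0
    param_ranges: ParamRanges = field(default_factory=ParamRanges)
    effect_ranges: EffectRanges = field(default_factory=EffectRanges)

    def __post_init__(self) -> None:
        if self.n_cases + self.n_controls < 1:
            raise ValueError("cohort must contain at least one recording")
        if self.duration_days[0] <= 21:
            raise ValueError("minimum duration must exceed 21 days")


def _uniform(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    return float(rng.uniform(*bounds))


def sample_patient_params(
    rng: np.random.Generator, ranges: ParamRanges | None = None
) -> PatientParams:
    """Draw one patient's stable-state parameters from the cohort ranges."""
    r = ranges or ParamRanges()
    rate0 = _uniform(rng, r.rate_low_mean)
    rate1 = rate0 + _uniform(rng, r.rate_separation)
    amp0 = _uniform(rng, r.amplitude_high_mean)
    amp1 = max(amp0 - _uniform(rng, r.amplitude_drop), 0.2)
    rate_sd = _uniform(rng, r.rate_sd)
    amp_sd = _uniform(rng, r.amplitude_sd)
    stay0 = _uniform(rng, r.stay_prob)
    stay1 = _uniform(rng, r.stay_prob)
    return PatientParams(
        state_means=[[rate0, amp0], [rate1, amp1]],
        state_sds=[[rate_sd, amp_sd], [rate_sd, amp_sd]],
        transition_probs=[[stay0, 1 - stay0], [1 - stay1, stay1]],
        initial_probs=[0.5, 0.5],
        usage_mean_hours=_uniform(rng, r.usage_mean_hours),
        usage_sd_hours=_uniform(rng, r.usage_sd_hours),
        day_sd=(
            _uniform(rng, r.day_sd_rate),
            _uniform(rng, r.day_sd_amplitude),
        ),
        p_missing_day=r.p_missing_day,
        p_invalid_sample=r.p_invalid_sample,
        recovery_slope=_uniform(rng, r.recovery_slope),
    )


def sample_effect(
    rng: np.random.Generator,
    onset_day: int,
    ranges: EffectRanges | None = None,
) -> ExacerbationEffect:
    r = ranges or EffectRanges()
    return ExacerbationEffect(
        onset_day=onset_day,
        ramp_days=r.ramp_days,
        delta_rate=_uniform(rng, r.delta_rate),
        delta_amplitude_frac=_uniform(rng, r.delta_amplitude_frac),
        delta_usage_hours=_uniform(rng, r.delta_usage_hours),
    )


def generate_recording(
    params: PatientParams,
    effect: ExacerbationEffect | None,
    duration_days: int,
    seed: int,
    recording_id: str = "sim",
    first_day: dt.date = DEFAULT_FIRST_DAY,
) -> tuple[Recording, dict]:
    """Simulate one recording; returns (recording, ground-truth annotation).

    Deterministic given ``seed``.  When an effect is present its onset must
    leave the final week untouched (``onset_day <= duration_days - 8``) so the
    recording stays eligible by construction.  Baseline-week days are exempt
    from whole-day dropout, preserving a trainable baseline.
    """
    if effect is not None and effect.onset_day > duration_days - 8:
        raise ValueError(
            "onset too close to discharge: the final week must stay clean"
        )
    rng = np.random.default_rng(seed)
    baseline_start_day = duration_days - BASELINE_DAYS + 1
    # only the baseline week is exempt from whole-day dropout (a trainable
    # baseline is guaranteed by construction); pre-onset days drop out at the
    # same rate as any other day, keeping case and control windows
    # missing-data exchangeable
    protected = {duration_days - i for i in range(BASELINE_DAYS)}

    samples: list[Sample] = []
    for day in range(1, duration_days + 1):
        if day not in protected and rng.uniform() < params.p_missing_day:
            continue
        f = 0.0 if effect is None else effect.factor(day, baseline_start_day)
        recovery = params.recovery_slope * max(0, baseline_start_day - day)
        day_offset = rng.normal(0.0, params.day_sd)
        means = params.state_means.copy()
        means[:, 0] += recovery + day_offset[0] + (
            0.0 if effect is None else f * effect.delta_rate
        )
        means[:, 1] = np.maximum(means[:, 1] + day_offset[1], 0.05)
        if effect is not None:
            means[:, 1] *= 1.0 - f * effect.delta_amplitude_frac

        usage_mean = params.usage_mean_hours - (
            0.0 if effect is None else f * effect.delta_usage_hours
        )
        usage = float(np.clip(rng.normal(usage_mean, params.usage_sd_hours), 0, 24))
        n_slots = int(round(usage * 12))
        if n_slots == 0:
            continue
        start_slot = max(0, SESSION_END_SLOT - n_slots)
        if start_slot + n_slots > SLOTS_PER_DAY:
            start_slot = SLOTS_PER_DAY - n_slots

        # hidden two-state chain across the session
        states = np.empty(n_slots, dtype=int)
        states[0] = rng.choice(2, p=params.initial_probs)
        u = rng.uniform(size=n_slots)
        for t in range(1, n_slots):
            states[t] = int(u[t] > params.transition_probs[states[t - 1], 0])
        obs = rng.normal(means[states], params.state_sds[states])
        obs[:, 0] = np.maximum(obs[:, 0], 0.1)
        obs[:, 1] = np.maximum(obs[:, 1], 0.01)
        invalid = rng.uniform(size=n_slots) < params.p_invalid_sample

        date = first_day + dt.timedelta(days=day - 1)
        midnight = dt.datetime.combine(date, dt.time())
        for t in range(n_slots):
            ts = midnight + dt.timedelta(minutes=(start_slot + t) * 5)
            if invalid[t]:
                samples.append(Sample(ts, params.flow_lpm, None, None, False))
            else:
                samples.append(
                    Sample(ts, params.flow_lpm, float(obs[t, 0]), float(obs[t, 1]), True)
                )

    onsets = (
        []
        if effect is None
        else [first_day + dt.timedelta(days=effect.onset_day - 1)]
    )
    recording = Recording(
        recording_id=recording_id,
        samples=samples,
        first_day=first_day,
        discharge_date=first_day + dt.timedelta(days=duration_days - 1),
        exacerbation_onsets=onsets,
    )
    annotation = {
        "recording_id": recording_id,
        "seed": int(seed),
        "duration_days": duration_days,
        "is_case": effect is not None,
        "effect": None if effect is None else asdict(effect),
        "usage_mean_hours": params.usage_mean_hours,
        "state_means": params.state_means.tolist(),
        "transition_probs": params.transition_probs.tolist(),
    }
    return recording, annotation


def generate_cohort(config: CohortConfig) -> tuple[list[Recording], list[dict]]:
    """Simulate a full cohort: cases carry one onset each, controls none.

    Every recording passes the eligibility rules by construction.  Onset days
    are uniform on [19, duration - 8], so pre-onset windows fall in the same
    day range as control stable windows.  Fully reproducible from
    ``config.seed``; per-recording seeds are derived from it.
    """
    master = np.random.default_rng(config.seed)
    recordings: list[Recording] = []
    annotations: list[dict] = []
    for i in range(config.n_cases + config.n_controls):
        is_case = i < config.n_cases
        params = sample_patient_params(master, config.param_ranges)
        duration = int(master.integers(config.duration_days[0], config.duration_days[1] + 1))
        effect = None
        if is_case:
            onset = int(master.integers(19, duration - 8 + 1))
            effect = sample_effect(master, onset, config.effect_ranges)
        seed = int(master.integers(2**31 - 1))
        rid = f"{'case' if is_case else 'ctrl'}-{i:03d}"
        rec, ann = generate_recording(
            params, effect, duration, seed, recording_id=rid
        )
        recordings.append(rec)
        annotations.append(ann)
    return recordings, annotations


# ---------------------------------------------------------------------------
# on-disk dialect shared with the telemetry reader


def write_cohort(
    recordings: list[Recording],
    annotations: list[dict],
    out_dir: str | Path,
) -> Path:
    """Write telemetry CSVs, the metadata table, and the ground-truth JSON."""
    out = Path(out_dir)
    (out / "telemetry").mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for rec in recordings:
        rows = [
            {
                "timestamp": s.timestamp.isoformat(),
                "flow_lpm": s.flow,
                "breathing_rate_bpm": "" if s.rate is None else s.rate,
                "inspiratory_amplitude": "" if s.amplitude is None else s.amplitude,
                "valid": int(s.valid),
            }
            for s in rec.samples
        ]
        pd.DataFrame(
            rows,
            columns=[
                "timestamp",
                "flow_lpm",
                "breathing_rate_bpm",
                "inspiratory_amplitude",
                "valid",
            ],
        ).to_csv(out / "telemetry" / f"{rec.recording_id}.csv", index=False)
        meta_rows.append(
            {
                "recording_id": rec.recording_id,
                "first_day": rec.first_day.isoformat(),
                "discharge_date": rec.discharge_date.isoformat(),
                "exacerbation_onsets": ";".join(
                    d.isoformat() for d in rec.exacerbation_onsets
                ),
            }
        )
    pd.DataFrame(meta_rows).to_csv(out / "metadata.csv", index=False)
    (out / "ground_truth.json").write_text(json.dumps(annotations, indent=1))
    return out


def read_cohort(data_dir: str | Path) -> list[Recording]:
    """Read a cohort directory written by :func:`write_cohort`."""
    from .telemetry import read_metadata, read_recording

    data_dir = Path(data_dir)
    records = read_metadata(data_dir / "metadata.csv")
    return [
        read_recording(
            data_dir / "telemetry" / f"{m['recording_id']}.csv", m
        )
        for m in records
    ]
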