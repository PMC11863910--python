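"""Telemonitoring recordings: parsing, validity filtering, daily views, labeling.

An oxygen-therapy telemonitor records one row every 5 minutes (288 slots per
day): oxygen flow, median breathing rate, median inspiratory amplitude, and a
signal-quality/spontaneous-breathing validity flag.  A recording covers a
rehabilitation stay; its metadata carries the discharge date and any
physician-confirmed exacerbation onset dates.

This module derives three views of a calendar day (daily summary, empirical
distribution of (rate, amplitude), gap-split time series), applies the
recording-eligibility rules (three-week minimum duration, uncontaminated
baseline week, usable exacerbations), and extracts the labeled test periods:
the up-to-4 days preceding an exacerbation, and randomly sampled 4-day windows
of assumed stability in control recordings.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SLOTS_PER_DAY = 288
SLOT_MINUTES = 5
#: a day counts as missing below this many valid samples (1 h of valid data)
DEFAULT_MIN_VALID_SAMPLES = 12
#: minimum non-missing days required in the baseline week
DEFAULT_MIN_BASELINE_DAYS = 4
#: recordings of at most this many days are excluded (three-week rule)
MIN_DURATION_DAYS = 21
#: length of the baseline window: the final week before discharge
BASELINE_DAYS = 7
#: maximal length of a test period
TEST_PERIOD_DAYS = 4
#: earliest day index from which stable windows may start
STABLE_EARLIEST_DAY = 15


class TelemetryError(ValueError):
    """Malformed telemetry input (row- or field-level message included)."""


class EligibilityError(ValueError):
    """Recording cannot be used in the requested role."""


@dataclass(frozen=True)
class Sample:
    """One 5-minute telemetry record.

    ``rate`` and ``amplitude`` are both present or both absent; they are absent
    for slots without spontaneous breathing or with poor signal quality.
    """

    timestamp: dt.datetime
    flow: float
    rate: float | None
    amplitude: float | None
    valid: bool

    def __post_init__(self) -> None:
        if (self.rate is None) != (self.amplitude is None):
            raise TelemetryError(
                f"sample at {self.timestamp}: rate and amplitude must be "
                "both present or both absent"
            )
        if self.flow < 0:
            raise TelemetryError(f"sample at {self.timestamp}: negative flow")


@dataclass
class Recording:
    """A labeled telemonitoring stay."""

    recording_id: str
    samples: list[Sample]
    first_day: dt.date
    discharge_date: dt.date
    exacerbation_onsets: list[dt.date] = field(default_factory=list)
    # memo caches; day summaries are requested thousands of times during
    # resampled evaluation
    _by_date: dict = field(default_factory=dict, init=False, repr=False, compare=False)
    _day_cache: dict = field(default_factory=dict, init=False, repr=False, compare=False)

    def samples_on(self, date: dt.date) -> list[Sample]:
        if not self._by_date:
            for s in self.samples:
                self._by_date.setdefault(s.timestamp.date(), []).append(s)
        return self._by_date.get(date, [])

    def __post_init__(self) -> None:
        if self.discharge_date < self.first_day:
            raise TelemetryError(
                f"{self.recording_id}: discharge before first day"
            )
        for onset in self.exacerbation_onsets:
            if not (self.first_day <= onset <= self.discharge_date):
                raise TelemetryError(
                    f"{self.recording_id}: onset {onset} outside stay "
                    f"[{self.first_day}, {self.discharge_date}]"
                )
        prev = None
        for s in self.samples:
            if prev is not None and s.timestamp <= prev:
                raise TelemetryError(
                    f"{self.recording_id}: timestamp {s.timestamp} not "
                    "strictly increasing"
                )
            prev = s.timestamp

    @property
    def duration_days(self) -> int:
        return (self.discharge_date - self.first_day).days + 1

    def day_index(self, date: dt.date) -> int:
        """1-based calendar day index from the first recorded day."""
        return (date - self.first_day).days + 1

    def date_of_day(self, day_index: int) -> dt.date:
        return self.first_day + dt.timedelta(days=day_index - 1)

    @property
    def baseline_start(self) -> dt.date:
        """First day of the baseline week (final 7 days before discharge)."""
        return self.discharge_date - dt.timedelta(days=BASELINE_DAYS - 1)


@dataclass
class DayData:
    """One calendar day viewed three ways: summary, distribution, time series."""

    date: dt.date
    day_index: int
    usage_hours: float
    mean_rate: float | None
    mean_amplitude: float | None
    #: (n_valid, 2) array of (rate, amplitude) pairs from valid samples
    distribution: np.ndarray
    #: runs of valid samples contiguous on the 5-minute grid, each (T_i, 2)
    segments: list[np.ndarray]
    n_valid: int
    missing: bool

    def summary(self, variable: str) -> float | None:
        """Daily value of one summary variable (usage, rate, amplitude)."""
        if variable == "usage":
            return self.usage_hours
        if variable == "rate":
            return self.mean_rate
        if variable == "amplitude":
            return self.mean_amplitude
        raise ValueError(f"unknown variable {variable!r}")


@dataclass
class EligibilityReport:
    status: str  # "eligible" | "excluded"
    reasons: list[str]
    usable_exacerbations: list[dt.date]

    @property
    def eligible(self) -> bool:
        return self.status == "eligible"


@dataclass
class TestPeriod:
    """Up to 4 consecutive days with a stable / pre-exacerbation truth label.

    ``dates`` holds the non-missing days kept from the original 4-day window.
    """

    recording_id: str
    dates: list[dt.date]
    truth: str  # "stable" | "pre-exacerbation"

    def __post_init__(self) -> None:
        if not 1 <= len(self.dates) <= TEST_PERIOD_DAYS:
            raise ValueError("a test period holds 1-4 days")
        if self.truth not in ("stable", "pre-exacerbation"):
            raise ValueError(f"unknown truth label {self.truth!r}")


# ---------------------------------------------------------------------------
# parsing

TELEMETRY_COLUMNS = [
    "timestamp",
    "flow_lpm",
    "breathing_rate_bpm",
    "inspiratory_amplitude",
    "valid",
]


def read_recording(
    telemetry_file: str | Path, metadata_record: dict
) -> Recording:
    """Parse one telemetry CSV plus its metadata record into a Recording.

    The telemetry dialect is one row per observed 5-minute slot with header
    ``timestamp,flow_lpm,breathing_rate_bpm,inspiratory_amplitude,valid``;
    absent rate/amplitude are empty fields, ``valid`` is 0/1.  Missing slots
    are simply absent rows.  Metadata supplies ``recording_id``, ``first_day``,
    ``discharge_date`` and ``exacerbation_onsets`` (list of ISO dates or a
    semicolon-joined string).
    """
    path = Path(telemetry_file)
    df = pd.read_csv(path, dtype={"valid": "Int64"})
    missing_cols = set(TELEMETRY_COLUMNS) - set(df.columns)
    if missing_cols:
        raise TelemetryError(f"{path.name}: missing columns {sorted(missing_cols)}")

    onsets = metadata_record.get("exacerbation_onsets", [])
    if isinstance(onsets, str):
        onsets = [s for s in onsets.split(";") if s]
    onsets = [_as_date(d) for d in onsets]

    samples: list[Sample] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            ts = dt.datetime.fromisoformat(str(row.timestamp))
        except ValueError as exc:
            raise TelemetryError(f"{path.name} line {i}: bad timestamp") from exc
        rate = None if pd.isna(row.breathing_rate_bpm) else float(row.breathing_rate_bpm)
        amp = None if pd.isna(row.inspiratory_amplitude) else float(row.inspiratory_amplitude)
        if pd.isna(row.valid) or pd.isna(row.flow_lpm):
            raise TelemetryError(f"{path.name} line {i}: flow and valid are required")
        try:
            samples.append(
                Sample(ts, float(row.flow_lpm), rate, amp, bool(int(row.valid)))
            )
        except TelemetryError as exc:
            raise TelemetryError(f"{path.name} line {i}: {exc}") from exc
    for a, b in zip(samples, samples[1:]):
        if b.timestamp == a.timestamp:
            raise TelemetryError(f"{path.name}: duplicate timestamp {a.timestamp}")
        if b.timestamp < a.timestamp:
            raise TelemetryError(
                f"{path.name}: out-of-order timestamp {b.timestamp}"
            )
    return Recording(
        recording_id=str(metadata_record["recording_id"]),
        samples=samples,
        first_day=_as_date(metadata_record["first_day"]),
        discharge_date=_as_date(metadata_record["discharge_date"]),
        exacerbation_onsets=onsets,
    )


def read_metadata(path: str | Path) -> list[dict]:
    """Read a cohort metadata table (CSV) into per-recording dicts."""
    df = pd.read_csv(path, dtype=str).fillna("")
    return df.to_dict(orient="records")


def _as_date(value) -> dt.date:
    if isinstance(value, dt.date) and not isinstance(value, dt.datetime):
        return value
    if isinstance(value, dt.datetime):
        return value.date()
    return dt.date.fromisoformat(str(value))


# ---------------------------------------------------------------------------
# filtering and daily views


def filter_valid(recording: Recording) -> Recording:
    """Mask rate/amplitude of invalid samples, keeping them for usage.

    Only slots with spontaneous breathing and good signal quality contribute
    respiratory measures; invalid slots still document oxygen delivery, so the
    rows themselves are retained.  Idempotent.
    """
    out = []
    for s in recording.samples:
        if s.valid or (s.rate is None and s.amplitude is None):
            out.append(s)
        else:
            out.append(Sample(s.timestamp, s.flow, None, None, s.valid))
    return Recording(
        recording_id=recording.recording_id,
        samples=out,
        first_day=recording.first_day,
        discharge_date=recording.discharge_date,
        exacerbation_onsets=list(recording.exacerbation_onsets),
    )


def summarize_day(
    recording: Recording,
    date: dt.date,
    min_valid_samples: int = DEFAULT_MIN_VALID_SAMPLES,
) -> DayData:
    """Compute the three daily views for one calendar day.

    Usage is 5 min per sample with positive flow; means/distribution/segments
    use valid samples only.  Segments split wherever consecutive valid samples
    are not adjacent on the 5-minute grid.
    """
    if not (recording.first_day <= date <= recording.discharge_date):
        raise TelemetryError(
            f"{recording.recording_id}: {date} outside recording span"
        )
    key = (date, min_valid_samples)
    cached = recording._day_cache.get(key)
    if cached is not None:
        return cached
    day_samples = recording.samples_on(date)
    n_flow_positive = sum(1 for s in day_samples if s.flow > 0)
    valid = [
        s for s in day_samples if s.valid and s.rate is not None
    ]
    n_valid = len(valid)
    if n_valid:
        arr = np.array([[s.rate, s.amplitude] for s in valid], dtype=float)
        mean_rate, mean_amplitude = arr.mean(axis=0)
    else:
        arr = np.empty((0, 2))
        mean_rate = mean_amplitude = None

    segments: list[np.ndarray] = []
    start = 0
    for i in range(1, n_valid + 1):
        contiguous = (
            i < n_valid
            and (valid[i].timestamp - valid[i - 1].timestamp)
            == dt.timedelta(minutes=SLOT_MINUTES)
        )
        if not contiguous:
            segments.append(arr[start:i])
            start = i

    day = DayData(
        date=date,
        day_index=recording.day_index(date),
        usage_hours=n_flow_positive * SLOT_MINUTES / 60.0,
        mean_rate=None if mean_rate is None else float(mean_rate),
        mean_amplitude=None if mean_amplitude is None else float(mean_amplitude),
        distribution=arr,
        segments=segments,
        n_valid=n_valid,
        missing=n_valid < min_valid_samples,
    )
    recording._day_cache[key] = day
    return day


def select_baseline_week(
    recording: Recording,
    min_valid_samples: int = DEFAULT_MIN_VALID_SAMPLES,
    min_baseline_days: int = DEFAULT_MIN_BASELINE_DAYS,
) -> list[DayData]:
    """The 7 calendar days ending at discharge, as DayData (missing included).

    Raises :class:`EligibilityError` when fewer than ``min_baseline_days`` of
    them are non-missing — too little stable reference data to train a model.
    """
    days = [
        summarize_day(
            recording,
            recording.discharge_date - dt.timedelta(days=offset),
            min_valid_samples,
        )
        for offset in range(BASELINE_DAYS - 1, -1, -1)
    ]
    n_present = sum(1 for d in days if not d.missing)
    if n_present < min_baseline_days:
        raise EligibilityError(
            f"{recording.recording_id}: insufficient_baseline_data "
            f"({n_present} non-missing baseline days < {min_baseline_days})"
        )
    return days


def check_eligibility(
    recording: Recording,
    min_valid_samples: int = DEFAULT_MIN_VALID_SAMPLES,
    min_baseline_days: int = DEFAULT_MIN_BASELINE_DAYS,
) -> EligibilityReport:
    """Apply the recording-selection rules.

    A recording is excluded when it lasts at most three weeks, when an
    exacerbation falls inside the baseline week (every week is then unsuitable
    as a stable reference), when the baseline week holds too little data, or —
    for recordings with exacerbations — when no onset keeps any data in its
    preceding week.
    """
    reasons: list[str] = []
    usable: list[dt.date] = []

    if recording.duration_days <= MIN_DURATION_DAYS:
        reasons.append("too_short")
    else:
        baseline_start = recording.baseline_start
        if any(o >= baseline_start for o in recording.exacerbation_onsets):
            reasons.append("baseline_contaminated")
        else:
            try:
                select_baseline_week(recording, min_valid_samples, min_baseline_days)
            except EligibilityError:
                reasons.append("insufficient_baseline_data")
        if not reasons:
            for onset in recording.exacerbation_onsets:
                week_before = [
                    onset - dt.timedelta(days=d) for d in range(1, 8)
                ]
                has_data = any(
                    recording.first_day <= day
                    and not summarize_day(recording, day, min_valid_samples).missing
                    for day in week_before
                )
                if has_data:
                    usable.append(onset)
            if recording.exacerbation_onsets and not usable:
                reasons.append("no_usable_exacerbation")

    return EligibilityReport(
        status="excluded" if reasons else "eligible",
        reasons=reasons,
        usable_exacerbations=sorted(usable),
    )


# ---------------------------------------------------------------------------
# test-period extraction


def extract_pre_exacerbation_periods(
    recording: Recording,
    min_valid_samples: int = DEFAULT_MIN_VALID_SAMPLES,
) -> list[TestPeriod]:
    """The up-to-4 days preceding each usable exacerbation onset.

    The onset day itself is never included; days before the first recorded day
    and missing days are dropped, so periods may hold fewer than 4 days.
    """
    report = check_eligibility(recording, min_valid_samples)
    periods = []
    for onset in report.usable_exacerbations:
        window = [
            onset - dt.timedelta(days=d)
            for d in range(TEST_PERIOD_DAYS, 0, -1)
        ]
        kept = [
            day
            for day in window
            if recording.first_day <= day
            and not summarize_day(recording, day, min_valid_samples).missing
        ]
        if kept:
            periods.append(
                TestPeriod(recording.recording_id, kept, "pre-exacerbation")
            )
    return periods


def stable_period_starts(
    recording: Recording,
    min_valid_samples: int = DEFAULT_MIN_VALID_SAMPLES,
) -> list[int]:
    """Feasible start day indices for stable windows.

    A window starts on or after day 15 and ends strictly before the first
    baseline day; starts whose 4-day window keeps no non-missing day are
    dropped (they could not yield a scoreable period).
    """
    baseline_start_index = recording.day_index(recording.baseline_start)
    feasible = []
    for s in range(STABLE_EARLIEST_DAY, baseline_start_index - TEST_PERIOD_DAYS + 1):
        window = [recording.date_of_day(s + i) for i in range(TEST_PERIOD_DAYS)]
        if any(
            not summarize_day(recording, day, min_valid_samples).missing
            for day in window
        ):
            feasible.append(s)
    return feasible


def sample_stable_period(
    recording: Recording,
    rng: np.random.Generator,
    min_valid_samples: int = DEFAULT_MIN_VALID_SAMPLES,
) -> TestPeriod:
    """Draw one 4-day window of assumed stability, uniformly over feasible starts.

    Deterministic given the generator state.  Raises
    :class:`EligibilityError` when no feasible window exists (the recording is
    unusable as a control).
    """
    starts = stable_period_starts(recording, min_valid_samples)
    if not starts:
        raise EligibilityError(
            f"{recording.recording_id}: no feasible stable window "
            "(stay too short between day 15 and the baseline week)"
        )
    s = int(rng.choice(starts))
    window = [recording.date_of_day(s + i) for i in range(TEST_PERIOD_DAYS)]
    kept = [
        day
        for day in window
        if not summarize_day(recording, day, min_valid_samples).missing
    ]
    return TestPeriod(recording.recording_id, kept, "stable")
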