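import datetime as dt

import numpy as np
import pytest

from respnovel.telemetry import Recording, Sample

FIRST_DAY = dt.date(2021, 3, 1)


def build_recording(
    duration_days,
    day_values=None,
    onsets=(),
    recording_id="r1",
    n_valid_default=24,
    rate_default=18.0,
    amplitude_default=0.8,
):
    """Construct a recording from compact per-day specs.

    ``day_values`` maps 1-based day index to a dict with optional keys
    ``rate``, ``amplitude``, ``n_valid``, ``n_invalid`` (invalid samples are
    appended after the valid run, flow-positive but masked).  Days absent from
    the map get the defaults; pass ``{"n_valid": 0}`` for an empty day and
    ``None`` (as the day's entry) for a day with no rows at all.
    """
    day_values = day_values or {}
    samples = []
    for day in range(1, duration_days + 1):
        spec = day_values.get(day, {})
        if spec is None:
            continue
        date = FIRST_DAY + dt.timedelta(days=day - 1)
        midnight = dt.datetime.combine(date, dt.time())
        n_valid = spec.get("n_valid", n_valid_default)
        n_invalid = spec.get("n_invalid", 0)
        rate = spec.get("rate", rate_default)
        amplitude = spec.get("amplitude", amplitude_default)
        slot = 0
        for _ in range(n_valid):
            samples.append(
                Sample(
                    midnight + dt.timedelta(minutes=5 * slot),
                    2.0,
                    float(rate),
                    float(amplitude),
                    True,
                )
            )
            slot += 1
        for _ in range(n_invalid):
            samples.append(
                Sample(midnight + dt.timedelta(minutes=5 * slot), 2.0, None, None, False)
            )
            slot += 1
    return Recording(
        recording_id=recording_id,
        samples=samples,
        first_day=FIRST_DAY,
        discharge_date=FIRST_DAY + dt.timedelta(days=duration_days - 1),
        exacerbation_onsets=[
            FIRST_DAY + dt.timedelta(days=d - 1) for d in onsets
        ],
    )


def day_date(day_index):
    return FIRST_DAY + dt.timedelta(days=day_index - 1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
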