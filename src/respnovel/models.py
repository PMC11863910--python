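"""Per-recording baseline models and daily novelty scores.

Novelty detection here is per patient: a reference model is trained on the
baseline week (the final week before discharge, taken as the patient's stable
state), every baseline day is scored against it to establish limits of
normality, and test days are flagged by how far their score strays from those
limits.

Three model families represent a day at increasing resolution:

* single daily measure — any non-empty subset of {usage, mean breathing rate,
  mean inspiratory amplitude}; score is the Euclidean distance between the
  day's (standardized) summary and the baseline-week mean;
* daily distribution — the empirical joint distribution of valid
  (rate, amplitude) samples; the reference is the 2-Wasserstein barycenter of
  the baseline days' distributions and the score the W2 distance to it;
* daily time series — a 2-state Gaussian hidden Markov model fit on the
  baseline week's gap-split valid sequences; the score is the
  length-normalised negative log-likelihood of the day under the model.

Breathing rate (breaths/min) and inspiratory amplitude (device units) live on
scales ~20x apart, so all multivariate geometry is computed after z-scoring
each variable by its baseline statistics.  For single-variable models this is
a monotone rescaling and leaves ROC analyses unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import hmm as _hmm
from .telemetry import DayData
from .transport import free_support_barycenter, wasserstein_distance

EPS = 1e-8

SINGLE_MEASURE_VARIABLES = ("usage", "rate", "amplitude")
#: the six reference methods compared in the evaluation
METHODS = ("usage", "rate", "amplitude", "combined", "barycenter", "hmm")
#: variable sets behind each single-measure method name
METHOD_VARIABLES = {
    "usage": ("usage",),
    "rate": ("rate",),
    "amplitude": ("amplitude",),
    "combined": ("rate", "amplitude"),
}


class FitError(ValueError):
    """Baseline data insufficient to fit the requested model."""


@dataclass(frozen=True)
class NoveltyScore:
    """A day's scalar deviation from the baseline model."""

    value: float
    method: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("novelty score must be finite")


@dataclass
class Standardizer:
    """Per-variable z-scoring by statistics pooled over baseline valid samples."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, samples: np.ndarray) -> "Standardizer":
        samples = np.atleast_2d(samples)
        sd = samples.std(axis=0, ddof=1) if samples.shape[0] > 1 else np.zeros(
            samples.shape[1]
        )
        return cls(mean=samples.mean(axis=0), sd=np.maximum(sd, EPS))

    def transform(self, samples: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(samples) - self.mean) / self.sd

    def inverse(self, samples: np.ndarray) -> np.ndarray:
        return np.atleast_2d(samples) * self.sd + self.mean


def _present_days(baseline_days: list[DayData]) -> list[DayData]:
    return [d for d in baseline_days if not d.missing]


# ---------------------------------------------------------------------------
# single daily measure


@dataclass
class SingleMeasureModel:
    variables: tuple[str, ...]
    reference: np.ndarray  # per-variable baseline-week mean
    scale: np.ndarray  # per-variable baseline-week sd, floored

    def day_vector(self, day: DayData) -> np.ndarray | None:
        values = [day.summary(v) for v in self.variables]
        if day.missing or any(v is None for v in values):
            return None
        return np.asarray(values, dtype=float)


def fit_single_measure(
    baseline_days: list[DayData], variables: tuple[str, ...]
) -> SingleMeasureModel:
    """Baseline-week mean and sd of the selected daily summaries.

    Uses the non-missing baseline days; sample standard deviation (n-1
    denominator) floored at ``EPS`` so identical weeks still score.
    """
    variables = tuple(variables)
    if not variables or any(v not in SINGLE_MEASURE_VARIABLES for v in variables):
        raise ValueError(f"variables must be a non-empty subset of {SINGLE_MEASURE_VARIABLES}")
    days = _present_days(baseline_days)
    if len(days) < 2:
        raise FitError("need at least 2 non-missing baseline days")
    values = np.array(
        [[d.summary(v) for v in variables] for d in days], dtype=float
    )
    return SingleMeasureModel(
        variables=variables,
        reference=values.mean(axis=0),
        scale=np.maximum(values.std(axis=0, ddof=1), EPS),
    )


def score_single_measure(
    model: SingleMeasureModel, day: DayData
) -> NoveltyScore | None:
    """Euclidean distance between the day's summary and the baseline mean.

    Computed in standardized coordinates; ``None`` when the day is missing a
    required variable.
    """
    x = model.day_vector(day)
    if x is None:
        return None
    z = (x - model.reference) / model.scale
    return NoveltyScore(float(np.sqrt(np.sum(z * z))), "+".join(model.variables))


# ---------------------------------------------------------------------------
# daily distribution / Wasserstein barycenter


@dataclass
class BarycenterModel:
    support: np.ndarray  # (N, 2) in standardized (rate, amplitude) space
    weights: np.ndarray  # simplex, length N
    standardizer: Standardizer
    objective: float = float("nan")


def fit_barycenter(
    baseline_days: list[DayData],
    rng: np.random.Generator,
    max_support: int = 50,
    max_iter: int = 30,
    tol: float = 1e-5,
) -> BarycenterModel:
    """Free-support W2 barycenter of the baseline days' daily distributions.

    Support size is the median per-day valid-sample count, capped at
    ``max_support`` to bound the transport solves.
    """
    days = [d for d in _present_days(baseline_days) if d.n_valid >= 1]
    if len(days) < 2:
        raise FitError("need at least 2 baseline days with valid samples")
    standardizer = Standardizer.fit(np.vstack([d.distribution for d in days]))
    clouds = [standardizer.transform(d.distribution) for d in days]
    n_support = int(min(np.median([d.n_valid for d in days]), max_support))
    support, weights, objective = free_support_barycenter(
        clouds, n_support=max(n_support, 1), rng=rng, max_iter=max_iter, tol=tol
    )
    return BarycenterModel(support, weights, standardizer, objective)


def score_barycenter(model: BarycenterModel, day: DayData) -> NoveltyScore | None:
    """W2 distance between the day's standardized distribution and the barycenter."""
    if day.missing or day.n_valid < 1:
        return None
    cloud = model.standardizer.transform(day.distribution)
    d = wasserstein_distance(model.support, cloud, wx=model.weights)
    return NoveltyScore(d, "barycenter")


# ---------------------------------------------------------------------------
# daily time series / hidden Markov model


@dataclass
class HmmModel:
    params: _hmm.HmmParams  # in standardized (rate, amplitude) space
    standardizer: Standardizer
    loglik_history: list[float] = field(default_factory=list)

    def state_means_original(self) -> np.ndarray:
        """Per-state emission means back in original units (K, 2)."""
        return self.standardizer.inverse(self.params.means)

    def state_sds_original(self) -> np.ndarray:
        return np.sqrt(self.params.variances) * self.standardizer.sd


def fit_hmm(
    baseline_days: list[DayData],
    rng: np.random.Generator,
    n_states: int = 2,
    min_train_samples: int = 100,
    max_iter: int = 200,
    tol: float = 1e-6,
    var_floor: float = 1e-4,
) -> HmmModel:
    """Baum-Welch fit of the 2-state Gaussian HMM on the baseline week.

    Training sequences are the gap-split valid segments of every non-missing
    baseline day (multi-sequence EM, each segment restarting from the initial
    distribution).  Initialisation is a seeded 2-means partition; covariances
    are diagonal with a floor — robust on a single week of data.
    """
    days = _present_days(baseline_days)
    segments = [seg for d in days for seg in d.segments if seg.shape[0] > 0]
    total = sum(s.shape[0] for s in segments)
    if total < min_train_samples:
        raise FitError(
            f"insufficient baseline samples for HMM ({total} < {min_train_samples})"
        )
    standardizer = Standardizer.fit(np.vstack(segments))
    std_segments = [standardizer.transform(s) for s in segments]
    init = _hmm.kmeans_init(
        np.vstack(std_segments), n_states, rng, var_floor=var_floor
    )
    params, history = _hmm.baum_welch(
        std_segments, init, max_iter=max_iter, tol=tol, var_floor=var_floor
    )
    return HmmModel(params, standardizer, history)


def forward_loglik(model: HmmModel, segments: list[np.ndarray]) -> float:
    """Log-likelihood of (already standardized) segments under the model."""
    return _hmm.forward_loglik(model.params, segments)


def score_hmm(model: HmmModel, day: DayData) -> NoveltyScore | None:
    """Length-normalised negative log-likelihood of the day's time series.

    ``S = -(1/T) log P(day | model)`` over the day's gap-split segments,
    ``T`` the total number of valid samples.  Invariant under relabeling of
    the hidden states.
    """
    if day.missing or day.n_valid < 1:
        return None
    segments = [
        model.standardizer.transform(s) for s in day.segments if s.shape[0] > 0
    ]
    loglik = _hmm.forward_loglik(model.params, segments)
    return NoveltyScore(-loglik / day.n_valid, "hmm")


# ---------------------------------------------------------------------------
# unified fitting / scoring across the six methods


@dataclass
class ModelConfig:
    """Tunable parameters shared across baseline-model fits."""

    max_support: int = 50
    barycenter_max_iter: int = 30
    barycenter_tol: float = 1e-5
    hmm_min_train_samples: int = 100
    hmm_max_iter: int = 200
    hmm_tol: float = 1e-6
    hmm_var_floor: float = 1e-4


def fit_method(
    method: str,
    baseline_days: list[DayData],
    rng: np.random.Generator,
    config: ModelConfig | None = None,
):
    """Fit one of the six reference methods on a baseline week."""
    config = config or ModelConfig()
    if method in METHOD_VARIABLES:
        return fit_single_measure(baseline_days, METHOD_VARIABLES[method])
    if method == "barycenter":
        return fit_barycenter(
            baseline_days,
            rng,
            max_support=config.max_support,
            max_iter=config.barycenter_max_iter,
            tol=config.barycenter_tol,
        )
    if method == "hmm":
        return fit_hmm(
            baseline_days,
            rng,
            min_train_samples=config.hmm_min_train_samples,
            max_iter=config.hmm_max_iter,
            tol=config.hmm_tol,
            var_floor=config.hmm_var_floor,
        )
    raise ValueError(f"unknown method {method!r}")


def score_method(method: str, model, day: DayData) -> float | None:
    """Novelty score of one day under a fitted method; None for missing days."""
    if method in METHOD_VARIABLES:
        score = score_single_measure(model, day)
    elif method == "barycenter":
        score = score_barycenter(model, day)
    elif method == "hmm":
        score = score_hmm(model, day)
    else:
        raise ValueError(f"unknown method {method!r}")
    return None if score is None else score.value


# ---------------------------------------------------------------------------
# serialization


def model_to_dict(model) -> dict:
    """JSON-serialisable document for any fitted model (round-trip stable)."""
    if isinstance(model, SingleMeasureModel):
        return {
            "kind": "single_measure",
            "variables": list(model.variables),
            "reference": model.reference.tolist(),
            "scale": model.scale.tolist(),
        }
    if isinstance(model, BarycenterModel):
        return {
            "kind": "barycenter",
            "support": model.support.tolist(),
            "weights": model.weights.tolist(),
            "standardizer": {
                "mean": model.standardizer.mean.tolist(),
                "sd": model.standardizer.sd.tolist(),
            },
            "objective": model.objective,
        }
    if isinstance(model, HmmModel):
        return {
            "kind": "hmm",
            "startprob": model.params.startprob.tolist(),
            "transmat": model.params.transmat.tolist(),
            "means": model.params.means.tolist(),
            "variances": model.params.variances.tolist(),
            "standardizer": {
                "mean": model.standardizer.mean.tolist(),
                "sd": model.standardizer.sd.tolist(),
            },
        }
    raise TypeError(f"cannot serialise {type(model).__name__}")


def model_from_dict(doc: dict):
    kind = doc["kind"]
    if kind == "single_measure":
        return SingleMeasureModel(
            variables=tuple(doc["variables"]),
            reference=np.asarray(doc["reference"]),
            scale=np.asarray(doc["scale"]),
        )
    std = (
        Standardizer(
            mean=np.asarray(doc["standardizer"]["mean"]),
            sd=np.asarray(doc["standardizer"]["sd"]),
        )
        if "standardizer" in doc
        else None
    )
    if kind == "barycenter":
        return BarycenterModel(
            support=np.asarray(doc["support"]),
            weights=np.asarray(doc["weights"]),
            standardizer=std,
            objective=float(doc.get("objective", float("nan"))),
        )
    if kind == "hmm":
        return HmmModel(
            params=_hmm.HmmParams(
                startprob=np.asarray(doc["startprob"]),
                transmat=np.asarray(doc["transmat"]),
                means=np.asarray(doc["means"]),
                variances=np.asarray(doc["variances"]),
            ),
            standardizer=std,
        )
    raise ValueError(f"unknown model kind {kind!r}")


def save_model(model, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def load_model(path: str | Path):
    return model_from_dict(json.loads(Path(path).read_text()))
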