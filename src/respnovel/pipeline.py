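"""End-to-end evaluation: fit baselines, score days, resample, compare.

Ties the other modules together for a cohort of recordings: per recording it
fits the requested baseline models on the final-week data, establishes limits
of normality from in-sample baseline scores, scores every day any resampled
test set can touch (scores are cached per (recording, day, method) — stable
windows overlap heavily across the 50 repeats), then builds the per-repeat
ROC curves, the AUC matrix, mean ROC curves, sensitivities at fixed
specificity and the BY-adjusted method comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from .models import METHODS, ModelConfig, fit_method, score_method
from .telemetry import Recording, select_baseline_week

logger = logging.getLogger(__name__)


@dataclass
class EvalConfig:
    """Everything the evaluation sweep needs, in one place."""

    methods: tuple[str, ...] = METHODS
    n_values: tuple[int, ...] = (1, 2, 3, 4)
    repeats: int = ev.DEFAULT_REPEATS
    specificity: float = 0.5
    min_valid_samples: int = 12
    min_baseline_days: int = 4
    model: ModelConfig = field(default_factory=ModelConfig)


@dataclass
class EvaluationResult:
    """Per-repeat AUCs plus derived summaries for a cohort evaluation."""

    auc: pd.DataFrame  # repeats x (method, n) columns
    mean_curves: dict  # (method, n) -> MeanRoc
    sensitivity: pd.DataFrame  # methods x n, TPR at the fixed specificity
    comparison: ev.MethodComparison

    def auc_summary(self) -> pd.DataFrame:
        """Mean +/- sd AUC per method x n (the usual comparison layout)."""
        mean = self.auc.mean().unstack()
        sd = self.auc.std().unstack()
        return pd.DataFrame(
            {
                n: [f"{mean.loc[m, n]:.3f} ± {sd.loc[m, n]:.3f}" for m in mean.index]
                for n in mean.columns
            },
            index=mean.index,
        )

    def mean_auc(self, method: str, n: int) -> float:
        return float(self.auc[(method, n)].mean())


def fit_cohort_models(
    recordings: list[Recording],
    config: EvalConfig,
    seed: int,
) -> tuple[dict, dict]:
    """Fit every requested method per recording; derive limits of normality.

    Returns ``(models, limits)`` keyed by ``(recording_id, method)`` and by
    ``recording_id -> {method: NoveltyLimits}``.  Baseline scores are computed
    in-sample on the same week the model was trained on.
    """
    rng = np.random.default_rng(seed)
    models: dict = {}
    limits: dict = {}
    for rec in recordings:
        baseline = select_baseline_week(
            rec, config.min_valid_samples, config.min_baseline_days
        )
        limits[rec.recording_id] = {}
        for method in config.methods:
            model = fit_method(method, baseline, rng, config.model)
            models[(rec.recording_id, method)] = model
            baseline_scores = [
                s
                for d in baseline
                if (s := score_method(method, model, d)) is not None
            ]
            limits[rec.recording_id][method] = ev.compute_limits(baseline_scores)
    return models, limits


def score_needed_days(
    recordings: list[Recording],
    test_sets: list[list],
    models: dict,
    config: EvalConfig,
) -> dict:
    """Score every (recording, day) any test set touches, once per method."""
    by_id = {rec.recording_id: rec for rec in recordings}
    needed = sorted(
        {
            (p.recording_id, date)
            for ts in test_sets
            for p in ts
            for date in p.dates
        }
    )
    scores: dict = {m: {} for m in config.methods}
    from .telemetry import summarize_day

    for rid, date in needed:
        day = summarize_day(by_id[rid], date, config.min_valid_samples)
        for method in config.methods:
            scores[method][(rid, date)] = score_method(
                method, models[(rid, method)], day
            )
    return scores


def evaluate_cohort(
    recordings: list[Recording],
    config: EvalConfig | None = None,
    seed: int = 0,
) -> EvaluationResult:
    """Run the full resampled comparison of novelty-detection methods.

    All randomness (stable-window resampling, barycenter/HMM initialisation)
    derives from ``seed``.
    """
    config = config or EvalConfig()
    rng = np.random.default_rng(seed)
    model_seed = int(rng.integers(2**31 - 1))
    sampling_seed = int(rng.integers(2**31 - 1))

    test_sets = ev.build_test_sets(
        recordings,
        repeats=config.repeats,
        seed=sampling_seed,
        min_valid_samples=config.min_valid_samples,
    )
    used_ids = {p.recording_id for ts in test_sets for p in ts}
    used = [r for r in recordings if r.recording_id in used_ids]
    logger.info("evaluating %d recordings, %d repeats", len(used), config.repeats)

    models, limits = fit_cohort_models(used, config, model_seed)
    scores = score_needed_days(used, test_sets, models, config)

    columns = [(m, n) for m in config.methods for n in config.n_values]
    auc_rows = []
    curves: dict = {col: [] for col in columns}
    for ts in test_sets:
        row = {}
        for method in config.methods:
            method_limits = {rid: limits[rid][method] for rid in limits}
            for n in config.n_values:
                curve = ev.roc_curve(ts, scores[method], method_limits, n)
                curves[(method, n)].append(curve)
                row[(method, n)] = ev.auc(curve)
        auc_rows.append(row)
    auc_df = pd.DataFrame(auc_rows, columns=pd.MultiIndex.from_tuples(columns))

    mean_curves = {col: ev.mean_roc(curves[col]) for col in columns}
    sensitivity = pd.DataFrame(
        {
            n: [
                ev.sensitivity_at_specificity(
                    mean_curves[(m, n)], config.specificity
                )
                for m in config.methods
            ]
            for n in config.n_values
        },
        index=list(config.methods),
    )
    comparison = ev.compare_methods(auc_df)
    return EvaluationResult(
        auc=auc_df,
        mean_curves=mean_curves,
        sensitivity=sensitivity,
        comparison=comparison,
    )


def write_results(result: EvaluationResult, out_dir: str | Path) -> Path:
    """Write the AUC matrix, summaries, ROC curves and p-values as CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.auc.to_csv(out / "auc_per_repeat.csv")
    result.auc_summary().to_csv(out / "auc_summary.csv")
    result.sensitivity.to_csv(out / "sensitivity_at_specificity.csv")
    result.comparison.raw_p.to_csv(out / "pvalues_raw.csv")
    result.comparison.adjusted_p.to_csv(out / "pvalues_adjusted.csv")
    rows = []
    for (method, n), curve in result.mean_curves.items():
        for fpr, tpr, lo, hi in zip(
            curve.fpr_grid, curve.mean_tpr, curve.ci_lower, curve.ci_upper
        ):
            rows.append(
                {
                    "method": method,
                    "n": n,
                    "fpr": fpr,
                    "mean_tpr": tpr,
                    "ci_lower": lo,
                    "ci_upper": hi,
                }
            )
    pd.DataFrame(rows).to_csv(out / "mean_roc.csv", index=False)
    return out
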