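"""Day/period classification and the resampled ROC/AUC evaluation machinery.

From each recording's baseline novelty scores, limits of normality are set at
``m_b + k * s_b`` (mean and standard deviation of the baseline scores).  A
test day is *atypical* when its score exceeds the limit; a period of up to 4
consecutive days is *pre-exacerbation* when it contains at least ``n``
atypical days.  Sweeping the threshold multiplier ``k`` traces a ROC curve
over the test set; the test-set sampling (one random stable window per
control) is repeated 50 times, yielding 50 ROC curves and AUCs per method.
Mean ROC curves with pointwise confidence bands, sensitivities at fixed
specificity, and BY-adjusted one-sided paired t-tests compare the methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .telemetry import (
    Recording,
    TestPeriod,
    check_eligibility,
    extract_pre_exacerbation_periods,
    sample_stable_period,
)

logger = logging.getLogger(__name__)

EPS = 1e-8
#: threshold-multiplier sweep for ROC construction: k in m_b + k * s_b
DEFAULT_K_GRID = np.concatenate(
    [[-np.inf], np.arange(-5.0, 10.0 + 1e-9, 0.1), [np.inf]]
)
DEFAULT_REPEATS = 50
#: FPR grid step for vertical averaging of ROC curves
MEAN_ROC_GRID_STEP = 0.02


class EvaluationError(ValueError):
    pass


class AllDaysMissingError(EvaluationError):
    """Every day label in a period is missing; the period carries no signal."""


@dataclass
class NoveltyLimits:
    """Limits of normality from the baseline-week novelty scores."""

    m_b: float
    s_b: float


def compute_limits(baseline_scores: list[float]) -> NoveltyLimits:
    """Mean and (floored) sample standard deviation of baseline scores."""
    scores = np.asarray(baseline_scores, dtype=float)
    if scores.size < 2:
        raise EvaluationError("need at least 2 baseline scores")
    return NoveltyLimits(
        m_b=float(scores.mean()),
        s_b=float(max(scores.std(ddof=1), EPS)),
    )


def classify_day(score: float | None, limits: NoveltyLimits, k: float) -> str:
    """'atypical' when the score strictly exceeds ``m_b + k * s_b``.

    One-sided: novelty scores are deviation magnitudes, so only the upper tail
    signals atypicality.  A missing score classifies as 'missing'.
    """
    if score is None:
        return "missing"
    return "atypical" if score > limits.m_b + k * limits.s_b else "normal"


def classify_period(day_labels: list[str], n: int) -> str:
    """'pre-exacerbation' when at least ``n`` non-missing days are atypical."""
    if not 1 <= n <= 4:
        raise ValueError("n must be in 1..4")
    present = [lab for lab in day_labels if lab != "missing"]
    if not present:
        raise AllDaysMissingError("all day labels missing")
    n_atypical = sum(1 for lab in present if lab == "atypical")
    return "pre-exacerbation" if n_atypical >= n else "stable"


# ---------------------------------------------------------------------------
# test-set construction


def build_test_sets(
    cohort: list[Recording],
    repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
    min_valid_samples: int | None = None,
) -> list[list[TestPeriod]]:
    """Resampled test sets over an eligible cohort.

    Pre-exacerbation periods are fixed across repeats; each repeat draws one
    fresh stable window per eligible control.  Fully reproducible from
    ``seed``.
    """
    kwargs = {} if min_valid_samples is None else {"min_valid_samples": min_valid_samples}
    cases, controls = [], []
    for rec in cohort:
        report = check_eligibility(rec, **kwargs)
        if not report.eligible:
            logger.info("excluding %s: %s", rec.recording_id, report.reasons)
            continue
        if report.usable_exacerbations:
            cases.append(rec)
        else:
            controls.append(rec)
    if not cases or not controls:
        raise EvaluationError(
            f"need at least one eligible case and control "
            f"(got {len(cases)} cases, {len(controls)} controls)"
        )
    pre_periods = [
        p for rec in cases for p in extract_pre_exacerbation_periods(rec, **kwargs)
    ]
    rng = np.random.default_rng(seed)
    test_sets = []
    for _ in range(repeats):
        stable = []
        for rec in controls:
            try:
                stable.append(sample_stable_period(rec, rng, **kwargs))
            except Exception:
                logger.warning("no stable window for %s", rec.recording_id)
        if not stable:
            raise EvaluationError("no stable periods could be sampled")
        test_sets.append(pre_periods + stable)
    return test_sets


# ---------------------------------------------------------------------------
# ROC machinery


@dataclass
class RocCurve:
    """ROC points sorted by FPR (endpoints (0,0) and (1,1) included)."""

    points: np.ndarray  # (n, 2) of (FPR, TPR)
    k_grid: np.ndarray = field(default_factory=lambda: DEFAULT_K_GRID)

    @property
    def fpr(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def tpr(self) -> np.ndarray:
        return self.points[:, 1]


def _period_stat(
    period: TestPeriod,
    scores: dict,
    limits: dict,
    n: int,
) -> float | None:
    """The n-th largest standardized day score; the period is flagged iff
    this statistic exceeds k.  None when no day is scored (period dropped)."""
    lim = limits[period.recording_id]
    zs = []
    for date in period.dates:
        s = scores.get((period.recording_id, date))
        if s is not None:
            zs.append((s - lim.m_b) / lim.s_b)
    if not zs:
        return None
    if len(zs) < n:
        return -np.inf  # can never reach n atypical days
    return float(np.sort(zs)[-n])


def roc_curve(
    test_set: list[TestPeriod],
    scores: dict,
    limits: dict,
    n: int,
    k_grid: np.ndarray | None = None,
) -> RocCurve:
    """ROC over the threshold-multiplier sweep for one test set.

    ``scores`` maps ``(recording_id, date)`` to a novelty score (or None for
    missing days); ``limits`` maps ``recording_id`` to its
    :class:`NoveltyLimits`.  For each k, days are classified, then periods;
    TPR is the flagged fraction of pre-exacerbation periods, FPR of stable
    periods.  Periods with no scored day are dropped (logged).
    """
    if not test_set:
        raise EvaluationError("empty test set")
    pos, neg = [], []
    n_dropped = 0
    for period in test_set:
        stat = _period_stat(period, scores, limits, n)
        if stat is None:
            n_dropped += 1
            continue
        (pos if period.truth == "pre-exacerbation" else neg).append(stat)
    if n_dropped:
        logger.info("dropped %d periods with no scored day", n_dropped)
    if not pos or not neg:
        raise EvaluationError("test set must keep both classes after drops")
    pos, neg = np.asarray(pos), np.asarray(neg)
    if k_grid is None:
        # the sweep must span "everything atypical" through "nothing
        # atypical": extend the default range at the same step whenever
        # period statistics fall outside it
        finite = np.concatenate([pos[np.isfinite(pos)], neg[np.isfinite(neg)]])
        lo, hi = -5.0, 10.0
        if finite.size:
            lo = min(lo, np.floor((finite.min() - 0.1) * 10) / 10)
            hi = max(hi, np.ceil((finite.max() + 0.1) * 10) / 10)
        k_grid = np.concatenate([[-np.inf], np.arange(lo, hi + 1e-9, 0.1), [np.inf]])
    else:
        k_grid = np.asarray(k_grid, dtype=float)
    tpr = np.array([(pos > k).mean() for k in k_grid])
    fpr = np.array([(neg > k).mean() for k in k_grid])
    pts = np.vstack([np.column_stack([fpr, tpr]), [[0.0, 0.0], [1.0, 1.0]]])
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    return RocCurve(points=pts[order], k_grid=k_grid)


def auc(roc: RocCurve) -> float:
    """Trapezoidal area under the ROC curve."""
    return float(np.trapezoid(roc.tpr, roc.fpr))


@dataclass
class MeanRoc:
    """Vertically averaged ROC with pointwise normal 95% confidence band."""

    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray


def _interp_tpr(curve: RocCurve, grid: np.ndarray) -> np.ndarray:
    # collapse duplicate FPR values to their maximal TPR (upper staircase envelope)
    fpr, tpr = curve.fpr, curve.tpr
    uniq, idx = np.unique(fpr, return_inverse=True)
    best = np.zeros_like(uniq)
    np.maximum.at(best, idx, tpr)
    return np.interp(grid, uniq, best)


def mean_roc(curves: list[RocCurve], grid_step: float = MEAN_ROC_GRID_STEP) -> MeanRoc:
    """Pointwise mean and 95% CI of TPR on a fixed FPR grid."""
    if len(curves) < 2:
        raise EvaluationError("need at least 2 curves to average")
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    tprs = np.array([_interp_tpr(c, grid) for c in curves])
    mean = tprs.mean(axis=0)
    half = 1.96 * tprs.std(axis=0, ddof=1) / np.sqrt(len(curves))
    return MeanRoc(
        fpr_grid=grid,
        mean_tpr=mean,
        ci_lower=np.clip(mean - half, 0, 1),
        ci_upper=np.clip(mean + half, 0, 1),
    )


def sensitivity_at_specificity(curve: MeanRoc, specificity: float = 0.5) -> float:
    """TPR of the mean ROC at FPR = 1 - specificity (linear interpolation)."""
    return float(np.interp(1.0 - specificity, curve.fpr_grid, curve.mean_tpr))


# ---------------------------------------------------------------------------
# method comparison


@dataclass
class MethodComparison:
    """All ordered-pair one-sided paired t-tests on per-repeat AUCs.

    ``raw_p``/``adjusted_p`` are indexed by "better" column, with one column
    per "worse" column; ``adjusted_p`` applies the Benjamini-Yekutieli
    correction once over the whole family.
    """

    raw_p: pd.DataFrame
    adjusted_p: pd.DataFrame


def compare_methods(auc_matrix: pd.DataFrame) -> MethodComparison:
    """Compare per-repeat AUC columns (one per method x n combination).

    For each ordered pair (a, b) the one-sided paired t-test of
    "mean AUC of a exceeds that of b" is computed on the repeat-paired
    differences; identical columns give p = 1 by convention.  The BY
    adjustment (valid under arbitrary dependence) is applied over all pairs.
    """
    cols = list(auc_matrix.columns)
    if len(cols) < 2:
        raise EvaluationError("need at least 2 columns to compare")
    if auc_matrix.isna().any().any():
        raise EvaluationError("AUC matrix has unequal repeat counts")
    pairs = [(a, b) for a in cols for b in cols if a != b]
    raw = []
    for a, b in pairs:
        diff = auc_matrix[a].to_numpy() - auc_matrix[b].to_numpy()
        if np.allclose(diff, 0):
            raw.append(1.0)
        else:
            raw.append(float(stats.ttest_rel(
                auc_matrix[a], auc_matrix[b], alternative="greater"
            ).pvalue))
    adjusted = benjamini_yekutieli(np.asarray(raw))
    raw_df = pd.DataFrame(np.nan, index=cols, columns=cols)
    adj_df = pd.DataFrame(np.nan, index=cols, columns=cols)
    for (a, b), p_raw, p_adj in zip(pairs, raw, adjusted):
        raw_df.loc[[a], [b]] = p_raw
        adj_df.loc[[a], [b]] = p_adj
    return MethodComparison(raw_p=raw_df, adjusted_p=adj_df)


def benjamini_yekutieli(pvalues: np.ndarray) -> np.ndarray:
    """BY step-up adjusted p-values: p * m * c(m) / rank, monotonised, capped at 1."""
    adjusted = multipletests(np.asarray(pvalues, float), method="fdr_by")[1]
    return np.minimum(adjusted, 1.0)
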