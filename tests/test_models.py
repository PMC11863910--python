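import numpy as np
import pytest
from scipy.stats import mannwhitneyu, norm

import respnovel as rn
from respnovel.models import (
    EPS,
    FitError,
    fit_barycenter,
    fit_hmm,
    fit_single_measure,
    load_model,
    model_from_dict,
    model_to_dict,
    save_model,
    score_barycenter,
    score_hmm,
    score_single_measure,
)
from respnovel.hmm import HmmParams

from conftest import FIRST_DAY, build_recording


def baseline_from(recording, **kwargs):
    return rn.select_baseline_week(recording, **kwargs)


def make_days(value_specs, variable="usage"):
    """Baseline DayData list with given daily usage (via n_valid slots)."""
    spec = {}
    for i, v in enumerate(value_specs):
        if v is None:
            spec[24 + i] = None
        else:
            spec[24 + i] = {"n_valid": int(v * 12)}
    rec = build_recording(30, spec)
    return baseline_from(rec)


class TestSingleMeasure:
    def test_reference_and_scale_arithmetic(self):
        days = make_days([10, 12, 14, 10, 12, 14, 12])
        model = fit_single_measure(days, ("usage",))
        values = [10, 12, 14, 10, 12, 14, 12]
        assert model.reference[0] == pytest.approx(np.mean(values))
        assert model.scale[0] == pytest.approx(np.std(values, ddof=1))

    def test_identical_days_floor_the_scale(self):
        days = make_days([12] * 7)
        model = fit_single_measure(days, ("usage",))
        assert model.scale[0] == EPS

    def test_missing_day_excluded_from_statistics(self):
        days = make_days([10, 12, 14, None, 10, 12, 14])
        model = fit_single_measure(days, ("usage",))
        kept = [10, 12, 14, 10, 12, 14]
        assert model.reference[0] == pytest.approx(np.mean(kept))
        assert model.scale[0] == pytest.approx(np.std(kept, ddof=1))

    def test_fewer_than_two_days_rejected(self):
        days = make_days([12] * 7)
        with pytest.raises(FitError):
            fit_single_measure([days[0]], ("usage",))

    def test_day_at_reference_scores_zero(self):
        days = make_days([10, 12, 14, 10, 12, 14, 12])
        model = fit_single_measure(days, ("usage",))
        day = make_days([12] * 7)[0]
        assert score_single_measure(model, day).value == pytest.approx(0.0)

    def test_usage_score_arithmetic(self):
        from respnovel.models import SingleMeasureModel

        model = SingleMeasureModel(("usage",), np.array([12.0]), np.array([2.0]))
        day = make_days([7] * 7)[0]
        assert score_single_measure(model, day).value == pytest.approx(2.5)

    def test_combined_score_is_standardized_euclidean(self):
        from respnovel.models import SingleMeasureModel

        model = SingleMeasureModel(
            ("rate", "amplitude"), np.array([18.0, 0.5]), np.array([2.0, 0.1])
        )
        rec = build_recording(30, {24: {"rate": 20.0, "amplitude": 0.4}})
        day = baseline_from(rec)[0]
        assert score_single_measure(model, day).value == pytest.approx(
            np.sqrt(2), abs=1e-6
        )

    def test_missing_day_yields_no_score(self):
        days = make_days([10, 12, 14, 10, 12, 14, 12])
        model = fit_single_measure(days, ("usage",))
        missing = make_days([0.0] + [12] * 6)[0]
        assert missing.missing
        assert score_single_measure(model, missing) is None


class TestBarycenterModel:
    def _recording(self, rng, shift=0.0):
        spec = {}
        for d in range(1, 31):
            spec[d] = {"n_valid": 40, "rate": 18.0, "amplitude": 0.8}
        return build_recording(30, spec)

    def test_identical_baseline_days_score_zero_on_same_day(self, rng):
        rec = self._recording(rng)
        baseline = baseline_from(rec)
        model = fit_barycenter(baseline, rng)
        assert score_barycenter(model, baseline[0]).value == pytest.approx(0.0, abs=1e-6)

    def test_score_consistent_with_direct_wasserstein_call(self, rng):
        recs, _ = rn.generate_cohort(rn.CohortConfig(n_cases=0, n_controls=1, seed=3))
        baseline = baseline_from(recs[0])
        model = fit_barycenter(baseline, rng, max_support=20)
        day = baseline[2]
        direct = rn.wasserstein_distance(
            model.support,
            model.standardizer.transform(day.distribution),
            wx=model.weights,
        )
        assert score_barycenter(model, day).value == pytest.approx(direct, abs=1e-12)

    def test_single_point_shift_scores_the_shift(self):
        from respnovel.models import BarycenterModel, Standardizer

        std = Standardizer(mean=np.zeros(2), sd=np.ones(2))
        model = BarycenterModel(np.array([[0.0, 0.0]]), np.array([1.0]), std)
        rec = build_recording(30, {24: {"n_valid": 12, "rate": 0.7, "amplitude": 0.0001}})
        day = baseline_from(rec, min_baseline_days=1)[0]
        day.distribution = np.array([[0.7, 0.0]])
        assert score_barycenter(model, day).value == pytest.approx(0.7, abs=1e-9)

    def test_insufficient_days_rejected(self, rng):
        days = make_days([12] * 7)
        with pytest.raises(FitError):
            fit_barycenter([days[0]], rng)


class TestHmmModel:
    def test_state_recovery_from_synthetic_baseline(self, rng):
        params = rn.PatientParams(
            state_means=[[14.0, 1.2], [20.0, 0.7]],
            state_sds=[[0.8, 0.05], [0.8, 0.05]],
            transition_probs=[[0.95, 0.05], [0.05, 0.95]],
            initial_probs=[0.5, 0.5],
            usage_mean_hours=14.0,
            usage_sd_hours=0.5,
            day_sd=(1e-9, 1e-9),
            p_missing_day=0.0,
            p_invalid_sample=0.02,
            recovery_slope=0.0,
        )
        rec, _ = rn.generate_recording(params, None, 28, seed=9)
        baseline = baseline_from(rec)
        model = fit_hmm(baseline, rng)
        means = model.state_means_original()
        order = np.argsort(means[:, 0])
        means = means[order]
        assert np.all(np.abs(means - params.state_means) / params.state_means < 0.05)
        trans = model.params.permuted(order).transmat
        assert np.all(np.abs(trans - params.transition_probs) < 0.1)

    def test_score_is_normalized_negative_loglik(self, rng):
        recs, _ = rn.generate_cohort(rn.CohortConfig(n_cases=0, n_controls=1, seed=3))
        baseline = baseline_from(recs[0])
        model = fit_hmm(baseline, rng)
        day = baseline[1]
        segments = [model.standardizer.transform(s) for s in day.segments]
        expected = -rn.forward_loglik(model, segments) / day.n_valid
        assert score_hmm(model, day).value == pytest.approx(expected, abs=1e-12)

    def test_constant_observations_score_pointwise_density(self):
        from respnovel.models import HmmModel, Standardizer

        params = HmmParams([0.4, 0.6], [[0.7, 0.3], [0.3, 0.7]],
                           [[1.0, 2.0], [1.0, 2.0]], [[0.5, 0.5], [0.5, 0.5]])
        model = HmmModel(params, Standardizer(np.zeros(2), np.ones(2)))
        rec = build_recording(30, {24: {"n_valid": 20, "rate": 1.0, "amplitude": 2.0}})
        day = baseline_from(rec, min_baseline_days=1)[0]
        expected = -norm.logpdf([1.0, 2.0], [1.0, 2.0], np.sqrt(0.5)).sum()
        assert score_hmm(model, day).value == pytest.approx(expected, abs=1e-9)

    def test_state_relabeling_leaves_score_unchanged(self, rng):
        recs, _ = rn.generate_cohort(rn.CohortConfig(n_cases=0, n_controls=1, seed=3))
        baseline = baseline_from(recs[0])
        model = fit_hmm(baseline, rng)
        from respnovel.models import HmmModel

        swapped = HmmModel(model.params.permuted([1, 0]), model.standardizer)
        day = baseline[3]
        assert score_hmm(model, day).value == pytest.approx(
            score_hmm(swapped, day).value, abs=1e-10
        )

    def test_insufficient_samples_rejected(self, rng):
        days = make_days([2, 2, 2, 2, 2, 2, 2])
        with pytest.raises(FitError):
            fit_hmm(days, rng, min_train_samples=1000)

    def test_stable_days_score_below_strongly_ramped_days(self, rng):
        # strong pre-exacerbation drift should raise the novelty score
        params = rn.sample_patient_params(np.random.default_rng(4))
        stable_scores, ramped_scores = [], []
        for i in range(16):
            effect = rn.ExacerbationEffect(
                onset_day=19, delta_rate=4.0, delta_amplitude_frac=0.3,
                delta_usage_hours=2.0,
            )
            rec_r, _ = rn.generate_recording(params, effect, 30, seed=100 + i)
            rec_s, _ = rn.generate_recording(params, None, 30, seed=100 + i)
            model = fit_hmm(baseline_from(rec_s), rng)
            for day_idx in range(15, 19):
                for rec, sink in ((rec_s, stable_scores), (rec_r, ramped_scores)):
                    day = rn.summarize_day(rec, rec.date_of_day(day_idx))
                    s = score_hmm(model, day)
                    if s is not None:
                        sink.append(s.value)
        assert len(stable_scores) >= 50 and len(ramped_scores) >= 50
        p = mannwhitneyu(ramped_scores, stable_scores, alternative="greater").pvalue
        assert p < 0.01


class TestSerialization:
    def test_round_trip_all_model_kinds(self, tmp_path, rng):
        recs, _ = rn.generate_cohort(rn.CohortConfig(n_cases=0, n_controls=1, seed=3))
        baseline = baseline_from(recs[0])
        day = baseline[2]
        for method in rn.METHODS:
            model = rn.fit_method(method, baseline, rng)
            path = tmp_path / f"{method}.json"
            save_model(model, path)
            loaded = load_model(path)
            assert rn.score_method(method, loaded, day) == pytest.approx(
                rn.score_method(method, model, day), abs=1e-12
            )
            assert model_to_dict(loaded) == model_to_dict(model)
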