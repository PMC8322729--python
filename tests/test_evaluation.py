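"""Evaluation protocol: pre-impact rule, metrics, lead times, subject split."""

import numpy as np
import pytest

import preimpact as pi
from preimpact.errors import UsageError
from preimpact.evaluation import UndefinedMetricError


class TestClassifyFile:
    def setup_method(self):
        self.label = pi.FallLabel("F01", "d", 1, onset_frame=30, impact_frame=70)

    def test_pre_impact_detection_counts(self):
        assert pi.classify_file([40, 65], self.label) == (True, 40)

    def test_post_impact_detection_is_a_miss(self):
        assert pi.classify_file([80, 90], self.label) == (False, None)

    def test_adl_file_with_no_positives_is_negative(self):
        assert pi.classify_file([], None) == (False, None)

    def test_adl_file_any_positive_is_false_positive(self):
        assert pi.classify_file([500], None) == (True, 500)


class TestConfusionMetrics:
    @pytest.mark.parametrize("tp,fn,tn,fp,sens,spec", [
        (424, 20, 423, 84, 95.50, 83.43),   # threshold benchmark row
        (443, 1, 481, 26, 99.77, 94.87),    # SVM benchmark row
        (441, 3, 502, 5, 99.32, 99.01),     # Conv+LSTM benchmark row
        (14, 1, 11, 4, 93.33, 73.33),       # external validation row
    ])
    def test_reproduces_published_rows(self, tp, fn, tn, fp, sens, spec):
        got_sens, got_spec = pi.confusion_metrics(pi.ConfusionCounts(tp, fn, tn, fp))
        assert round(got_sens, 2) == sens
        assert round(got_spec, 2) == spec

    def test_empty_class_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            pi.confusion_metrics(pi.ConfusionCounts(0, 0, 5, 5))
        with pytest.raises(UndefinedMetricError):
            pi.confusion_metrics(pi.ConfusionCounts(5, 5, 0, 0))


class TestLeadTime:
    @pytest.mark.parametrize("det,imp,expected", [
        (460, 500, 400.0),
        (500, 500, 0.0),
        (10, 500, 4900.0),
    ])
    def test_closed_forms(self, det, imp, expected):
        assert pi.lead_time(det, imp, 100.0) == pytest.approx(expected)

    def test_detection_after_impact_is_contract_error(self):
        with pytest.raises(UsageError):
            pi.lead_time(510, 500, 100.0)


class TestSubjectSplit:
    def test_32_subjects_split_26_6(self):
        ids = [f"S{i:02d}" for i in range(1, 33)]
        train, test = pi.subject_split(ids, test_fraction=0.2, seed=0)
        assert (len(train), len(test)) == (26, 6)
        assert sorted(train + test) == sorted(ids)
        assert not set(train) & set(test)

    def test_deterministic_under_seed(self):
        ids = [f"S{i}" for i in range(10)]
        assert pi.subject_split(ids, seed=5) == pi.subject_split(ids, seed=5)
        assert pi.subject_split(ids, seed=5) != pi.subject_split(ids, seed=6)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.3])
    def test_bad_fraction_is_usage_error(self, frac):
        with pytest.raises(UsageError):
            pi.subject_split(["a", "b"], test_fraction=frac)

    def test_too_few_subjects_is_usage_error(self):
        with pytest.raises(UsageError):
            pi.subject_split(["only"], test_fraction=0.2)


@pytest.fixture(scope="module")
def small_set():
    falls = [pi.simulate_fall("F09", seed=s) for s in range(3)]
    adls = [(pi.simulate_adl("D06", seed=s), None) for s in range(3)]
    return list(falls) + adls


class TestEvaluate:
    def test_perfect_detector(self, small_set):
        def oracle_detector(rec):
            # fires one frame after onset on fall trials only (falls are the
            # trials whose task begins with F; the oracle peeks at metadata)
            return [201] if rec.task_id.startswith("F") else []

        rep = pi.evaluate(small_set, oracle_detector)
        assert (rep.sensitivity_pct, rep.specificity_pct) == (100.0, 100.0)
        assert all(lt > 0 for lt in rep.lead_times_ms)

    def test_always_negative_detector(self, small_set):
        rep = pi.evaluate(small_set, lambda rec: [])
        assert (rep.sensitivity_pct, rep.specificity_pct) == (0.0, 100.0)
        assert rep.lead_times_ms == []

    def test_invariant_to_file_order(self, small_set):
        det = pi.as_detector()
        rep1 = pi.evaluate(small_set, det)
        rep2 = pi.evaluate(small_set[::-1], det)
        assert rep1.counts == rep2.counts
        assert sorted(rep1.lead_times_ms) == sorted(rep2.lead_times_ms)

    def test_single_class_dataset_is_usage_error(self, small_set):
        with pytest.raises(UsageError):
            pi.evaluate([x for x in small_set if x[1] is None], pi.as_detector())

    def test_one_lead_time_per_true_positive(self, small_set):
        rep = pi.evaluate(small_set, pi.as_detector())
        assert len(rep.lead_times_ms) == rep.counts.tp
        assert all(lt > 0 for lt in rep.lead_times_ms)

    def test_report_serialization(self, small_set):
        rep = pi.evaluate(small_set, pi.as_detector())
        d = rep.to_dict()
        assert set(d["counts"]) == {"tp", "fn", "tn", "fp"}
        table = rep.to_table("threshold")
        assert "Sensitivity" in table and "threshold" in table
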