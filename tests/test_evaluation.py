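"""Metric arithmetic, LOSO mechanics, transfer validation, reporting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nervespec.benchmarks import ALL_BENCHMARKS
from nervespec.evaluation import (
    ConfusionMatrix,
    EvalPipeline,
    loso_cv,
    mcc,
    report_tables,
    summary_metrics,
    transfer_validate,
)

counts = st.integers(min_value=0, max_value=5000)


class TestMCC:
    def test_published_svm_combined_rows(self):
        assert mcc(ConfusionMatrix(641, 61, 49, 523)) == pytest.approx(0.826, abs=5e-4)
        assert mcc(ConfusionMatrix(93, 14, 20, 162)) == pytest.approx(0.751, abs=5e-4)

    def test_perfect_prediction_is_one(self):
        assert mcc(ConfusionMatrix(10, 0, 0, 20)) == 1.0
        assert mcc(ConfusionMatrix(0, 10, 20, 0)) == -1.0

    def test_zero_denominator_convention(self):
        assert mcc(ConfusionMatrix(5, 5, 0, 0)) == 0.0
        assert math.isnan(mcc(ConfusionMatrix(0, 0, 0, 0)))

    @settings(max_examples=100, deadline=None)
    @given(tp=counts, fn=counts, fp=counts, tn=counts)
    def test_symmetric_under_class_swap(self, tp, fn, fp, tn):
        a = mcc(ConfusionMatrix(tp, fn, fp, tn))
        b = mcc(ConfusionMatrix(tn, fp, fn, tp))
        assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)

    @settings(max_examples=100, deadline=None)
    @given(tp=counts, fn=counts, fp=counts, tn=counts,
           k=st.integers(min_value=2, max_value=9))
    def test_invariant_under_count_scaling(self, tp, fn, fp, tn, k):
        a = mcc(ConfusionMatrix(tp, fn, fp, tn))
        b = mcc(ConfusionMatrix(k * tp, k * fn, k * fp, k * tn))
        assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)


class TestSummaryMetrics:
    def test_published_examples(self):
        row = summary_metrics(ConfusionMatrix(580, 122, 64, 508))
        assert round(row.sens_pct, 1) == 82.6
        row = summary_metrics(ConfusionMatrix(570, 132, 112, 460))
        assert round(row.acc, 3) == 0.808

    def test_all_metrics_invariant_under_count_scaling(self):
        r1 = summary_metrics(ConfusionMatrix(9, 3, 2, 6))
        r2 = summary_metrics(ConfusionMatrix(27, 9, 6, 18))
        for m in ("mcc", "acc", "sens_pct", "spec_pct", "ppv", "npv"):
            assert getattr(r1, m) == pytest.approx(getattr(r2, m))

    def test_zero_denominator_yields_undefined_for_that_ratio_only(self):
        row = summary_metrics(ConfusionMatrix(0, 0, 3, 7))
        assert math.isnan(row.sens_pct)
        assert not math.isnan(row.spec_pct)
        assert math.isnan(row.ppv) is False  # TP+FP = 3 > 0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            summary_metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_benchmark_counts_reproduce_all_printed_ratio_metrics(self):
        """Every printed ACC/SENS/SPEC/PPV/NPV cell recomputes exactly
        from its own printed counts at the printed rounding."""
        for bench in ALL_BENCHMARKS:
            row = summary_metrics(bench.cm)
            got = row.rounded()
            for key in ("ACC", "SENS", "SPEC", "PPV", "NPV"):
                assert got[key] == bench.printed[key], (bench.method, key)


class TestReportTables:
    def test_rounding_conventions(self):
        row = summary_metrics(ConfusionMatrix(9136, 864, 1, 1), "m", "f")
        table = report_tables([row])
        # 0.91366... rounds to 0.914 at the 3-decimal report convention
        assert table.loc[0, "SENS"] == 91.4
        assert table.loc[0, "MCC"] == round(row.mcc, 3)

    def test_empty_rows_give_header_only(self):
        table = report_tables([])
        assert len(table) == 0
        assert list(table.columns)[:4] == ["method", "feature_selection",
                                           "MCC", "ACC"]


class TestLOSO:
    def test_fold_count_partition_and_perfect_separation(self, tiny_cohort,
                                                         lib, geom):
        dataset, _ = tiny_cohort
        cervical = dataset.subset(lambda s: s.area == "cervical")
        pipeline = EvalPipeline(classifier="svm_rbf", feature_method="segments")
        total, row, folds = loso_cv(cervical, pipeline)
        assert len(folds) == len(cervical.specimen_ids)
        assert total.total == len(cervical)
        assert sum(f.n_test for f in folds) == len(cervical)
        # tissue classes are strongly separated in the synthetic cohort
        assert row.mcc > 0.6

    def test_single_specimen_rejected(self, tiny_cohort):
        dataset, _ = tiny_cohort
        one = dataset.subset(lambda s: s.specimen_id == dataset.specimen_ids[0])
        with pytest.raises(ValueError):
            loso_cv(one, EvalPipeline(feature_method="segments"))

    def test_single_class_training_fold_names_specimen(self, tiny_cohort):
        dataset, _ = tiny_cohort
        sp0 = dataset.specimen_ids[0]
        # keep only nerve outside sp0: every other holdout is single-class
        skewed = dataset.subset(
            lambda s: s.specimen_id == sp0 or s.is_positive)
        with pytest.raises(ValueError, match="holding out"):
            loso_cv(skewed, EvalPipeline(feature_method="segments"))


class TestTransfer:
    def test_transfer_runs_and_is_asymmetric(self, tiny_cohort):
        dataset, _ = tiny_cohort
        cervical = dataset.subset(lambda s: s.area == "cervical")
        forearm = dataset.subset(lambda s: s.area == "forearm")
        pipeline = EvalPipeline(classifier="plsda", feature_method="spectra")
        fwd = transfer_validate(cervical, forearm, pipeline)
        rev = transfer_validate(forearm, cervical, pipeline)
        assert fwd.cm.total == len(forearm)
        assert rev.cm.total == len(cervical)
        assert fwd.cm != rev.cm

    def test_overlapping_location_ids_rejected(self, tiny_cohort):
        dataset, _ = tiny_cohort
        cervical = dataset.subset(lambda s: s.area == "cervical")
        with pytest.raises(ValueError, match="location_id"):
            transfer_validate(cervical, cervical, EvalPipeline())

    def test_single_spectrum_test_set(self, tiny_cohort):
        dataset, _ = tiny_cohort
        cervical = dataset.subset(lambda s: s.area == "cervical")
        forearm = dataset.subset(lambda s: s.area == "forearm")
        one = forearm.subset(lambda s: s.location_id == forearm.location_ids()[0])
        row = transfer_validate(cervical, one,
                                EvalPipeline(feature_method="segments"))
        assert row.cm.total == 1
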