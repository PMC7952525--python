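import math

import numpy as np
import pytest

from ductus.errors import DegenerateInputError, InvalidInputError
from ductus.roc import (
    auc_mann_whitney,
    compare_schemes,
    diagnostic_performance,
    performance_from_counts,
    predictive_values_from_rates,
    roc_curve,
    youden_cutoff,
)
from ductus.staging import model5_scheme


class TestROCCurve:
    def test_small_example(self):
        # positives {3,5}, negatives {1,4}: 3 of 4 pairs correctly ordered
        r = roc_curve([3, 5, 1, 4], [1, 1, 0, 0])
        assert r.auc == pytest.approx(0.75)
        assert auc_mann_whitney([3, 5, 1, 4], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_curve([1, 2, 8, 9], [0, 0, 1, 1]).auc == 1.0

    def test_all_ties_gives_half(self):
        assert roc_curve([2.0, 2.0, 2.0], [0, 1, 1]).auc == pytest.approx(0.5)

    def test_tied_pair(self):
        assert auc_mann_whitney([2, 2], [1, 0]) == pytest.approx(0.5)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(8)
        s = rng.integers(0, 8, 30).astype(float)
        y = rng.integers(0, 2, 30)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert auc_mann_whitney(s, 1 - y) == pytest.approx(1 - auc_mann_whitney(s, y))

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            roc_curve([1, 2, 3], [1, 1, 1])

    def test_monotonicity_of_operating_points(self):
        rng = np.random.default_rng(12)
        s = rng.normal(size=50)
        y = rng.integers(0, 2, 50)
        r = roc_curve(s, y)
        assert (np.diff(r.sensitivity) <= 1e-12).all()
        assert (np.diff(r.specificity) >= -1e-12).all()

    def test_trapezoid_equals_mann_whitney_with_ties(self):
        """The midpoint-threshold trapezoidal area and the tie-corrected
        Mann-Whitney estimator are the same number, to 1e-12, on 100 random
        datasets containing ties."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(6, 60))
            s = rng.integers(0, 6, n).astype(float)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            assert roc_curve(s, y).auc == pytest.approx(
                auc_mann_whitney(s, y), abs=1e-12
            )

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(17)
        for _ in range(20):
            s = rng.normal(size=80) + rng.integers(0, 3, 80)
            y = rng.integers(0, 2, 80)
            if y.min() == y.max():
                continue
            assert roc_curve(s, y).auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(31)
        s = rng.uniform(0, 10, 60)
        y = rng.integers(0, 2, 60)
        r1 = roc_curve(s, y)
        r2 = roc_curve(np.expm1(s / 3), y)  # strictly increasing transform
        assert r2.auc == pytest.approx(r1.auc, abs=1e-12)
        assert np.allclose(np.sort(r1.sensitivity), np.sort(r2.sensitivity))
        assert np.allclose(np.sort(r1.specificity), np.sort(r2.specificity))


class TestYouden:
    def test_small_example(self):
        r = roc_curve([3, 5, 1, 4], [1, 1, 0, 0])
        t, j = youden_cutoff(r)
        assert (t, j) == (2.0, pytest.approx(0.5))  # sensitivity-favouring tie-break

    def test_perfect_midpoint(self):
        r = roc_curve([4, 5], [0, 1])
        assert youden_cutoff(r) == (4.5, pytest.approx(1.0))


class TestDiagnosticPerformance:
    def test_reference_counts_reproduce_printed_metrics(self):
        """Counts 19/2/6/36 (treated-positive orientation) simultaneously
        give sens 0.90 (0.71-0.97), spec 0.86 (0.72-0.93), PPV 0.76 and NPV
        0.95 at two decimals."""
        perf = performance_from_counts(tp=19, fp=6, fn=2, tn=36)
        assert perf.sensitivity.estimate == pytest.approx(0.905, abs=5e-4)
        assert (round(perf.sensitivity.ci_low, 2), round(perf.sensitivity.ci_high, 2)) == (0.71, 0.97)
        assert perf.specificity.estimate == pytest.approx(0.857, abs=5e-4)
        assert (round(perf.specificity.ci_low, 2), round(perf.specificity.ci_high, 2)) == (0.72, 0.93)
        assert perf.ppv.estimate == pytest.approx(0.76, abs=5e-3)
        assert perf.npv.estimate == pytest.approx(0.947, abs=5e-4)
        for prop in (perf.sensitivity, perf.specificity, perf.ppv, perf.npv):
            assert prop.ci_low <= prop.estimate <= prop.ci_high

    def test_perfect_classifier(self):
        perf = performance_from_counts(tp=21, fp=0, fn=0, tn=42)
        for prop in (perf.sensitivity, perf.specificity, perf.ppv, perf.npv):
            assert prop.estimate == 1.0

    def test_cutoff_below_all_scores(self):
        perf = diagnostic_performance([2, 3, 4, 5], [0, 1, 0, 1], cutoff=0.0)
        assert perf.sensitivity.estimate == 1.0
        assert perf.specificity.estimate == 0.0

    def test_empty_margin_flagged_not_zero(self):
        perf = diagnostic_performance([1, 2], [0, 1], cutoff=10)  # nobody test-positive
        assert not perf.ppv.defined
        assert math.isnan(perf.ppv.estimate)

    def test_wilson_interval_bounds_and_shrinkage(self):
        prev = None
        for n in (10, 40, 160, 640):
            perf = performance_from_counts(tp=int(0.9 * n), fp=0, fn=n - int(0.9 * n), tn=1)
            ci = perf.sensitivity
            assert 0 <= ci.ci_low <= ci.ci_high <= 1
            width = ci.ci_high - ci.ci_low
            if prev is not None:
                assert width < prev
            prev = width


class TestBayesPredictiveValues:
    @pytest.mark.parametrize(
        "sens, spec, prev, ppv, npv",
        [
            (0.90, 0.86, 21 / 63, 0.763, 0.945),
            (1.0, 1.0, 0.3, 1.0, 1.0),
            (0.8, 0.9, 0.5, 0.889, 0.818),
        ],
    )
    def test_examples(self, sens, spec, prev, ppv, npv):
        got = predictive_values_from_rates(sens, spec, prev)
        assert got[0] == pytest.approx(ppv, abs=5e-4)
        assert got[1] == pytest.approx(npv, abs=5e-4)

    def test_undefined_flagged(self):
        ppv, npv = predictive_values_from_rates(0.0, 1.0, 0.0)
        assert math.isnan(ppv)

    def test_out_of_range(self):
        with pytest.raises(InvalidInputError):
            predictive_values_from_rates(1.2, 0.5, 0.5)


class TestCompareSchemes:
    def test_single_scheme_consistent_with_direct_computation(self, default_cohort):
        table = compare_schemes(default_cohort, [model5_scheme()])
        assert len(table) == 1
        labels = (default_cohort["group"] == "IBT").to_numpy()
        scores = default_cohort["pda_score"].to_numpy(dtype=float)
        r = roc_curve(scores, labels)
        assert table.loc[0, "auc"] == pytest.approx(r.auc)
        assert table.loc[0, "cutoff"] == youden_cutoff(r)[0]

    def test_duplicate_scheme_identical_rows(self, default_cohort):
        table = compare_schemes(default_cohort, [model5_scheme(), model5_scheme()])
        assert table.drop(columns="scheme").iloc[0].equals(table.drop(columns="scheme").iloc[1])
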