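"""Cosine summaries, paired contrasts, McNemar, classification metrics."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from iconotrans import (
    classification_metrics,
    confidence_interval,
    cosine,
    cross_language_consistency,
    mcnemar,
    paired_contrast,
    summarize,
)


class TestCosine:
    def test_identical_vectors(self):
        v = np.array([0.3, 0.4, 0.5])
        assert cosine(v, v) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert cosine([1.0, 0.0], [0.0, 2.0]) == pytest.approx(0.0)

    def test_closed_form_45_degrees(self):
        assert cosine([1.0, 0.0], [1.0, 1.0]) == pytest.approx(0.70711, abs=1e-5)

    def test_zero_vector_is_an_error_not_zero(self):
        with pytest.raises(ValueError):
            cosine([0.0, 0.0], [1.0, 1.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cosine([1.0], [1.0, 2.0])


class TestSummarize:
    def test_ci_from_printed_moments_regression_experiment(self):
        # mean .2343, SD .0411, n = 3423 -> CI [0.2329, 0.2357] at 4 decimals
        lo, hi = confidence_interval(0.2343, 0.0411, 3423)
        assert round(lo, 4) == 0.2329
        assert round(hi, 4) == 0.2357

    def test_ci_from_printed_moments_semantic_experiment(self):
        # mean .5263, SD .0687, n = 4922 -> CI [0.5244, 0.5282]
        lo, hi = confidence_interval(0.5263, 0.0687, 4922)
        assert round(lo, 4) == 0.5244
        assert round(hi, 4) == 0.5282

    def test_constant_values_give_degenerate_ci(self):
        s = summarize([0.25, 0.25, 0.25])  # exactly representable
        assert s.sd == 0.0 and s.ci_low == s.ci_high == s.mean

    def test_summary_consistent_with_moment_formula(self):
        rng = np.random.default_rng(0)
        values = rng.standard_normal(500)
        s = summarize(values)
        lo, hi = confidence_interval(s.mean, s.sd, s.n)
        assert s.ci_low == pytest.approx(lo) and s.ci_high == pytest.approx(hi)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            summarize([0.5])


class TestPairedContrast:
    def test_identical_samples(self):
        r = paired_contrast([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert r.t == 0.0 and r.p == 1.0 and r.d == 0.0

    def test_hand_computed_example(self):
        # diffs (.1, .1, .2, 0): mean .1, sd sqrt(1/150)
        r = paired_contrast([0.3, 0.5, 0.7, 0.4], [0.2, 0.4, 0.5, 0.4])
        assert r.t == pytest.approx(2.4495, abs=1e-3)
        assert r.d == pytest.approx(1.2247, abs=1e-3)

    def test_negative_mean_difference_gives_negative_t(self):
        r = paired_contrast([0.1, 0.2, 0.35], [0.3, 0.25, 0.4])
        assert r.t < 0 and r.d < 0
        assert 0 < r.p <= 1

    def test_agrees_with_scipy_on_random_data(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = rng.integers(5, 60)
            a = rng.standard_normal(n)
            b = a + 0.1 * rng.standard_normal(n) + 0.05
            ours = paired_contrast(a, b)
            ref = sps.ttest_rel(a, b)
            assert ours.t == pytest.approx(ref.statistic, abs=1e-6)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_degenerate_zero_variance_nonzero_mean(self):
        r = paired_contrast([0.75, 1.0, 1.25], [0.5, 0.75, 1.0])  # diffs exactly 0.25
        assert math.isinf(r.t) and r.t > 0 and r.p == 0.0

    def test_sign_convention_matches_mean_difference(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(30)
        b = rng.standard_normal(30)
        r = paired_contrast(a, b)
        assert np.sign(r.t) == np.sign(np.mean(a - b))


class TestMcNemar:
    @staticmethod
    def _lists(b, c, both=5, neither=4):
        model = [True] * both + [True] * b + [False] * c + [False] * neither
        base = [True] * both + [False] * b + [True] * c + [False] * neither
        return model, base

    def test_closed_form_example(self):
        chi2, p = mcnemar(*self._lists(10, 2))
        assert chi2 == pytest.approx(5.3333, abs=1e-3)

    def test_equal_discordants_give_null(self):
        chi2, p = mcnemar(*self._lists(4, 4))
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_symmetric_in_argument_order(self):
        m, b = self._lists(7, 3)
        assert mcnemar(m, b).chi2 == pytest.approx(mcnemar(b, m).chi2)

    def test_exhaustive_small_tables_match_closed_form(self):
        for b, c in itertools.product(range(7), repeat=2):
            if b + c == 0:
                continue
            chi2, p = mcnemar(*self._lists(b, c))
            assert chi2 == pytest.approx((b - c) ** 2 / (b + c), abs=1e-9)
            assert p == pytest.approx(sps.chi2.sf((b - c) ** 2 / (b + c), 1), abs=1e-9)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c in [(10, 2), (3, 6), (1, 1), (6, 0)]:
            m, base = self._lists(b, c)
            ours = mcnemar(m, base)
            table = [[5, b], [c, 4]]
            ref = sm_mcnemar(table, exact=False, correction=False)
            assert ours.chi2 == pytest.approx(ref.statistic, abs=1e-9)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_no_discordant_pairs_flagged(self):
        r = mcnemar([True, False], [True, False])
        assert r.chi2 == 0.0 and r.p == 1.0 and r.degenerate

    def test_continuity_correction_variant(self):
        r = mcnemar(*self._lists(10, 2), continuity=True)
        assert r.chi2 == pytest.approx((abs(10 - 2) - 1) ** 2 / 12, abs=1e-9)


class TestClassificationMetrics:
    def test_hand_computed_example(self):
        # precision A = 1/2, B = 2/3; supports 2 and 3
        m = classification_metrics(
            ["A", "A", "B", "B", "B"], ["A", "B", "B", "B", "A"], ["A", "B"]
        )
        assert m["accuracy"] == pytest.approx(0.6, abs=1e-9)
        assert m["weighted_precision"] == pytest.approx(0.6, abs=1e-9)
        assert m["weighted_f1"] == pytest.approx(0.6, abs=1e-9)

    def test_perfect_predictions(self):
        labels = ["A", "B", "C", "A"]
        m = classification_metrics(labels, labels, ["A", "B", "C"])
        assert m["accuracy"] == 1.0
        assert m["weighted_precision"] == 1.0
        assert m["weighted_f1"] == 1.0
        assert all(v == 1.0 for v in m["per_class_accuracy"].values())

    def test_weighted_recall_equals_accuracy(self):
        from sklearn.metrics import recall_score

        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(10, 80)
            classes = list(range(4))
            true = rng.integers(0, 4, size=n)
            pred = rng.integers(0, 4, size=n)
            m = classification_metrics(true, pred, classes)
            wr = recall_score(true, pred, labels=classes, average="weighted", zero_division=0)
            assert m["accuracy"] == pytest.approx(wr, abs=1e-12)

    def test_per_class_accuracy_is_recall(self):
        m = classification_metrics(
            ["A", "A", "A", "B"], ["A", "B", "B", "B"], ["A", "B"]
        )
        assert m["per_class_accuracy"]["A"] == pytest.approx(1 / 3)
        assert m["per_class_accuracy"]["B"] == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([], [], ["A"])


class TestCrossLanguageConsistency:
    def test_identical_profiles_give_unit_correlation(self):
        prof = {"c1": 0.2, "c2": 0.5, "c3": 0.9}
        per_class, mean_r, excluded = cross_language_consistency(
            {f"lang{i}": dict(prof) for i in range(4)}
        )
        assert mean_r == pytest.approx(1.0)
        assert not excluded

    def test_reversed_rankings_anticorrelate(self):
        a = {"c1": 0.1, "c2": 0.2, "c3": 0.3, "c4": 0.4}
        b = {"c1": 0.4, "c2": 0.3, "c3": 0.2, "c4": 0.1}
        _, mean_r, _ = cross_language_consistency({"l1": a, "l2": b})
        assert mean_r == pytest.approx(-1.0)

    def test_three_languages_match_brute_force(self):
        profiles = {
            "l1": {"a": 0.1, "b": 0.5, "c": 0.9},
            "l2": {"a": 0.2, "b": 0.4, "c": 0.7},
            "l3": {"a": 0.8, "b": 0.3, "c": 0.1},
        }
        per_class, mean_r, _ = cross_language_consistency(profiles)
        classes = sorted(profiles["l1"])
        vecs = {l: np.array([profiles[l][c] for c in classes]) for l in profiles}
        expected = np.mean(
            [
                np.corrcoef(vecs[x], vecs[y])[0, 1]
                for x, y in itertools.combinations(sorted(profiles), 2)
            ]
        )
        assert mean_r == pytest.approx(expected, abs=1e-9)
        assert per_class["a"] == pytest.approx((0.1 + 0.2 + 0.8) / 3)

    def test_zero_variance_language_excluded(self):
        profiles = {
            "l1": {"a": 0.5, "b": 0.5},
            "l2": {"a": 0.1, "b": 0.9},
            "l3": {"a": 0.2, "b": 0.8},
        }
        _, mean_r, excluded = cross_language_consistency(profiles)
        assert excluded == ["l1"]
        assert mean_r == pytest.approx(1.0)

    def test_mismatched_class_sets_rejected(self):
        with pytest.raises(ValueError):
            cross_language_consistency(
                {"l1": {"a": 0.1}, "l2": {"b": 0.2}}
            )
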