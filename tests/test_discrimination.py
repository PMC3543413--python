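"""ROC machinery, anchored on exhaustive pair-counting oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fidegam.discrimination import (
    DegenerateLabelingError,
    LabeledUnits,
    density_diagnostic,
    empirical_auc,
    label_by_median_records,
    label_by_true_completeness,
    orient_scores,
    roc_glm,
    youden_threshold,
)
from fidegam.simulate import SimulatedDatabase, SimulationConfig

from conftest import make_table


def brute_force_auc(scores, labels):
    """Count concordant (S1, S2) pairs one by one; ties worth one half."""
    s1 = [s for s, l in zip(scores, labels) if l == 1]
    s2 = [s for s, l in zip(scores, labels) if l == 0]
    total = correct = 0.0
    for a in s1:
        for b in s2:
            total += 1
            if a > b:
                correct += 1
            elif a == b:
                correct += 0.5
    return correct / total


def table_with_record_counts(counts):
    return make_table(
        {f"u{i}": [["A"]] * c for i, c in enumerate(counts, start=1)}
    )


def sub_database(sr_true, sr_sub):
    """Minimal subsampled-stage database carrying known richness."""
    table = make_table({u: [["A"], ["B"], ["C"]] for u in sr_true})
    return SimulatedDatabase(
        table, dict(sr_true), SimulationConfig(), "subsampled", dict(sr_sub)
    )


class TestLabeling:
    def test_median_rule_tie_goes_to_poorly_sampled(self):
        lab = label_by_median_records(table_with_record_counts([10, 20, 30]))
        np.testing.assert_array_equal(lab.labels, [0, 0, 1])

    def test_two_units(self):
        lab = label_by_median_records(table_with_record_counts([5, 50]))
        np.testing.assert_array_equal(lab.labels, [0, 1])

    def test_all_tied_is_degenerate(self):
        with pytest.raises(DegenerateLabelingError):
            label_by_median_records(table_with_record_counts([7, 7, 7]))

    def test_true_completeness_strict_at_boundary(self):
        sim = sub_database(
            {"a": 100, "b": 100, "c": 400}, {"a": 100, "b": 70, "c": 280}
        )
        lab = label_by_true_completeness(sim)
        # 100% -> S1; exactly 70% -> S2 (strict inequality)
        np.testing.assert_array_equal(lab.labels, [1, 0, 0])


class TestEmpiricalAuc:
    def test_perfect_separation(self):
        assert empirical_auc([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert empirical_auc([5, 5, 5, 5], [1, 1, 0, 0]) == 0.5

    def test_four_point_example(self):
        # pairs: (.9,.5) ok, (.9,.1) ok, (.4,.5) wrong, (.4,.1) ok -> 3/4
        assert empirical_auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == 0.75

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force some ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert empirical_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels)
        )

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_monotone_transform_invariance_and_label_flip(self, data):
        n = data.draw(st.integers(4, 15))
        # coarse grid: keeps distinct scores distinct after exp()
        scores = 0.1 * np.array(
            data.draw(st.lists(st.integers(-50, 50), min_size=n, max_size=n))
        )
        labels = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        auc = empirical_auc(scores, labels)
        assert empirical_auc(np.exp(0.7 * scores), labels) == pytest.approx(auc)
        assert empirical_auc(scores, 1 - labels) == pytest.approx(1 - auc)

    def test_orientation_flips_slope_measures(self):
        v = np.array([0.1, 0.9])
        np.testing.assert_array_equal(orient_scores("NPE", v), v)
        np.testing.assert_array_equal(orient_scores("FIDEGAM", v), -v)
        np.testing.assert_array_equal(orient_scores("STE", v), -v)


class TestRocGlm:
    def test_labels_as_scores_give_perfect_auc(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        roc = roc_glm(y.astype(float), y, n_boot=50, seed=0)
        assert roc.auc == 1.0
        # probabilities clump at 0 and 1 (or the separation fallback fires)
        if roc.glm_converged:
            assert np.all((roc.probabilities > 0.9) | (roc.probabilities < 0.1))

    def test_null_scores_give_chance_auc(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, size=200)
        roc = roc_glm(scores, labels, n_boot=50, seed=0)
        assert 0.40 <= roc.auc <= 0.60

    def test_bootstrap_ci_contains_point_estimate(self):
        rng = np.random.default_rng(3)
        scores = np.concatenate([rng.normal(1, 1, 30), rng.normal(0, 1, 30)])
        labels = np.array([1] * 30 + [0] * 30)
        roc = roc_glm(scores, labels, n_boot=200, seed=0)
        assert roc.ci_low <= roc.auc <= roc.ci_high

    def test_auc_equals_trapezoid_under_stored_curve(self):
        rng = np.random.default_rng(4)
        scores = np.concatenate([rng.normal(1, 1, 40), rng.normal(0, 1, 40)])
        labels = np.array([1] * 40 + [0] * 40)
        roc = roc_glm(scores, labels, n_boot=10, seed=0)
        assert np.trapezoid(roc.tpr, roc.fpr) == pytest.approx(roc.auc, abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelingError):
            roc_glm(np.array([1.0, 2.0]), np.array([1, 1]), n_boot=10)


class TestDensities:
    def test_ideal_classifier_modes_at_ends(self):
        probs = np.array([0.98, 0.99, 0.97, 0.02, 0.01, 0.03])
        labels = np.array([1, 1, 1, 0, 0, 0])
        df = density_diagnostic(probs, labels)
        assert df.loc[df["density_S1"].idxmax(), "p"] > 0.9
        assert df.loc[df["density_S2"].idxmax(), "p"] < 0.1

    def test_uninformative_classifier_overlaps(self):
        rng = np.random.default_rng(0)
        probs = rng.uniform(0.3, 0.7, size=200)
        labels = rng.integers(0, 2, size=200)
        df = density_diagnostic(probs, labels)
        l1 = np.trapezoid(
            np.abs(df["density_S1"] - df["density_S2"]), df["p"]
        )
        assert l1 < 0.5

    def test_single_observation_per_class(self):
        df = density_diagnostic(np.array([0.8, 0.2]), np.array([1, 0]))
        assert np.isfinite(df[["density_S1", "density_S2"]].to_numpy()).all()


class TestYouden:
    def test_perfect_classifier(self):
        y = np.array([1, 1, 0, 0])
        roc = roc_glm(np.array([0.9, 0.8, 0.2, 0.1]), y, n_boot=10, seed=0)
        assert youden_threshold(roc).J == pytest.approx(1.0)

    def test_uninformative_classifier(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=300)
        labels = rng.integers(0, 2, size=300)
        roc = roc_glm(scores, labels, n_boot=10, seed=0)
        assert youden_threshold(roc).J < 0.25

    def test_separable_cut_between_classes(self):
        # any cut in (0.6, 0.7) separates S1={0.8,0.7} from S2={0.6,0.2}
        y = np.array([1, 1, 0, 0])
        roc = roc_glm(np.array([0.8, 0.7, 0.6, 0.2]), y, n_boot=10, seed=0)
        res = youden_threshold(roc)
        assert res.J == pytest.approx(1.0)

    def test_threshold_maps_back_to_measure_scale(self):
        # oriented scores are negated FIDEGAM values; the returned
        # threshold must be on the raw (positive) scale and separate
        # the classes in the raw direction (above = poorly sampled)
        raw = np.array([0.01, 0.02, 0.2, 0.4])  # low = well sampled
        y = np.array([1, 1, 0, 0])
        roc = roc_glm(orient_scores("FIDEGAM", raw), y, n_boot=10, seed=0, method="FIDEGAM")
        thr = youden_threshold(roc).threshold_on_measure
        assert np.all(raw[y == 1] <= thr) and np.all(raw[y == 0] > thr)
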