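"""Model search: splits, metrics, combination sampling, two-phase selection,
finalisation and repeated cross-validation."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from conftest import NEG_DRIVER, planted_arrays, planted_spec
from qcar.exceptions import ClassDegeneracyError, ParameterError
from qcar.pretreatment import PretreatmentParams
from qcar.search import (
    Combination,
    SearchSpace,
    confusion_metrics,
    evaluate_combination,
    finalize_model,
    repeated_cv,
    run_search,
    sample_combinations,
    stratified_split,
)
from qcar.synthetic import GeneratorSpec, generate_dataset
from qcar.dataset import align


def dt_combination(threshold=0.25, **params):
    return Combination(
        params=PretreatmentParams(threshold=threshold, **params),
        family="decision_tree",
        hyper=(("max_depth", 3), ("min_samples_leaf", 1)),
    )


class TestStratifiedSplit:
    def test_balanced_ten(self):
        labels = np.array([0] * 5 + [1] * 5)
        train, test = stratified_split(labels, 0.8, seed=1)
        assert len(test) == 2 and len(train) == 8
        assert labels[test].sum() == 1  # one per class

    def test_61_oils_80_20(self):
        labels = np.array([0] * 40 + [1] * 21)
        train, test = stratified_split(labels, 0.8, seed=3)
        assert len(test) == 13 and len(train) == 48  # ceil(61 × 0.2) = 13
        # per-class proportions within ±1 of exact
        for cls, n_cls in ((0, 40), (1, 21)):
            expected = n_cls * 13 / 61
            assert abs((labels[test] == cls).sum() - expected) <= 1

    def test_deterministic_and_disjoint(self):
        labels = np.array([0] * 8 + [1] * 6)
        a = stratified_split(labels, 0.75, seed=9)
        b = stratified_split(labels, 0.75, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
        assert set(a[0]) | set(a[1]) == set(range(14))
        assert not set(a[0]) & set(a[1])

    def test_single_class_rejected(self):
        with pytest.raises(ClassDegeneracyError):
            stratified_split(np.ones(10, dtype=int), 0.8, seed=0)


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 1, 0, 1])
        assert confusion_metrics(y, y) == pytest.approx((1.0, 1.0, 1.0, 1.0))

    def test_chance_table_maps_to_nmcc_half(self):
        y_true = np.array([1] * 50 + [0] * 50)
        y_pred = np.array(([1] * 25 + [0] * 25) * 2)  # TP=FP=FN=TN=25
        acc, f1, mcc, nmcc = confusion_metrics(y_true, y_pred)
        assert mcc == pytest.approx(0.0)
        assert nmcc == pytest.approx(0.5)

    def test_direct_formula_oracle(self):
        # (TP, FP, TN, FN) = (3, 1, 4, 2) → MCC = 10/√600
        y_true = np.array([1] * 3 + [0] * 1 + [0] * 4 + [1] * 2)
        y_pred = np.array([1] * 3 + [1] * 1 + [0] * 4 + [0] * 2)
        _, _, mcc, _ = confusion_metrics(y_true, y_pred)
        assert mcc == pytest.approx(10 / np.sqrt(600))

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_brute_force_enumeration_small_tables(self):
        """Agreement with the closed form and sklearn on every table n ≤ 8."""
        for tp, fp, tn, fn in itertools.product(range(9), repeat=4):
            n = tp + fp + tn + fn
            if not 0 < n <= 8:
                continue
            y_true = np.array([1] * tp + [0] * fp + [0] * tn + [1] * fn)
            y_pred = np.array([1] * tp + [1] * fp + [0] * tn + [0] * fn)
            acc, f1, mcc, nmcc = confusion_metrics(y_true, y_pred)
            den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            expected = (tp * tn - fp * fn) / np.sqrt(den) if den else 0.0
            assert mcc == pytest.approx(expected)
            assert nmcc == pytest.approx((expected + 1) / 2)
            assert acc == pytest.approx((tp + tn) / n)
            # independent route: scikit-learn's implementation
            assert mcc == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-12
            )

    def test_symmetry_under_label_swap(self, rng):
        y_true = rng.integers(0, 2, size=30)
        y_pred = rng.integers(0, 2, size=30)
        _, _, mcc, _ = confusion_metrics(y_true, y_pred)
        _, _, swapped, _ = confusion_metrics(1 - y_true, 1 - y_pred)
        assert mcc == pytest.approx(swapped)

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            confusion_metrics([], [])


class TestSampleCombinations:
    def small_space(self):
        return SearchSpace(
            grids={"knn": {"n_neighbors": (3, 5), "weights": ("uniform",)}},
            thresholds=(0.5,), n_levels=(0, 1), scaling_flags=(False,),
            pca_levels=(None, 0.90),
        )

    def test_exhaustion_when_budget_exceeds_space(self):
        space = self.small_space()
        combos = sample_combinations(space, budget=100, seed=0)
        assert len(combos) == space.size() == 8
        assert len(set(combos)) == 8

    def test_deterministic_subsample(self):
        space = self.small_space()
        a = sample_combinations(space, budget=5, seed=4)
        b = sample_combinations(space, budget=5, seed=4)
        assert a == b and len(a) == 5

    def test_first_draw_frequencies_uniform(self):
        """Binomial oracle: over many seeds each point is drawn ≈ uniformly."""
        space = self.small_space()  # 8 combinations
        n_seeds = 1600
        counts: dict = {}
        for s in range(n_seeds):
            first = sample_combinations(space, budget=1, seed=s)[0]
            counts[first] = counts.get(first, 0) + 1
        p = 1 / 8
        sigma = np.sqrt(n_seeds * p * (1 - p))
        for c in counts.values():
            assert abs(c - n_seeds * p) <= 3 * sigma

    def test_restriction_and_empty_restriction(self):
        space = self.small_space()
        cell = ("knn", PretreatmentParams(threshold=0.5))
        combos = sample_combinations(space, 100, restrict_to=[cell])
        assert len(combos) == 2  # both knn hyper settings, one cell
        with pytest.raises(ParameterError):
            sample_combinations(
                space, 10,
                restrict_to=[("svm", PretreatmentParams(threshold=0.5))],
            )


class TestEvaluateCombination:
    def test_separable_planted_data_reaches_mcc_one(self, planted_xy):
        comps, values, censored = planted_arrays(seed=3, noise_sd=0.0)
        result = evaluate_combination(
            comps, values, censored, dt_combination(threshold=0.25),
            split_seed=0,
        )
        assert result.mcc_pred == pytest.approx(1.0)
        assert result.nmcc_pred == pytest.approx(1.0)

    def test_all_active_threshold_is_sentinel(self, planted_xy):
        comps, values, censored = planted_xy
        huge = dt_combination(threshold=1.0)
        # force single class: everything uncensored and ≤ 1 → use noise-free
        # all-zero-beta data instead
        spec = GeneratorSpec(
            n_oils=12, n_components=6, noise_sd=0.0,
            intercept_log10=-1.0, censor_limit=5.0, seed=2,
        )
        comps2, records2 = generate_dataset(spec)
        _, v2, c2 = align(comps2, records2, "dpph")
        result = evaluate_combination(comps2, v2, c2, huge, split_seed=0)
        assert result.is_sentinel and result.reason == "single_class"
        assert result.mcc_pred == -1.0

    def test_label_permutation_gives_near_zero_mcc(self, planted_xy):
        comps, values, censored = planted_xy
        rng = np.random.default_rng(0)
        hits = 0
        n_seeds = 60
        for s in range(n_seeds):
            perm = rng.permutation(comps.n_oils)
            result = evaluate_combination(
                comps, values[perm], censored[perm],
                dt_combination(threshold=0.25), split_seed=s,
            )
            if abs(result.mcc_pred) < 0.5:
                hits += 1
        assert hits >= 0.9 * n_seeds


class TestRunSearch:
    def test_exhaustive_equals_global_argmax(self, planted_xy, compact_space):
        comps, values, censored = planted_xy
        outcome = run_search(
            comps, values, censored, compact_space,
            coarse_budget=10_000, refined_budget=10_000, seed=5,
        )
        # independent exhaustive pass with the same split seed
        best_mcc = max(
            evaluate_combination(
                comps, values, censored, comb, split_seed=5
            ).mcc_pred
            for comb in sample_combinations(compact_space, 10_000, seed=5)
        )
        assert outcome.best.mcc_pred == pytest.approx(best_mcc)
        assert not outcome.best.is_sentinel

    def test_deterministic(self, planted_xy, compact_space):
        comps, values, censored = planted_xy
        a = run_search(comps, values, censored, compact_space,
                       coarse_budget=30, refined_budget=60, seed=11)
        b = run_search(comps, values, censored, compact_space,
                       coarse_budget=30, refined_budget=60, seed=11)
        assert a.chosen == b.chosen
        assert [r.mcc_pred for r in a.results] == [r.mcc_pred for r in b.results]

    def test_never_selects_sentinel_when_alternative_exists(
        self, planted_xy, compact_space
    ):
        comps, values, censored = planted_xy
        outcome = run_search(comps, values, censored, compact_space,
                             coarse_budget=50, refined_budget=100, seed=2)
        assert not outcome.best.is_sentinel


class TestFinalizeAndCv:
    def test_separable_training_mcc_is_one(self):
        comps, values, censored = planted_arrays(seed=5, noise_sd=0.0)
        final = finalize_model(
            comps, values, censored, dt_combination(threshold=0.25), seed=0
        )
        assert final.train_mcc == pytest.approx(1.0)

    def test_anti_leakage_test_labels_never_touch_the_fit(self):
        comps, values, censored = planted_arrays(seed=5)
        comb = dt_combination(threshold=0.25)
        labels = (values <= 0.25) & ~censored
        train_idx, test_idx = stratified_split(labels.astype(int), 0.8, seed=1)
        v2, c2 = values.copy(), censored.copy()
        v2[test_idx] = 0.9  # corrupt held-out activities
        from qcar.pretreatment import apply_pretreatment

        _, _, ft_a = apply_pretreatment(
            comps, values, censored, comb.params, train_idx, test_idx
        )
        _, _, ft_b = apply_pretreatment(
            comps, v2, c2, comb.params, train_idx, test_idx
        )
        assert ft_a.kept_components == ft_b.kept_components

    def test_repeated_cv_deterministic_and_bounded(self):
        comps, values, censored = planted_arrays(seed=5, noise_sd=0.0)
        comb = dt_combination(threshold=0.25)
        mean1, vals1 = repeated_cv(comps, values, censored, comb,
                                   iterations=3, seed=21)
        mean2, vals2 = repeated_cv(comps, values, censored, comb,
                                   iterations=3, seed=21)
        np.testing.assert_array_equal(vals1, vals2)
        assert -1.0 <= mean1 <= 1.0
        # noiseless separable data cross-validates essentially perfectly
        assert mean1 > 0.8

    def test_cv_requires_class_of_size_k(self):
        comps, values, censored = planted_arrays(seed=5)
        comb = dt_combination(threshold=0.003)  # near-empty active class
        with pytest.raises((ParameterError, ClassDegeneracyError)):
            repeated_cv(comps, values, censored, comb, k=5, iterations=2)
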