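"""Shrunken-centroid, PCA and clustering prongs, and their integration."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tgxddi import (
    DDI,
    NON_DDI,
    UNCLASSIFIED,
    UNKNOWN,
    SimConfig,
    TrainingSet,
    class_probabilities,
    classify_conditions,
    fit_nsc,
    fit_pca,
    generate_training_set,
    hc_call,
    integrate,
    pa_call,
    pca_call,
    select_delta_cv,
)
from tgxddi.errors import AlignmentError, DataError, StratifiedFoldingError
from tgxddi.normalization import LogRatioMatrix
from tgxddi.tgx_classifier import discriminant_scores


def brute_force_nsc(profiles: pd.DataFrame, labels: pd.Series, query: np.ndarray):
    """Independent nearest-centroid-with-pooled-variance oracle (delta = 0).

    Plain per-class means, pooled within-class SD by direct summation, and
    the Gaussian discriminant evaluated term by term.
    """
    X = profiles.to_numpy(dtype=float)
    classes = [DDI, NON_DDI]
    n = X.shape[1]
    cents, nks = [], []
    for c in classes:
        cols = [j for j, p in enumerate(profiles.columns) if labels.iloc[j] == c]
        cents.append(X[:, cols].mean(axis=1))
        nks.append(len(cols))
    ss = np.zeros(X.shape[0])
    for j in range(n):
        k = classes.index(labels.iloc[j])
        ss += (X[:, j] - cents[k]) ** 2
    s = np.sqrt(ss / (n - 2))
    s0 = float(np.median(s))
    deltas = []
    for k, c in enumerate(classes):
        d = 0.0
        for i in range(X.shape[0]):
            d += (query[i] - cents[k][i]) ** 2 / (s[i] + s0) ** 2
        deltas.append(d - 2 * np.log(nks[k] / n))
    return np.array([cents[0], cents[1]]).T, s, s0, np.array(deltas)


def random_training(rng, n_genes=5, n_per_class=4, spread=1.0):
    cols = [f"D{i}" for i in range(n_per_class)] + [f"N{i}" for i in range(n_per_class)]
    profiles = pd.DataFrame(
        rng.normal(0, spread, size=(n_genes, 2 * n_per_class)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=cols,
    )
    labels = pd.Series([DDI] * n_per_class + [NON_DDI] * n_per_class, index=cols)
    return TrainingSet(profiles, labels)


class TestNSCFit:
    def test_delta_zero_matches_brute_force_oracle_on_random_toys(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            train = random_training(rng)
            query = rng.normal(0, 1, 5)
            model = fit_nsc(train, delta=0.0)
            cents, s, s0, deltas = brute_force_nsc(train.profiles, train.labels, query)
            np.testing.assert_allclose(model.shrunken_centroids, cents, atol=1e-10)
            np.testing.assert_allclose(model.pooled_sd, s, atol=1e-10)
            assert model.s0 == pytest.approx(s0, abs=1e-10)
            np.testing.assert_allclose(
                discriminant_scores(model, query), deltas, atol=1e-10
            )

    def test_large_delta_collapses_to_priors(self, toy_training):
        model = fit_nsc(toy_training, delta=1e6)
        np.testing.assert_allclose(
            model.shrunken_centroids, model.overall_centroid[:, None] * np.ones((1, 2))
        )
        p = class_probabilities(model, np.array([0.3, -0.7]))
        assert p[0] == pytest.approx(model.priors[0], abs=1e-12)

    def test_shrinkage_monotonicity_in_active_genes(self, default_training):
        deltas = np.linspace(0, 8, 15)
        counts = [fit_nsc(default_training, d).n_nonzero_genes for d in deltas]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_probabilities_sum_to_one(self, default_training):
        rng = np.random.default_rng(1)
        model = fit_nsc(default_training, delta=1.0)
        for _ in range(20):
            p = class_probabilities(model, rng.normal(0, 2, 64))
            assert p[0] + p[1] == pytest.approx(1.0, abs=1e-12)

    def test_minus_and_plus_size_factor_conventions_differ_only_in_scores(
        self, toy_training
    ):
        minus = fit_nsc(toy_training, delta=0.0, class_size_factor="minus")
        plus = fit_nsc(toy_training, delta=0.0, class_size_factor="plus")
        np.testing.assert_allclose(minus.shrunken_centroids, plus.shrunken_centroids)
        assert (np.abs(minus.d_scores) > np.abs(plus.d_scores)).all()


class TestClassProbabilities:
    def test_worked_two_gene_toy(self, unit_toy_model):
        # query at the DDI centroid: delta_DDI = 0, delta_nonDDI = 8
        p_ddi, p_non = class_probabilities(unit_toy_model, np.array([1.0, 1.0]))
        assert p_ddi == pytest.approx(1.0 / (1.0 + np.exp(-4.0)), abs=1e-12)

    def test_equidistant_query_with_equal_priors(self, unit_toy_model):
        p = class_probabilities(unit_toy_model, np.array([0.0, 0.0]))
        assert p == pytest.approx((0.5, 0.5), abs=1e-12)

    def test_gene_mismatch_raises(self, default_training):
        model = fit_nsc(default_training)
        with pytest.raises(AlignmentError):
            class_probabilities(model, pd.Series([1.0], index=["not_a_gene"]))


class TestPACall:
    @pytest.mark.parametrize(
        "probs, expected",
        [
            ((0.95, 0.05), DDI),
            ((0.05, 0.95), NON_DDI),
            ((0.5, 0.5), UNCLASSIFIED),
            ((0.90, 0.10), UNCLASSIFIED),  # threshold is strict
        ],
    )
    def test_threshold_semantics(self, probs, expected):
        assert pa_call(probs) == expected


class TestPCA:
    def test_training_mean_profile_scores_zero_and_calls_nonddi(self, default_training):
        model = fit_pca(default_training)
        mean_profile = default_training.profiles.mean(axis=1)
        pc1, call = pca_call(model, mean_profile)
        assert pc1 == pytest.approx(0.0, abs=1e-9)
        assert call == NON_DDI  # the "otherwise" branch at PC1 = 0

    def test_orientation_makes_mean_ddi_score_negative(self):
        for seed in range(5):
            train, _ = generate_training_set(SimConfig(seed=seed))
            model = fit_pca(train)
            scores = [
                pca_call(model, train.profiles[c])[0]
                for c in train.profiles.columns
                if train.labels[c] == DDI
            ]
            assert np.mean(scores) < 0

    def test_two_gene_toy_loadings_along_diagonal(self, toy_training):
        model = fit_pca(toy_training)
        assert np.abs(model.loadings[0]) == pytest.approx(
            np.full(2, 1 / np.sqrt(2)), abs=0.02
        )

    def test_negating_centered_profile_negates_pc1(self, default_training):
        model = fit_pca(default_training)
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 64)
        pc1_pos, _ = pca_call(model, pd.Series(model.center + x, index=model.gene_ids))
        pc1_neg, _ = pca_call(model, pd.Series(model.center - x, index=model.gene_ids))
        assert pc1_neg == pytest.approx(-pc1_pos, abs=1e-9)

    def test_ddi_centroid_classifies_ddi(self, default_training):
        model = fit_pca(default_training)
        ddi_cols = default_training.labels[default_training.labels == DDI].index
        centroid = default_training.profiles[ddi_cols].mean(axis=1)
        _, call = pca_call(model, centroid)
        assert call == DDI


class TestHCCall:
    def test_query_identical_to_training_profile_inherits_label(self, default_training):
        ddi_col = default_training.labels[default_training.labels == DDI].index[0]
        non_col = default_training.labels[default_training.labels == NON_DDI].index[0]
        assert hc_call(default_training, default_training.profiles[ddi_col]) == DDI
        assert hc_call(default_training, default_training.profiles[non_col]) == NON_DDI

    def test_far_away_query_is_unknown_singleton(self, default_training):
        profile = default_training.profiles.iloc[:, 0] * 1000.0
        assert hc_call(default_training, profile) == UNKNOWN


class TestIntegration:
    def test_exhaustive_truth_table(self):
        pa_states = [DDI, NON_DDI, UNCLASSIFIED]
        pca_states = [DDI, NON_DDI]
        hc_states = [DDI, NON_DDI, UNKNOWN]
        for pa, pca, hc in itertools.product(pa_states, pca_states, hc_states):
            call = integrate(pa, pca, hc)
            if DDI in (pa, pca, hc):
                assert call == DDI
            elif pa == NON_DDI and pca == NON_DDI and hc == NON_DDI:
                assert call == NON_DDI
            else:
                assert call == UNCLASSIFIED


class TestLabelRecovery:
    def test_holdout_accuracy_on_separated_synthetic_training(self):
        train, _ = generate_training_set(SimConfig(seed=5, effect_size=2.0, noise_sd=0.5))
        model = fit_nsc(train)
        test_cfg = SimConfig(seed=99, effect_size=2.0, noise_sd=0.5, n_ddi=100, n_nonddi=100)
        test_set, truth = generate_training_set(test_cfg)
        correct = 0
        for pid in test_set.profiles.columns:
            p_ddi, _ = class_probabilities(model, test_set.profiles[pid])
            pred = DDI if p_ddi > 0.5 else NON_DDI
            correct += pred == truth.labels[pid]
        assert correct / 200 >= 0.95

    def test_null_effect_accuracy_near_chance(self):
        train, _ = generate_training_set(SimConfig(seed=6, effect_size=0.0))
        model = fit_nsc(train)
        test_set, truth = generate_training_set(
            SimConfig(seed=123, effect_size=0.0, n_ddi=100, n_nonddi=100)
        )
        correct = sum(
            (DDI if class_probabilities(model, test_set.profiles[p])[0] > 0.5 else NON_DDI)
            == truth.labels[p]
            for p in test_set.profiles.columns
        )
        acc = correct / 200
        se = np.sqrt(0.25 / 200)
        assert abs(acc - 0.5) <= 3 * se


class TestClassifyConditions:
    def _lrm(self, train, profiles: dict[str, np.ndarray], conc: float = 125.0):
        values = pd.DataFrame(profiles, index=train.gene_ids)
        meta = pd.DataFrame(
            {
                "sample_id": list(profiles),
                "chemical": "X",
                "concentration_uM": conc,
                "is_vehicle": False,
                "replicate": range(1, len(profiles) + 1),
            }
        )
        return LogRatioMatrix(values=values, meta=meta, pseudocount=0.5)

    def test_ddi_like_profiles_called_ddi(self, default_training):
        ddi_cols = default_training.labels[default_training.labels == DDI].index
        centroid = default_training.profiles[ddi_cols].mean(axis=1).to_numpy()
        lrm = self._lrm(default_training, {f"r{i}": centroid for i in range(3)})
        grid = classify_conditions(default_training, lrm)
        assert grid.loc[0, "overall_call"] == DDI
        assert grid.loc[0, "n_replicates"] == 3

    def test_zero_profile_never_pa_ddi_under_symmetric_training(self):
        for seed in range(5):
            train, _ = generate_training_set(SimConfig(seed=seed))
            lrm = self._lrm(train, {"r1": np.zeros(64)})
            grid = classify_conditions(train, lrm)
            assert grid.loc[0, "pa_call"] != DDI

    def test_single_replicate_condition_is_handled(self, default_training):
        lrm = self._lrm(default_training, {"only": np.zeros(64)})
        grid = classify_conditions(default_training, lrm)
        assert len(grid) == 1 and grid.loc[0, "n_replicates"] == 1

    def test_per_replicate_mode_rows(self, default_training):
        lrm = self._lrm(default_training, {"a": np.zeros(64), "b": np.zeros(64)})
        grid = classify_conditions(default_training, lrm, per_replicate=True)
        assert len(grid) == 2 and (grid["n_replicates"] == 1).all()


class TestDeltaSelection:
    def test_separated_training_reaches_zero_cv_error_and_deterministic(self):
        train, _ = generate_training_set(SimConfig(seed=3, effect_size=2.0, noise_sd=0.5))
        d1 = select_delta_cv(train, folds=4, seed=10)
        d2 = select_delta_cv(train, folds=4, seed=10)
        assert d1 == d2
        # with strong separation the best CV error is 0 at some delta
        assert d1 >= 0.0

    def test_fold_without_both_classes_raises(self):
        train, _ = generate_training_set(SimConfig(seed=3, n_ddi=2, n_nonddi=2))
        with pytest.raises(StratifiedFoldingError):
            select_delta_cv(train, folds=2, seed=0)

    def test_class_smaller_than_two_rejected_at_construction(self):
        profiles = pd.DataFrame(
            np.zeros((3, 3)), index=list("abc"), columns=["p1", "p2", "p3"]
        )
        labels = pd.Series([DDI, DDI, NON_DDI], index=profiles.columns)
        with pytest.raises(DataError):
            TrainingSet(profiles, labels)
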