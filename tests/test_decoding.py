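import numpy as np
import pytest

import odorcode as oc
from odorcode.decoding import (
    DecodingConfig,
    _permutation_p,
    assemble_pseudopopulation,
    cross_validated_accuracy,
    max_correlation_classify,
    session_feature_matrix,
)
from odorcode.session import TimeWindow


def classify_oracle(train_X, train_y, test_X):
    """Brute-force max-correlation classification (tie-free instances only)."""
    classes = np.unique(train_y)
    templates = [train_X[train_y == c].mean(axis=0) for c in classes]
    preds = []
    for x in test_X:
        corrs = [np.corrcoef(x, t)[0, 1] for t in templates]
        preds.append(classes[int(np.argmax(corrs))])
    return np.array(preds)


class TestClassifier:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n_classes = int(rng.integers(3, 7))
            n_neurons = int(rng.integers(4, 10))
            n_train = int(rng.integers(2, 5))
            train_X = rng.normal(size=(n_classes * n_train, n_neurons))
            train_y = np.repeat(np.arange(n_classes), n_train)
            test_X = rng.normal(size=(6, n_neurons))
            preds = max_correlation_classify(train_X, train_y, test_X, rng=0)
            assert np.array_equal(preds, classify_oracle(train_X, train_y, test_X))

    def test_recovers_planted_templates(self):
        rng = np.random.default_rng(1)
        templates = np.eye(4).repeat(3, axis=1)  # 4 orthogonal 12-d patterns
        train_X = np.vstack([t + 0.01 * rng.normal(size=12) for t in templates for _ in range(3)])
        train_y = np.repeat(np.arange(4), 3)
        test_X = templates + 0.01 * rng.normal(size=(4, 12))
        preds = max_correlation_classify(train_X, train_y, test_X, rng=0)
        assert np.array_equal(preds, np.arange(4))

    def test_relabeling_symmetry(self):
        rng = np.random.default_rng(3)
        train_X = rng.normal(size=(12, 6))
        train_y = np.repeat([0, 1, 2], 4)
        test_X = rng.normal(size=(5, 6))
        preds = max_correlation_classify(train_X, train_y, test_X, rng=0)
        phi = {0: 2, 1: 0, 2: 1}
        relabeled = np.array([phi[c] for c in train_y])
        preds2 = max_correlation_classify(train_X, relabeled, test_X, rng=0)
        assert np.array_equal(np.array([phi[c] for c in preds]), preds2)

    def test_undefined_correlations_get_seeded_random_class(self):
        train_X = np.array([[1.0, 2.0], [2.0, 1.0], [0.0, 3.0], [3.0, 0.0]])
        train_y = np.array([0, 0, 1, 1])
        test_X = np.array([[5.0, 5.0]])  # zero variance: correlation undefined
        p1 = max_correlation_classify(train_X, train_y, test_X, rng=11)
        p2 = max_correlation_classify(train_X, train_y, test_X, rng=11)
        assert p1[0] in (0, 1)
        assert np.array_equal(p1, p2)

    def test_single_neuron_rejected(self):
        with pytest.raises(ValueError):
            max_correlation_classify(
                np.ones((4, 1)), np.array([0, 0, 1, 1]), np.ones((1, 1))
            )


class TestPermutationP:
    def test_add_one_rule(self):
        null = np.array([0.1, 0.2, 0.3])
        assert _permutation_p(null, 0.5) == 1 / 4
        assert _permutation_p(null, 0.0) == 1.0
        assert _permutation_p(null, 0.25) == 2 / 4


class TestPseudopopulation:
    def _feats(self, rng, n_sessions=3, n_neurons=5, n_classes=4, n_trials=6):
        feats = []
        for s in range(n_sessions):
            y = np.repeat(np.arange(n_classes), n_trials)
            X = rng.normal(size=(y.size, n_neurons))
            ids = [f"s{s}-n{j}" for j in range(n_neurons)]
            feats.append((X, y, ids))
        return feats

    def test_shape_and_labels(self):
        rng = np.random.default_rng(0)
        feats = self._feats(rng)
        pop = assemble_pseudopopulation(feats, n_neurons=8, n_per_class=6, rng=rng)
        assert pop.X.shape == (4 * 6, 8)
        assert np.array_equal(pop.labels, np.repeat(np.arange(4), 6))
        assert len(set(pop.neuron_ids)) == 8

    def test_rows_are_permutations_of_source_trials(self):
        rng = np.random.default_rng(5)
        feats = self._feats(rng, n_trials=6)
        pop = assemble_pseudopopulation(feats, n_neurons=6, n_per_class=6, rng=rng)
        lookup = {
            nid: (s, j)
            for s, (_, _, ids) in enumerate(feats)
            for j, nid in enumerate(ids)
        }
        for k, nid in enumerate(pop.neuron_ids):
            s, j = lookup[nid]
            X, y, _ = feats[s]
            for c in range(4):
                got = np.sort(pop.X[pop.labels == c, k])
                want = np.sort(X[y == c, j])
                assert np.allclose(got, want)

    def test_subsamples_when_more_trials_than_needed(self):
        rng = np.random.default_rng(2)
        feats = self._feats(rng, n_trials=8)
        pop = assemble_pseudopopulation(feats, n_neurons=4, n_per_class=5, rng=rng)
        lookup = {
            nid: (s, j)
            for s, (_, _, ids) in enumerate(feats)
            for j, nid in enumerate(ids)
        }
        for k, nid in enumerate(pop.neuron_ids):
            s, j = lookup[nid]
            X, y, _ = feats[s]
            for c in range(4):
                got = set(np.round(pop.X[pop.labels == c, k], 12))
                want = set(np.round(X[y == c, j], 12))
                assert got <= want and len(got) == 5

    def test_deterministic_for_fixed_seed(self):
        feats = self._feats(np.random.default_rng(9))
        pop1 = assemble_pseudopopulation(feats, 6, 6, np.random.default_rng(4))
        pop2 = assemble_pseudopopulation(feats, 6, 6, np.random.default_rng(4))
        assert np.array_equal(pop1.X, pop2.X)
        assert pop1.neuron_ids == pop2.neuron_ids

    def test_errors_on_small_pool_or_few_trials(self):
        rng = np.random.default_rng(0)
        feats = self._feats(rng, n_sessions=1, n_neurons=3)
        with pytest.raises(ValueError):
            assemble_pseudopopulation(feats, n_neurons=10, n_per_class=6, rng=rng)
        with pytest.raises(ValueError):
            assemble_pseudopopulation(feats, n_neurons=2, n_per_class=7, rng=rng)


class TestCrossValidation:
    def test_perfectly_separable_classes_decode_perfectly(self):
        rng = np.random.default_rng(0)
        n_classes, n_per, n_neurons = 4, 8, 12
        templates = np.eye(n_classes).repeat(3, axis=1) * 10
        X = np.vstack(
            [t + 0.01 * rng.normal(size=n_neurons) for t in templates for _ in range(n_per)]
        )
        y = np.repeat(np.arange(n_classes), n_per)
        acc = cross_validated_accuracy(X, y, n_splits=8, n_resample_runs=2, rng=0)
        assert acc == 1.0

    def test_unequal_class_counts_rejected(self):
        X = np.ones((7, 3))
        y = np.array([0, 0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError):
            cross_validated_accuracy(X, y, n_splits=2)

    def test_splits_must_divide_trials(self):
        X = np.ones((12, 3))
        y = np.repeat([0, 1], 6)
        with pytest.raises(ValueError):
            cross_validated_accuracy(X, y, n_splits=5)


class TestSessionFeatureMatrix:
    def test_shapes_and_labels(self, session1):
        session, _ = session1
        X, y, ids = session_feature_matrix(session, "PC", TimeWindow(0, 2))
        assert X.shape == (128, len(ids))
        assert sorted(set(y)) == list(range(16))

    def test_drop_first_cycle(self, session1):
        session, _ = session1
        X, y, _ = session_feature_matrix(
            session, "PC", TimeWindow(0, 2), drop_first_cycle=True
        )
        assert X.shape[0] == 112  # 16 stimuli x 7 cycles

    def test_perceived_labels(self, session1):
        session, _ = session1
        X, y, _ = session_feature_matrix(
            session, "AMY", TimeWindow(0, 2), phase="identification",
            label="chosen_stimulus_id",
        )
        assert X.shape[0] == 64
        assert np.all(y >= 0)  # identification trials always record a choice

    def test_empty_region(self, session1):
        session, _ = session1
        stripped = oc.SessionData(
            "x", "p", [n for n in session.neurons if n.region != "PC"], session.trials
        )
        X, y, ids = session_feature_matrix(stripped, "PC", TimeWindow(0, 2))
        assert X.size == 0 and ids == []


class TestDecodingAnalyses:
    def test_population_decoding_above_chance_in_pc(self, cohort4):
        sessions, _ = cohort4
        cfg = DecodingConfig(
            n_neurons=30, n_subsample_runs=8, n_permutations=25, seed=5
        )
        res = oc.population_decoding_with_null(sessions, "PC", cfg)
        assert res.chance == pytest.approx(1 / 16)
        assert res.accuracy > 2 * res.chance
        assert res.p < 0.05
        assert abs(float(res.null_accuracies.mean()) - res.chance) < 0.03

    def test_session_decoding_skips_tiny_regions(self, session1):
        session, _ = session1
        one_neuron = oc.SessionData(
            "x", "p", session.neurons_in_region("PC")[:1], session.trials
        )
        res = oc.session_decoding(one_neuron, "PC")
        assert res.skipped
        assert "need >= 2" in res.skip_reason

    def test_session_decoding_runs(self, session1):
        session, _ = session1
        cfg = DecodingConfig(n_permutations=20, seed=0)
        res = oc.session_decoding(session, "AMY", cfg)
        assert not res.skipped
        assert 0.0 <= res.accuracy <= 1.0
        assert res.null_accuracies.size == 20
        assert 0 < res.p <= 1

    def test_cross_modal_requires_image_block(self, session1):
        session, _ = session1
        no_images = oc.SessionData(
            "x", "p", session.neurons, session.odour_trials()
        )
        res = oc.cross_modal_decoding([no_images], "PC", "image_to_odour")
        assert res.skipped

    def test_cross_modal_direction_validated(self, cohort4):
        with pytest.raises(ValueError):
            oc.cross_modal_decoding(cohort4[0], "PC", "sideways")
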