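"""Learner contracts: supervised, self-learning, rho-path/LDS, stacking."""

import numpy as np
import networkx as nx
import pytest

from ppimut.classifiers import (
    PROBLEM_1,
    PROBLEM_2,
    PROBLEM_3,
    ConfigurationError,
    DisconnectedGraphError,
    LearnerConfig,
    ProblemSpec,
    _center_and_clip,
    _knn_graph,
    augment_with_stacked_features,
    load_model,
    predict,
    project_labels,
    rho_path_distance,
    save_model,
    stacked_feature,
    train,
    train_lds,
    train_self_learning_rf,
    train_stacked_3class,
    train_supervised,
)
from ppimut.features import N_FEATURES, FeatureTable
from ppimut.synthetic import GeneratorConfig, generate, truth_accuracy

from conftest import make_stub_model


def split(table, n_train):
    n = len(table)
    train_part = table.select([i < n_train for i in range(n)])
    test_part = table.select([i >= n_train for i in range(n)])
    return train_part, test_part


class TestSupervised:
    def test_separable_clusters_are_memorized(self, separable_dataset):
        table = separable_dataset.labeled
        model = train_supervised(table, PROBLEM_3, LearnerConfig(kind="rf", seed=0))
        preds = predict(model, table.drop_labels())
        assert [p.predicted_class for p in preds] == list(table.labels)

    def test_same_seed_gives_identical_predictions(self, separable_dataset, hard_dataset):
        probe = hard_dataset.labeled.drop_labels()
        runs = []
        for _ in range(2):
            model = train_supervised(
                separable_dataset.labeled, PROBLEM_3, LearnerConfig(kind="rf", seed=42)
            )
            runs.append([(p.predicted_class, tuple(p.scores.values())) for p in predict(model, probe)])
        assert runs[0] == runs[1]

    def test_high_separability_holdout_accuracy(self):
        ds = generate(GeneratorConfig(n_mutations=500, separability=3.0, seed=21,
                                      unlabeled_multiplier=0))
        tr, te = split(ds.labeled, 400)
        model = train_supervised(tr, PROBLEM_3, LearnerConfig(kind="rf", seed=21))
        acc = truth_accuracy(predict(model, te.drop_labels()), ds)
        assert acc >= 0.90

    @pytest.mark.parametrize("kernel", ["linear", "poly", "rbf"])
    def test_svm_kernels_train_and_score(self, separable_dataset, kernel):
        model = train_supervised(
            separable_dataset.labeled, PROBLEM_3,
            LearnerConfig(kind="svm", kernel=kernel, seed=0),
        )
        preds = predict(model, separable_dataset.unlabeled)
        for p in preds:
            assert sum(p.scores.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(0.0 <= s <= 1.0 for s in p.scores.values())

    def test_absent_class_is_a_configuration_error(self, separable_dataset):
        mask = [lab != "beneficial" for lab in separable_dataset.labeled.labels]
        truncated = separable_dataset.labeled.select(mask)
        with pytest.raises(ConfigurationError, match="absent"):
            train_supervised(truncated, PROBLEM_3, LearnerConfig(kind="rf", seed=0))

    def test_scores_equal_forest_vote_fractions(self, separable_dataset, hard_dataset):
        model = train_supervised(
            separable_dataset.labeled, PROBLEM_3, LearnerConfig(kind="rf", seed=3)
        )
        probe = hard_dataset.labeled.drop_labels()
        preds = predict(model, probe)
        forest = model._impl.forest
        X = probe.frame[list(model.input_names)].to_numpy(float)
        votes = np.stack([tree.predict(X) for tree in forest.estimators_])
        for i, p in enumerate(preds):
            for j, cls in enumerate(forest.classes_):
                assert p.scores[cls] == pytest.approx(float((votes[:, i] == j).mean()))


class TestProjectLabels:
    def test_problem1_drops_neutral(self, separable_dataset):
        table = separable_dataset.labeled
        projected = project_labels(table, PROBLEM_1)
        assert set(projected.labels) == {"strengthening", "weakening"}
        n_neutral = (table.labels == "neutral").sum()
        assert len(projected) == len(table) - n_neutral

    def test_problem2_merges_preserving(self, separable_dataset):
        table = separable_dataset.labeled
        projected = project_labels(table, PROBLEM_2)
        counts = projected.labels.value_counts()
        expected = (table.labels == "beneficial").sum() + (table.labels == "neutral").sum()
        assert counts["preserving"] == expected
        assert len(projected) == len(table)


class TestSelfLearning:
    def test_empty_unlabeled_degenerates_to_supervised(self, separable_dataset, hard_dataset):
        probe = hard_dataset.labeled.drop_labels()
        sup = train_supervised(separable_dataset.labeled, PROBLEM_3,
                               LearnerConfig(kind="rf", seed=5))
        deg = train_self_learning_rf(separable_dataset.labeled, None, PROBLEM_3,
                                     LearnerConfig(kind="rf_sl", seed=5))
        assert [p.predicted_class for p in predict(sup, probe)] == [
            p.predicted_class for p in predict(deg, probe)
        ]

    def test_every_unlabeled_row_gets_a_pseudo_label(self, separable_dataset):
        model = train_self_learning_rf(
            separable_dataset.labeled, separable_dataset.unlabeled, PROBLEM_3,
            LearnerConfig(kind="rf_sl", seed=5),
        )
        counts = model.training_summary["pseudo_label_counts"]
        assert sum(counts.values()) == len(separable_dataset.unlabeled)
        assert model.training_summary["unlabeled_size"] == len(separable_dataset.unlabeled)

    def test_pseudo_labels_agree_with_latent_truth_when_separated(self, separable_dataset):
        model = train_self_learning_rf(
            separable_dataset.labeled, separable_dataset.unlabeled, PROBLEM_3,
            LearnerConfig(kind="rf_sl", seed=5),
        )
        preds = predict(model, separable_dataset.unlabeled)
        assert truth_accuracy(preds, separable_dataset) >= 0.95

    def test_labeled_set_required(self, separable_dataset):
        empty = separable_dataset.labeled.select([False] * len(separable_dataset.labeled))
        with pytest.raises(ConfigurationError):
            train_self_learning_rf(empty, separable_dataset.unlabeled, PROBLEM_3,
                                   LearnerConfig(kind="rf_sl", seed=0))

    def test_unlabeled_with_labels_rejected(self, separable_dataset):
        with pytest.raises(ConfigurationError, match="must not carry labels"):
            train_self_learning_rf(
                separable_dataset.labeled, separable_dataset.labeled, PROBLEM_3,
                LearnerConfig(kind="rf_sl", seed=0),
            )


class TestRhoPathDistance:
    def test_diagonal_is_zero_symmetric_nonnegative(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        D = rho_path_distance(pts, 3, 1.0)
        assert np.allclose(np.diag(D), 0.0)
        assert np.allclose(D, D.T)
        assert (D >= 0).all()

    def test_collinear_points_shortest_path_limit(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        D = rho_path_distance(pts, 2, 1e-6)
        assert D[0, 2] == pytest.approx(2.0, abs=1e-4)

    def test_matches_brute_force_simple_path_enumeration(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 2))
        k, rho = 3, 1.0
        D = rho_path_distance(pts, k, rho)
        W = _knn_graph(pts, k).toarray()
        G = nx.from_numpy_array(W)
        for i in range(6):
            for j in range(i + 1, 6):
                best = min(
                    sum(np.expm1(rho * W[a][b]) for a, b in zip(p, p[1:]))
                    for p in nx.all_simple_paths(G, i, j)
                )
                assert D[i, j] == pytest.approx(np.log1p(best) / rho, abs=1e-9)

    def test_large_rho_approaches_bottleneck_distance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(7, 2))
        k = 3
        D = rho_path_distance(pts, k, 50.0)
        W = _knn_graph(pts, k).toarray()
        G = nx.from_numpy_array(W)
        for i in range(7):
            for j in range(i + 1, 7):
                bottleneck = min(
                    max(W[a][b] for a, b in zip(p, p[1:]))
                    for p in nx.all_simple_paths(G, i, j)
                )
                assert D[i, j] == pytest.approx(bottleneck, abs=0.05)

    def test_disconnected_graph_names_components(self):
        pts = np.vstack([np.zeros((3, 2)), np.full((3, 2), 100.0)])
        pts += np.random.default_rng(1).normal(0, 0.1, pts.shape)
        with pytest.raises(DisconnectedGraphError, match="2 connected components"):
            rho_path_distance(pts, 2, 1.0)

    def test_invalid_parameters(self):
        pts = np.zeros((3, 1))
        with pytest.raises(ConfigurationError):
            rho_path_distance(pts, 3, -1.0)
        with pytest.raises(ConfigurationError):
            rho_path_distance(pts, 0, 1.0)


class TestLds:
    def test_clusters_bridged_by_low_density_space(self, two_blob_tables):
        labeled, unlabeled, membership = two_blob_tables
        problem = ProblemSpec(1, ("left", "right"), "left")
        model = train_lds(labeled, unlabeled, problem,
                          LearnerConfig(kind="lds", seed=0, k_neighbors=5, rho=1.0))
        preds = predict(model, unlabeled)
        assert all(p.predicted_class == membership[p.example_id] for p in preds)

    def test_empty_unlabeled_still_trains(self, separable_dataset):
        model = train_lds(separable_dataset.labeled, None, PROBLEM_3,
                          LearnerConfig(kind="lds", seed=0))
        preds = predict(model, separable_dataset.labeled.drop_labels())
        assert len(preds) == len(separable_dataset.labeled)

    def test_corrected_kernel_is_positive_semidefinite(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(20, 4))
        D = rho_path_distance(pts, 4, 1.0)
        eigvecs, eigvals, _, _ = _center_and_clip(D)
        assert (eigvals > 0).all()
        K = (eigvecs * eigvals) @ eigvecs.T
        spectrum = np.linalg.eigvalsh((K + K.T) / 2)
        assert spectrum.min() >= -1e-8

    def test_out_of_sample_points_follow_their_cluster(self, two_blob_tables):
        labeled, unlabeled, membership = two_blob_tables
        problem = ProblemSpec(1, ("left", "right"), "left")
        model = train_lds(labeled, unlabeled, problem,
                          LearnerConfig(kind="lds", seed=0, k_neighbors=5, rho=1.0))
        rng = np.random.default_rng(12)
        fresh = FeatureTable.from_arrays(
            ["new_left", "new_right"],
            np.vstack([
                rng.normal(-1.0, 0.2, N_FEATURES),
                rng.normal(1.0, 0.2, N_FEATURES),
            ]),
        )
        preds = {p.example_id: p.predicted_class for p in predict(model, fresh)}
        assert preds == {"new_left": "left", "new_right": "right"}


class TestStacking:
    def test_scaled_prediction_value_rule(self):
        table = FeatureTable.from_arrays(["e1"], np.zeros((1, N_FEATURES)))
        positive_08 = make_stub_model(PROBLEM_1, [0.8, 0.2])
        negative_08 = make_stub_model(PROBLEM_1, [0.2, 0.8])
        fifty_fifty = make_stub_model(PROBLEM_1, [0.5, 0.5])
        assert stacked_feature(positive_08, table)[0] == pytest.approx(0.8)
        assert stacked_feature(negative_08, table)[0] == pytest.approx(0.2)
        assert stacked_feature(fifty_fifty, table)[0] == pytest.approx(0.5)

    def test_three_class_model_is_a_contract_error(self):
        table = FeatureTable.from_arrays(["e1"], np.zeros((1, N_FEATURES)))
        model3 = make_stub_model(PROBLEM_3, [0.2, 0.3, 0.5])
        with pytest.raises(ConfigurationError):
            stacked_feature(model3, table)

    def test_augmented_width_is_35(self, separable_dataset):
        binaries = (
            make_stub_model(PROBLEM_1, [0.6, 0.4]),
            make_stub_model(PROBLEM_2, [0.7, 0.3]),
        )
        aug = augment_with_stacked_features(separable_dataset.labeled, binaries)
        feature_cols = [c for c in aug.frame.columns if c not in ("id", "label", "ddg")]
        assert len(feature_cols) == 35

    def test_stacked_training_and_prediction(self, separable_dataset):
        model = train(
            separable_dataset.labeled, PROBLEM_3,
            LearnerConfig(kind="rf_sl_2f", seed=1),
            unlabeled=separable_dataset.unlabeled,
        )
        assert len(model._impl.forest_impl.names) == 35
        preds = predict(model, separable_dataset.unlabeled)
        assert truth_accuracy(preds, separable_dataset) >= 0.9

    def test_uninformative_augmentation_within_sampling_noise(self):
        """Constant stacked features should not change accuracy materially."""
        deltas = []
        for seed in range(10):
            ds = generate(GeneratorConfig(n_mutations=260, separability=1.0, seed=100 + seed,
                                          unlabeled_multiplier=0))
            tr, te = split(ds.labeled, 200)
            plain = train_self_learning_rf(tr, None, PROBLEM_3,
                                           LearnerConfig(kind="rf_sl", seed=seed))
            flat_binaries = (
                make_stub_model(PROBLEM_1, [0.5, 0.5]),
                make_stub_model(PROBLEM_2, [0.5, 0.5]),
            )
            stacked = train_stacked_3class(tr, None, PROBLEM_3, flat_binaries,
                                           LearnerConfig(kind="rf_sl_2f", seed=seed))
            probe = te.drop_labels()
            acc_plain = truth_accuracy(predict(plain, probe), ds)
            acc_stacked = truth_accuracy(predict(stacked, probe), ds)
            deltas.append(acc_stacked - acc_plain)
        assert abs(float(np.mean(deltas))) < 0.03


class TestPredictContract:
    def test_missing_columns_named(self, separable_dataset):
        model = train_supervised(separable_dataset.labeled, PROBLEM_3,
                                 LearnerConfig(kind="rf", seed=0))
        broken = separable_dataset.labeled.frame.drop(columns=["ASA"])
        with pytest.raises(Exception, match="ASA"):
            predict(model, FeatureTable(broken))

    def test_tie_break_uses_class_order(self):
        table = FeatureTable.from_arrays(["e1"], np.zeros((1, N_FEATURES)))
        tied = make_stub_model(PROBLEM_3, [1 / 3, 1 / 3, 1 / 3])
        assert predict(tied, table)[0].predicted_class == PROBLEM_3.classes[0]

    def test_serialization_round_trip_and_version_guard(self, tmp_path, separable_dataset):
        model = train_supervised(separable_dataset.labeled, PROBLEM_3,
                                 LearnerConfig(kind="rf", seed=8))
        path = tmp_path / "model.joblib"
        save_model(model, path)
        back = load_model(path)
        probe = separable_dataset.unlabeled
        assert [p.predicted_class for p in predict(back, probe)] == [
            p.predicted_class for p in predict(model, probe)
        ]
        import joblib

        payload = joblib.load(path)
        payload["format_version"] = 99
        joblib.dump(payload, path)
        with pytest.raises(ConfigurationError, match="version"):
            load_model(path)


class TestSeparabilityMonotonicity:
    @pytest.mark.parametrize("kind", ["rf", "svm", "rf_sl", "lds"])
    def test_holdout_accuracy_non_decreasing_in_separability(self, kind):
        """Mean held-out accuracy rises with signal; one small inversion allowed."""
        levels = (0.0, 1.0, 3.0)
        regime = "cluster" if kind == "lds" else "linear"
        n_inf = 33 if kind == "lds" else 8
        means = []
        for sep in levels:
            accs = []
            for seed in range(5):
                ds = generate(GeneratorConfig(
                    n_mutations=180, separability=sep, seed=200 + seed,
                    unlabeled_multiplier=1, regime=regime, n_informative_features=n_inf,
                ))
                tr, te = split(ds.labeled, 120)
                model = train(tr, PROBLEM_3, LearnerConfig(kind=kind, seed=seed),
                              unlabeled=ds.unlabeled)
                accs.append(truth_accuracy(predict(model, te.drop_labels()), ds))
            means.append(float(np.mean(accs)))
        inversions = [means[i + 1] < means[i] - 0.02 for i in range(len(means) - 1)]
        assert sum(inversions) <= 1, means


class TestSemiSupervisedUsefulness:
    def test_self_learning_not_worse_than_supervised(self):
        """With informative unlabeled data RF-SL stays within 0.02 of RF."""
        diffs = []
        for seed in range(10):
            ds = generate(GeneratorConfig(
                n_mutations=200, separability=2.0, seed=300 + seed,
                unlabeled_multiplier=2, regime="cluster", n_informative_features=33,
            ))
            tr, te = split(ds.labeled, 150)
            probe = te.drop_labels()
            sup = train(tr, PROBLEM_3, LearnerConfig(kind="rf", seed=seed))
            semi = train(tr, PROBLEM_3, LearnerConfig(kind="rf_sl", seed=seed),
                         unlabeled=ds.unlabeled)
            diffs.append(
                truth_accuracy(predict(semi, probe), ds)
                - truth_accuracy(predict(sup, probe), ds)
            )
        assert float(np.mean(diffs)) >= -0.02
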