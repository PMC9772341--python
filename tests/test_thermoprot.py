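import numpy as np
import pytest

from petmine.errors import ConfigError, EvaluationError
from petmine.io import CANONICAL_AA, SequenceRecord
from petmine.synthetic import (
    SyntheticConfig,
    gen_ogt_proteomes,
    plant_dipeptide_signal,
)
from petmine.thermoprot import (
    ClassifierSpec,
    LabeledDataset,
    METHODS,
    TrainedModel,
    band_ogt_to_class,
    binary_metrics,
    cluster_identity,
    cross_validate,
    dataset_from_ogt,
    pairwise_identity,
    predict_thermophilicity,
    select_ggap_features,
    split_by_cluster,
    train_classifier,
)

from _oracles import nw_identity


class TestBanding:
    @pytest.mark.parametrize("ogt,expected", [
        (10, "psychrophilic"),
        (14.99, "psychrophilic"),
        (20, None),
        (25, "mesophilic"),
        (37, "mesophilic"),
        (40, None),
        (45, "thermophilic"),
        (55, "thermophilic"),
        (70, "thermophilic"),
        (75, None),
        (80.5, "hyperthermophilic"),
    ])
    def test_bands(self, ogt, expected):
        assert band_ogt_to_class(ogt) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ConfigError):
            band_ogt_to_class(float("nan"))


class TestClustering:
    def test_identical_sequences_one_cluster(self):
        recs = [SequenceRecord(id="a", residues="ACDEFGHIKL"),
                SequenceRecord(id="b", residues="ACDEFGHIKL")]
        assignment = cluster_identity(recs, 0.4)
        assert assignment["a"] == assignment["b"]

    def test_disjoint_sequences_two_clusters(self):
        recs = [SequenceRecord(id="a", residues="AAAAAAAAAA"),
                SequenceRecord(id="b", residues="CCCCCCCCCC")]
        assignment = cluster_identity(recs, 0.4)
        assert assignment["a"] != assignment["b"]

    def test_identity_matches_nw_oracle(self, rng):
        for _ in range(15):
            a = "".join(rng.choice(list("ACDEFG"), rng.integers(5, 15)))
            b = "".join(rng.choice(list("ACDEFG"), rng.integers(5, 15)))
            assert pairwise_identity(a, b) == pytest.approx(nw_identity(a, b))

    def test_threshold_is_inclusive(self, rng):
        # pairs at exactly the threshold join the representative's cluster
        for _ in range(20):
            a = "".join(rng.choice(list("ACDEFGHIKL"), 10))
            b = "".join(rng.choice(list("ACDEFGHIKL"), 10))
            ident = nw_identity(a, b)
            recs = [SequenceRecord(id="a", residues=a),
                    SequenceRecord(id="b", residues=b)]
            assignment = cluster_identity(recs, threshold=max(ident, 1e-9))
            assert (assignment["a"] == assignment["b"]) == (ident > 0)


class TestSplit:
    def test_singleton_clusters_follow_fractions(self):
        assignment = {f"r{i}": i for i in range(10)}
        parts = split_by_cluster(assignment, (0.8, 0.1, 0.1), seed=5)
        sizes = {p: sum(1 for v in parts.values() if v == p)
                 for p in ("train", "tune", "validation")}
        assert sizes == {"train": 8, "tune": 1, "validation": 1}
        assert parts == split_by_cluster(assignment, (0.8, 0.1, 0.1), seed=5)

    def test_single_cluster_warns(self):
        with pytest.warns(UserWarning):
            parts = split_by_cluster({"a": 0, "b": 0}, (0.8, 0.1, 0.1), seed=0)
        assert len(set(parts.values())) == 1

    def test_clusters_never_straddle_partitions(self):
        assignment = {f"r{i}": i % 7 for i in range(42)}
        parts = split_by_cluster(assignment, (0.6, 0.2, 0.2), seed=1)
        for ci in range(7):
            members = {parts[r] for r, c in assignment.items() if c == ci}
            assert len(members) == 1

    def test_missing_class_raises_balance_error(self):
        assignment = {"a": 0, "b": 1, "c": 2}
        labels = {"a": "mesophilic", "b": "mesophilic", "c": "thermophilic"}
        with pytest.raises(EvaluationError):
            split_by_cluster(assignment, (0.4, 0.3, 0.3), seed=0, labels=labels)


class TestGgapSelection:
    def test_returns_k_descriptors(self, rng):
        recs = [SequenceRecord(id=f"s{i}",
                               residues="".join(rng.choice(list(CANONICAL_AA), 60)))
                for i in range(40)]
        y = [i % 2 for i in range(40)]
        top = select_ggap_features(recs, y, k=10, seed=0)
        assert len(top) == 10 and len(set(top)) == 10

    def test_single_class_rejected(self, rng):
        recs = [SequenceRecord(id=f"s{i}",
                               residues="".join(rng.choice(list(CANONICAL_AA), 30)))
                for i in range(6)]
        with pytest.raises(EvaluationError):
            select_ggap_features(recs, [1] * 6, k=5, seed=0)

    def test_recovers_planted_descriptors(self):
        planted = [("W", 1, "W"), ("M", 0, "C"), ("H", 2, "H"),
                   ("C", 1, "M"), ("W", 0, "H")]
        for seed in (11, 12):
            cfg = SyntheticConfig(seed=seed, n_per_class=100, delta=0.0,
                                  length=(80, 160))
            recs, _ = gen_ogt_proteomes(cfg)
            pos = [r.id for r in recs if r.id.startswith("thermo")]
            recs2, _ = plant_dipeptide_signal(recs, planted, 3, seed, pos)
            y = [1 if r.id.startswith("thermo") else 0 for r in recs2]
            top = select_ggap_features(recs2, y, k=10, seed=seed)
            assert len(set(planted) & set(top)) >= 4


def _toy_dataset(n=40, seed=0, separable=True):
    rng = np.random.default_rng(seed)
    records, labels, feats = [], [], []
    for i in range(n):
        pos = i < n // 2
        center = (2.0 if pos else -2.0) if separable else 0.0
        records.append(SequenceRecord(id=f"s{i}", residues="ACDEFGHIKL"))
        labels.append("thermophilic" if pos else "mesophilic")
        feats.append(rng.normal(center, 0.3, size=2))
    return LabeledDataset(records, labels, np.array(feats), ["f0", "f1"])


class TestTraining:
    def test_separable_toy_reaches_perfect_tuning_accuracy(self):
        train = _toy_dataset(40, 0)
        tune = _toy_dataset(20, 1)
        for method in ("support_vector_machine", "logistic_regression"):
            spec = ClassifierSpec(scheme="MTH", method=method, seed=0)
            model = train_classifier(spec, train, tune)
            Xtu, ytu = tune.features, np.array([1] * 10 + [0] * 10)
            assert (model.predict(Xtu) == ytu).all()

    def test_retraining_is_deterministic(self):
        train, tune = _toy_dataset(40, 0), _toy_dataset(20, 1)
        probe = _toy_dataset(30, 2).features
        spec = ClassifierSpec(method="random_forest", seed=3)
        m1 = train_classifier(spec, train, tune)
        m2 = train_classifier(ClassifierSpec(method="random_forest", seed=3),
                              train, tune)
        assert np.array_equal(m1.decision_scores(probe), m2.decision_scores(probe))

    def test_zero_variance_feature_dropped_with_warning(self):
        train, tune = _toy_dataset(40, 0), _toy_dataset(20, 1)
        train.features = np.hstack([train.features, np.ones((40, 1))])
        tune.features = np.hstack([tune.features, np.ones((20, 1))])
        train.feature_names = tune.feature_names = ["f0", "f1", "const"]
        with pytest.warns(UserWarning, match="zero-variance"):
            model = train_classifier(ClassifierSpec(seed=0), train, tune)
        assert model.kept_idx == [0, 1]

    @pytest.mark.parametrize("method", METHODS)
    def test_serialization_round_trips_predictions(self, method, tmp_path, rng):
        train, tune = _toy_dataset(40, 0), _toy_dataset(20, 1)
        model = train_classifier(ClassifierSpec(method=method, seed=1), train, tune)
        path = tmp_path / "model.json"
        model.save(path)
        back = TrainedModel.load(path)
        probe = rng.normal(0, 2, size=(100, 2))
        assert np.array_equal(model.predict(probe), back.predict(probe))
        assert np.array_equal(model.decision_scores(probe),
                              back.decision_scores(probe))


class TestMetrics:
    def test_mcc_example(self):
        m = binary_metrics(tp=8, fp=2, fn=1, tn=9)
        assert m["mcc"] == pytest.approx((8 * 9 - 2 * 1) /
                                         np.sqrt(10 * 9 * 10 * 11))
        assert m["accuracy"] == pytest.approx(17 / 20)

    def test_all_positive_predictions(self):
        m = binary_metrics(tp=10, fp=10, fn=0, tn=0)
        assert m["recall"] == 1.0
        assert m["specificity"] == 0.0
        assert m["mcc"] == 0.0

    def test_perfect_confusion_gives_unit_mcc(self):
        assert binary_metrics(5, 0, 0, 5)["mcc"] == 1.0


class TestCrossValidation:
    def test_strong_effect_is_learnable(self):
        cfg = SyntheticConfig(seed=5, n_per_class=100, delta=0.2)
        recs, _ = gen_ogt_proteomes(cfg)
        ds = dataset_from_ogt(recs)
        em = cross_validate(ClassifierSpec(seed=5), ds, folds=5, seed=5)
        assert em.accuracy >= 0.95

    def test_label_permutation_is_chance_level(self):
        cfg = SyntheticConfig(seed=3, n_per_class=200, delta=0.0)
        recs, _ = gen_ogt_proteomes(cfg)
        ds = dataset_from_ogt(recs)
        em = cross_validate(
            ClassifierSpec(method="logistic_regression", seed=3), ds, 5, seed=3)
        assert abs(em.accuracy - 0.5) <= 0.07

    def test_accuracy_nondecreasing_in_effect_size(self):
        # allow one inversion within 0.02 across the effect-size ladder
        for seed in range(1, 6):
            accs = []
            for delta in (0.0, 0.02, 0.05, 0.1):
                cfg = SyntheticConfig(seed=seed, n_per_class=100, delta=delta)
                recs, _ = gen_ogt_proteomes(cfg)
                ds = dataset_from_ogt(recs)
                em = cross_validate(ClassifierSpec(seed=seed), ds, 5, seed=seed)
                accs.append(em.accuracy)
            inversions = [max(0.0, accs[i] - accs[i + 1]) for i in range(3)]
            assert sum(1 for v in inversions if v > 1e-12) <= 1
            assert max(inversions) <= 0.02 + 1e-12, (seed, accs)

    def test_cluster_fold_hygiene(self):
        cfg = SyntheticConfig(seed=9, n_per_class=30, delta=0.1)
        recs, _ = gen_ogt_proteomes(cfg)
        clusters = {r.id: i // 3 for i, r in enumerate(recs)}
        ds = dataset_from_ogt(recs, clusters=clusters)
        from sklearn.model_selection import StratifiedGroupKFold
        X, y, _, cl = (ds.features,
                       np.array([1 if l == "thermophilic" else 0 for l in ds.labels]),
                       None, ds.clusters)
        for tr, te in StratifiedGroupKFold(5, shuffle=True, random_state=0).split(X, y, cl):
            assert not (set(cl[tr]) & set(cl[te]))

    def test_too_few_folds_rejected(self):
        ds = _toy_dataset(20, 0)
        with pytest.raises(ConfigError):
            cross_validate(ClassifierSpec(seed=0), ds, folds=1, seed=0)


class TestPrediction:
    def test_empty_input_gives_empty_output(self):
        train, tune = _toy_dataset(40, 0), _toy_dataset(20, 1)
        model = train_classifier(ClassifierSpec(seed=0), train, tune)
        assert predict_thermophilicity(model, []) == []

    def test_training_sequences_reproduce_in_sample_labels(self):
        cfg = SyntheticConfig(seed=9, n_per_class=60, delta=0.2, length=(90, 110))
        recs, _ = gen_ogt_proteomes(cfg)
        ds = dataset_from_ogt(recs)
        half = len(ds.records) // 2
        tr = LabeledDataset(ds.records[:50] + ds.records[half:half + 50],
                            ds.labels[:50] + ds.labels[half:half + 50],
                            np.vstack([ds.features[:50], ds.features[half:half + 50]]),
                            ds.feature_names)
        tu = LabeledDataset(ds.records[50:60] + ds.records[half + 50:half + 60],
                            ds.labels[50:60] + ds.labels[half + 50:half + 60],
                            np.vstack([ds.features[50:60],
                                       ds.features[half + 50:half + 60]]),
                            ds.feature_names)
        model = train_classifier(ClassifierSpec(seed=9), tr, tu)
        calls = predict_thermophilicity(model, tr.records)
        scores = model.decision_scores(tr.features)
        for call, s in zip(calls, scores):
            assert (call["label"] == "thermophilic") == (s > 0)

    def test_biased_sequences_called_thermophilic(self):
        from conftest import train_model_on_proteomes
        model = train_model_on_proteomes(delta=0.2, seed=9, n_per_class=100,
                                         length=(150, 250))
        cfg = SyntheticConfig(seed=99, n_per_class=50, delta=0.2, length=(190, 210))
        recs, _ = gen_ogt_proteomes(cfg)
        thermo = [r for r in recs if r.id.startswith("thermo")]
        calls = predict_thermophilicity(model, thermo)
        frac = np.mean([c["label"] == "thermophilic" for c in calls])
        assert frac >= 0.9
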