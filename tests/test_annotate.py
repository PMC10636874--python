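import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import cross_val_score
from sklearn.svm import SVC

from lncgo.annotate import (AnnotationTable, SVMConfig,
                            build_term_training_set, filter_non_iea,
                            predict_lncrna_functions, propagate_annotations,
                            train_term_classifier, train_term_classifiers)

GO = [f"GO:{i:07d}" for i in range(1, 10)]


def table(rows):
    return AnnotationTable.from_records(rows)


class TestAnnotationTable:
    def test_malformed_go_id_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            table([("p1", "GO:123", "EXP")])

    def test_exact_duplicates_dropped(self):
        t = table([("p1", GO[0], "EXP"), ("p1", GO[0], "EXP")])
        assert len(t) == 1


class TestFilterNonIea:
    def test_iea_only_protein_removed(self):
        t = table([("p1", GO[0], "IEA"), ("p2", GO[1], "EXP")])
        out = filter_non_iea(t)
        assert out.proteins() == ["p2"]

    def test_mixed_evidence_protein_keeps_all_records(self):
        t = table([("p1", GO[0], "EXP"), ("p1", GO[1], "IEA")])
        out = filter_non_iea(t)
        assert len(out) == 2

    def test_empty_table_passes_through(self):
        out = filter_non_iea(AnnotationTable(
            pd.DataFrame(columns=list(AnnotationTable.COLUMNS))))
        assert len(out) == 0


class TestPropagate:
    def test_disabled_is_identity(self):
        t = table([("p1", GO[2], "EXP")])
        assert propagate_annotations(t, None, enabled=False) is t

    def test_chain_propagates_to_all_ancestors(self):
        dag = nx.DiGraph([(GO[2], GO[1]), (GO[1], GO[0])])  # c is_a b is_a a
        t = table([("p1", GO[2], "EXP")])
        out = propagate_annotations(t, dag, enabled=True)
        assert set(out.records["go_term"]) == {GO[0], GO[1], GO[2]}

    def test_diamond_matches_reachability_oracle(self):
        dag = nx.DiGraph([(GO[3], GO[1]), (GO[3], GO[2]),
                          (GO[1], GO[0]), (GO[2], GO[0])])
        t = table([("p1", GO[3], "EXP")])
        out = propagate_annotations(t, dag, enabled=True)
        expected = {GO[3]} | set(nx.descendants(dag, GO[3]))
        assert set(out.records["go_term"]) == expected

    def test_cycle_rejected(self):
        dag = nx.DiGraph([(GO[0], GO[1]), (GO[1], GO[0])])
        with pytest.raises(ValueError, match="cycle"):
            propagate_annotations(table([("p1", GO[0], "EXP")]), dag,
                                  enabled=True)


def embeddings_for(n, d=4, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"p{i}" for i in range(n)]
    return pd.DataFrame(rng.random((n, d)), index=ids), ids


class TestTrainingSet:
    def test_balanced_and_disjoint(self):
        emb, ids = embeddings_for(100)
        t = table([(p, GO[0], "EXP") for p in ids[:10]])
        ts = build_term_training_set(GO[0], t, emb, seed=1)
        assert len(ts.negatives) == len(ts.positives) == 10
        assert not set(ts.positives) & set(ts.negatives)

    def test_too_few_positives_skipped(self):
        emb, ids = embeddings_for(50)
        t = table([(p, GO[0], "EXP") for p in ids[:2]])
        assert build_term_training_set(GO[0], t, emb, seed=1,
                                       min_positives=10) is None

    def test_same_seed_same_negatives(self):
        emb, ids = embeddings_for(80)
        t = table([(p, GO[0], "EXP") for p in ids[:15]])
        a = build_term_training_set(GO[0], t, emb, seed=5)
        b = build_term_training_set(GO[0], t, emb, seed=5)
        assert a.negatives == b.negatives

    def test_missing_embedding_raises(self):
        emb, ids = embeddings_for(20)
        t = table([("ghost", GO[0], "EXP")])
        with pytest.raises(ValueError, match="ghost"):
            build_term_training_set(GO[0], t, emb, seed=1, min_positives=1)


def separable_training_set(n_per_class=15, seed=0):
    """Two well-separated Gaussian blobs in 2-D."""
    rng = np.random.default_rng(seed)
    pos = rng.normal([3.0, 3.0], 0.3, size=(n_per_class, 2))
    neg = rng.normal([-3.0, -3.0], 0.3, size=(n_per_class, 2))
    ids = [f"p{i}" for i in range(2 * n_per_class)]
    emb = pd.DataFrame(np.vstack([pos, neg]), index=ids)
    t = table([(p, GO[0], "EXP") for p in ids[:n_per_class]])
    return build_term_training_set(GO[0], t, emb, seed=seed)


class TestTermClassifier:
    def test_separable_toy_training_accuracy_one(self):
        ts = separable_training_set()
        clf = train_term_classifier(ts)
        scores = clf.predict_proba(ts.X)
        assert ((scores >= 0.5).astype(int) == ts.y).all()

    def test_scores_always_in_unit_interval(self):
        ts = separable_training_set(seed=3)
        clf = train_term_classifier(ts)
        probe = np.random.default_rng(0).normal(0, 10, size=(50, 2))
        s = clf.predict_proba(probe)
        assert (s >= 0.0).all() and (s <= 1.0).all()

    def test_permuted_labels_give_chance_level_cv(self):
        rng = np.random.default_rng(7)
        X = rng.random((60, 5))
        y = np.array([1] * 30 + [0] * 30)
        y_perm = rng.permutation(y)
        acc = cross_val_score(SVC(kernel="rbf", C=1.0), X, y_perm, cv=5).mean()
        assert abs(acc - 0.5) <= 0.15

    def test_degenerate_features_rejected(self):
        ts = separable_training_set()
        ts.X = np.ones_like(ts.X)
        with pytest.raises(ValueError, match="degenerate"):
            train_term_classifier(ts)


class TestPredict:
    def test_lncrna_close_to_positives_scores_high(self):
        ts = separable_training_set()
        clf = train_term_classifier(ts)
        lnc = pd.DataFrame([[3.0, 3.0]], index=["lnc1"])
        pred = predict_lncrna_functions([clf], lnc)
        assert pred.loc["lnc1", GO[0]] > 0.5

    def test_no_classifiers_gives_empty_matrix(self):
        lnc = pd.DataFrame(np.zeros((3, 2)), index=["a", "b", "c"])
        pred = predict_lncrna_functions([], lnc)
        assert pred.shape == (3, 0)

    def test_output_shape(self):
        emb, ids = embeddings_for(60, d=3, seed=1)
        t = table([(p, GO[k], "EXP") for k in range(2) for p in ids[k::2][:20]])
        classifiers = train_term_classifiers(t, emb, seed=0, min_positives=10)
        lnc = pd.DataFrame(np.random.default_rng(2).random((7, 3)),
                           index=[f"l{i}" for i in range(7)])
        pred = predict_lncrna_functions(classifiers, lnc)
        assert pred.shape == (7, len(classifiers))
        assert ((pred.to_numpy() >= 0) & (pred.to_numpy() <= 1)).all()

    def test_width_mismatch_rejected(self):
        ts = separable_training_set()
        clf = train_term_classifier(ts)
        with pytest.raises(ValueError, match="width"):
            predict_lncrna_functions([clf], pd.DataFrame(np.zeros((2, 5))))

    def test_per_term_auroc_beats_chance_on_planted_structure(self):
        # proteins in two clusters; held-out proteins of each cluster must
        # score higher for their own cluster's term
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(11)
        n = 40
        emb = np.vstack([rng.normal(1.0, 0.5, size=(n, 4)),
                         rng.normal(-1.0, 0.5, size=(n, 4))])
        ids = [f"p{i}" for i in range(2 * n)]
        train_ids = ids[:30] + ids[n:n + 30]
        held = ids[30:n] + ids[n + 30:]
        emb_df = pd.DataFrame(emb, index=ids)
        t = table([(p, GO[0], "EXP") for p in train_ids[:30]]
                  + [(p, GO[1], "EXP") for p in train_ids[30:]])
        classifiers = train_term_classifiers(t, emb_df.loc[train_ids], seed=3)
        pred = predict_lncrna_functions(classifiers, emb_df.loc[held])
        y_true = [1] * (n - 30) + [0] * (n - 30)
        auroc = roc_auc_score(y_true, pred[GO[0]])
        assert auroc > 0.9
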