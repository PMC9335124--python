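import numpy as np
import pytest

from conftest import FAST
from pepbinder.datasets import SubDataset
from pepbinder.ensemble import (
    EnsembleBinderClassifier,
    grid_search_rbf,
    load_ensemble,
    predict_peptides,
    save_ensemble,
    train_ensemble,
    train_submodel,
)
from pepbinder.synthetic import gen_background_peptides


def _blobs(rng, n=60, sep=6.0):
    X = np.vstack([rng.normal(0, 1, (n // 2, 5)), rng.normal(sep, 1, (n // 2, 5))])
    y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    return X, y


class TestGridSearch:
    def test_grid_of_size_one(self, rng):
        X, y = _blobs(rng)
        assert grid_search_rbf(X, y, c_grid=(4.0,), gamma_grid=(0.25,), seed=0) == (4.0, 0.25)

    def test_separable_blobs_reach_perfect_cv(self, rng):
        X, y = _blobs(rng)
        c, g = grid_search_rbf(X, y, c_grid=(1.0, 8.0), gamma_grid=(0.01, 0.1), seed=0)
        from sklearn.model_selection import cross_val_score
        from sklearn.svm import SVC

        assert cross_val_score(SVC(C=c, gamma=g), X, y, cv=5).mean() == 1.0

    def test_tie_prefers_smallest_pair(self, rng):
        X, y = _blobs(rng, sep=50.0)  # trivially separable: all combos tie
        c, g = grid_search_rbf(X, y, c_grid=(1.0, 8.0), gamma_grid=(0.01, 0.1), seed=0)
        assert (c, g) == (1.0, 0.01)

    def test_deterministic_given_seed(self, rng):
        X, y = _blobs(rng, sep=1.5)
        a = grid_search_rbf(X, y, c_grid=(0.5, 2.0), gamma_grid=(0.05, 0.5), seed=3)
        b = grid_search_rbf(X, y, c_grid=(0.5, 2.0), gamma_grid=(0.05, 0.5), seed=3)
        assert a == b


class TestSubmodel:
    def test_separable_subdataset_high_cv_accuracy(self, benchmark_160):
        sm = train_submodel(benchmark_160[0], seed=1, **FAST)
        assert sm.cv_metrics_["Acc"] >= 0.95
        assert len(sm.selected_features) == FAST["n_features"]

    def test_shuffled_labels_null_auroc(self, benchmark_160, rng):
        sub = benchmark_160[0]
        pool = sub.positives + sub.negatives
        order = rng.permutation(len(pool))
        half = len(pool) // 2
        pos = [pool[i] for i in order[:half]]
        neg = [pool[i] for i in order[half:]]
        from pepbinder.io import Peptide

        shuffled = SubDataset(
            positives=[Peptide(p.id, p.seq, "positive") for p in pos],
            negatives=[Peptide(p.id, p.seq, "negative") for p in neg],
        )
        sm = train_submodel(shuffled, seed=1, **FAST)
        assert 0.3 <= sm.cv_metrics_["AUROC"] <= 0.7

    def test_training_deterministic(self, benchmark_160):
        a = train_submodel(benchmark_160[1], seed=5, **FAST)
        b = train_submodel(benchmark_160[1], seed=5, **FAST)
        assert (a.c_, a.gamma_) == (b.c_, b.gamma_)
        assert a.cv_metrics_ == b.cv_metrics_
        assert np.array_equal(a.selected_features, b.selected_features)


class TestEnsemble:
    def test_one_submodel_per_subdataset(self, small_ensemble):
        assert len(small_ensemble.submodels_) == 3

    def test_single_subdataset_degenerates_to_submodel(self, benchmark_160):
        ens = train_ensemble(benchmark_160[:1], seed=3, **FAST)
        X = ens.submodels_[0].selector_  # fitted
        from pepbinder.descriptors import encode_many

        Xq = encode_many([p.seq for p in benchmark_160[0].positives[:5]])
        assert np.allclose(
            ens.predict_proba(Xq)[:, 1], ens.submodels_[0].predict_proba(Xq)[:, 1]
        )

    def test_empty_subdataset_list_error(self):
        with pytest.raises(ValueError):
            train_ensemble([])

    def test_prob_bounded_and_permutation_invariant(self, small_ensemble, benchmark_160):
        from pepbinder.descriptors import encode_many

        X = encode_many([p.seq for p in benchmark_160[0].positives[:8]])
        p1 = small_ensemble.predict_proba(X)[:, 1]
        assert np.all((0 <= p1) & (p1 <= 1))
        small_ensemble.submodels_.reverse()
        p2 = small_ensemble.predict_proba(X)[:, 1]
        small_ensemble.submodels_.reverse()
        assert np.allclose(p1, p2)

    def test_sklearn_get_set_params_round_trip(self):
        ens = EnsembleBinderClassifier(n_submodels=4, tp=0.6)
        params = ens.get_params()
        assert params["n_submodels"] == 4 and params["tp"] == 0.6
        ens.set_params(tp=0.55)
        assert ens.tp == 0.55


class TestPredictPeptides:
    def test_threshold_is_inclusive(self, small_ensemble, benchmark_160):
        preds = predict_peptides(small_ensemble, benchmark_160[0].positives[:5], tp=0.0)
        assert all(p.label == "binder" for p in preds)  # prob >= 0 always

    def test_tp_one_requires_certainty(self, small_ensemble):
        peps = gen_background_peptides(5, seed=99)
        preds = predict_peptides(small_ensemble, peps, tp=1.0)
        for p in preds:
            assert (p.label == "binder") == (p.prob >= 1.0)

    def test_votes_count_submodels_above_threshold(self, small_ensemble, benchmark_160):
        from pepbinder.descriptors import encode_many

        preds = predict_peptides(small_ensemble, benchmark_160[0].positives[:5], tp=0.5)
        probs = small_ensemble.submodel_probs(
            encode_many([p.seq for p in benchmark_160[0].positives[:5]])
        )
        for p, row in zip(preds, probs):
            assert p.votes == int((row >= 0.5).sum())
            assert np.isclose(p.prob, row.mean())

    def test_unencodable_peptide_gets_error_entry(self, small_ensemble):
        preds = predict_peptides(small_ensemble, ["ACD", "WHRNYVACDEFG"], tp=0.5)
        assert preds[0].label == "error" and preds[0].error
        assert preds[1].label in ("binder", "non-binder")

    def test_binder_count_monotone_in_threshold(self, small_ensemble, benchmark_160):
        pool = benchmark_160[0].positives[:10] + benchmark_160[0].negatives[:10]
        counts = []
        for tp in np.linspace(0, 1, 11):
            preds = predict_peptides(small_ensemble, pool, tp=float(tp))
            counts.append(sum(p.label == "binder" for p in preds))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_invalid_threshold_rejected(self, small_ensemble):
        with pytest.raises(ValueError):
            predict_peptides(small_ensemble, [], tp=1.5)


class TestPersistence:
    def test_save_load_round_trip(self, small_ensemble, benchmark_160, tmp_path):
        from pepbinder.descriptors import encode_many

        path = tmp_path / "m.bundle"
        save_ensemble(small_ensemble, path)
        loaded = load_ensemble(path)
        X = encode_many([p.seq for p in benchmark_160[0].positives[:5]])
        assert np.allclose(
            loaded.predict_proba(X)[:, 1], small_ensemble.predict_proba(X)[:, 1]
        )

    def test_version_mismatch_fails_loudly(self, tmp_path):
        import joblib

        path = tmp_path / "bad.bundle"
        joblib.dump({"format_version": "other-0", "ensemble": None}, path)
        with pytest.raises(ValueError, match="version"):
            load_ensemble(path)
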