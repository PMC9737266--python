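import json

import numpy as np
import pytest

import pinenir as pn
from pinenir.chemometrics import one_hot, plsda_scores


def _centered(rng, n, p):
    X = rng.normal(size=(n, p))
    return X - X.mean(axis=0)


class TestPCA:
    def test_rank_one_data(self, rng):
        d = rng.normal(size=5)
        t = rng.normal(size=20)
        X = np.outer(t - t.mean(), d)
        m = pn.fit_pca(X, 1)
        assert m.explained_variance_pct[0] == pytest.approx(100.0)
        np.testing.assert_allclose(m.Q, 0, atol=1e-20)

    def test_centroid_row_has_zero_statistics(self, rng):
        X = _centered(rng, 10, 5)
        X = np.vstack([X, np.zeros(5)])  # centroid of the centered cloud
        X -= X.mean(axis=0)
        m = pn.fit_pca(X, 2)
        assert m.T2[-1] == pytest.approx(0.0, abs=1e-16)
        assert m.Q[-1] == pytest.approx(0.0, abs=1e-16)

    def test_explained_variance_matches_eigh_oracle(self, rng):
        X = _centered(rng, 50, 20)
        m = pn.fit_pca(X, 5)
        evals = np.linalg.eigvalsh(X.T @ X)[::-1]
        expected = 100.0 * evals / evals.sum()
        np.testing.assert_allclose(m.explained_variance_pct,
                                   expected[:m.explained_variance_pct.size],
                                   atol=1e-8)

    def test_scores_uncorrelated_and_loadings_orthonormal(self, rng):
        X = _centered(rng, 30, 12)
        m = pn.fit_pca(X, 6)
        cov = m.scores.T @ m.scores
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.abs(cov))
        np.testing.assert_allclose(m.loadings.T @ m.loadings, np.eye(6),
                                   atol=1e-8)

    def test_scores_equal_data_times_loadings(self, rng):
        X = _centered(rng, 25, 8)
        m = pn.fit_pca(X, 3)
        np.testing.assert_allclose(m.scores, X @ m.loadings, atol=1e-10)

    def test_npc_beyond_rank_reduced_with_warning(self, rng):
        X = _centered(rng, 5, 10)  # rank 4
        with pytest.warns(UserWarning, match="rank"):
            m = pn.fit_pca(X, 8)
        assert m.n_pc == 4

    def test_uncentered_input_rejected(self, rng):
        with pytest.raises(ValueError, match="centered"):
            pn.fit_pca(rng.normal(loc=10.0, size=(10, 4)), 2)


class TestOutlierFlags:
    def test_gross_outlier_flagged(self, rng):
        X = rng.normal(size=(30, 10))
        X[7] *= 50.0
        Xc = X - X.mean(axis=0)
        m = pn.fit_pca(Xc, 3)
        flags = pn.flag_outliers(m)
        assert flags[7]

    def test_default_synthetic_set_has_no_gross_outliers(self, default_set):
        # screening a clean set: no gross outliers; at the 99% limits a
        # chance-level marginal exceedance (~1% of 60 spectra per
        # statistic) is statistically expected and stays advisory
        X = default_set.absorbance
        m = pn.fit_pca(X - X.mean(axis=0), 3)
        flags = pn.flag_outliers(m)
        assert flags.sum() <= 2
        assert np.all(m.T2 < 2.0 * m.T2_limit)
        assert np.all(m.Q < 2.0 * m.Q_limit)


class TestPLS1:
    def test_exact_univariate(self):
        x = np.arange(10.0)[:, None]
        y = 2.0 * x.ravel()
        m = pn.fit_pls1(x, y, 1)
        assert m.b[0] == pytest.approx(2.0)
        np.testing.assert_allclose(pn.predict_pls(m, x), y, atol=1e-10)

    def test_zero_lv_predicts_mean(self, rng):
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        m = pn.fit_pls1(X, y, 3)
        np.testing.assert_allclose(pn.predict_pls(m, X, k=0), y.mean())

    def test_predicting_x_mean_gives_y_mean(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        m = pn.fit_pls1(X, y, 4)
        assert pn.predict_pls(m, m.x_mean[None])[0] == pytest.approx(m.y_mean)

    @pytest.mark.parametrize("seed", range(20))
    def test_full_rank_matches_pseudoinverse(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(15, 40))
        y = rng.normal(size=15)
        m = pn.fit_pls1(X, y, 15)
        Xc = X - X.mean(axis=0)
        b_ls = np.linalg.pinv(Xc) @ (y - y.mean())
        np.testing.assert_allclose(pn.predict_pls(m, X),
                                   y.mean() + Xc @ b_ls, atol=1e-6)

    def test_rmsec_nonincreasing_in_lv(self, rng):
        X = rng.normal(size=(20, 15))
        y = rng.normal(size=20)
        errs = []
        m = pn.fit_pls1(X, y, 10)
        for k in range(1, m.n_lv + 1):
            errs.append(pn.rmse(y, pn.predict_pls(m, X, k)))
        assert all(a >= b - 1e-10 for a, b in zip(errs, errs[1:]))

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(25, 12))
        y = rng.normal(size=25)
        m = pn.fit_pls1(X, y, 6)
        # reconstruct scores from the stored weight/loading recursion
        Xc = X - m.x_mean
        T = np.zeros((25, m.n_lv))
        for a in range(m.n_lv):
            T[:, a] = Xc @ m.W[:, a]
            Xc = Xc - np.outer(T[:, a], m.P[:, a])
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.abs(G))

    def test_early_stop_on_orthogonal_response(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to X columns
        with pytest.warns(UserWarning, match="NIPALS stopped"):
            m = pn.fit_pls1(X, y, 2)
        assert m.n_lv == 0

    def test_matches_sklearn_predictions(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(30, 20))
        y = X @ rng.normal(size=20) + 0.1 * rng.normal(size=30)
        for k in (1, 3, 5):
            ours = pn.fit_pls1(X, y, k)
            ref = sklearn.PLSRegression(n_components=k, scale=False).fit(X, y)
            np.testing.assert_allclose(pn.predict_pls(ours, X),
                                       ref.predict(X).ravel(), atol=1e-6)

    def test_one_lv_matches_simpls_oracle(self, rng):
        # SIMPLS and NIPALS coincide at a single latent variable: the
        # weight is the dominant direction of X'y and the regression is
        # least squares of y on the single score.
        X = rng.normal(size=(18, 7))
        y = rng.normal(size=18)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        t = Xc @ w
        b_simpls = w * (t @ yc) / (t @ t)
        m = pn.fit_pls1(X, y, 1)
        np.testing.assert_allclose(m.b, b_simpls, atol=1e-8)

    def test_width_mismatch_rejected(self, rng):
        m = pn.fit_pls1(rng.normal(size=(10, 5)), rng.normal(size=10), 2)
        with pytest.raises(ValueError, match="columns"):
            pn.predict_pls(m, rng.normal(size=(3, 4)))


class TestPLSDA:
    def test_separable_clusters_fully_assigned(self, rng):
        a = rng.normal(size=(10, 5)) + np.r_[10, 0, 0, 0, 0]
        b = rng.normal(size=(10, 5)) - np.r_[10, 0, 0, 0, 0]
        X = np.vstack([a, b])
        labels = ["Aleppo"] * 10 + ["Maritime"] * 10
        m = pn.fit_plsda(X, labels, 1)
        assert list(pn.predict_plsda(m, X)) == labels

    def test_argmax_assignment_rule(self):
        # craft a model whose predicted indicator scores are fixed
        m = pn.PLSDAModel(
            n_lv=0, class_labels=("Aleppo", "Maritime", "Brutia"),
            x_mean=np.zeros(2), y_mean=np.array([0.8, 0.1, 0.1]),
            W=np.zeros((2, 0)), P=np.zeros((2, 0)), Q=np.zeros((3, 0)),
            B=np.zeros((2, 3)))
        assert pn.predict_plsda(m, np.zeros((1, 2)))[0] == "Aleppo"
        # tie between Maritime and Brutia resolves to the earlier class
        m.y_mean = np.array([0.0, 0.5, 0.5])
        assert pn.predict_plsda(m, np.zeros((1, 2)))[0] == "Maritime"

    def test_indicator_scores_sum_to_one(self, rng):
        X = rng.normal(size=(24, 8))
        labels = (["Aleppo"] * 12 + ["Maritime"] * 6 + ["Brutia"] * 6)
        m = pn.fit_plsda(X, labels, 4)
        scores = plsda_scores(m, rng.normal(size=(9, 8)))
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-8)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            pn.fit_plsda(rng.normal(size=(6, 4)), ["Aleppo"] * 6, 2)

    def test_unseen_label_rejected(self):
        with pytest.raises(ValueError, match="Stone"):
            one_hot(["Aleppo", "Stone"])


class TestSerialization:
    def test_pls1_roundtrip(self, rng):
        X = rng.normal(size=(14, 9))
        y = rng.normal(size=14)
        m = pn.fit_pls1(X, y, 3, provenance=pn.Provenance(("R1", "R3"),
                                                          "SNV", "TotalFat"))
        back = pn.model_from_json(pn.model_to_json(m))
        np.testing.assert_allclose(pn.predict_pls(back, X),
                                   pn.predict_pls(m, X), atol=1e-14)
        assert back.provenance.region_combo == ("R1", "R3")
        assert back.provenance.parameter == "TotalFat"

    def test_plsda_roundtrip_is_valid_json(self, rng):
        X = rng.normal(size=(12, 6))
        labels = ["Aleppo"] * 6 + ["Brutia"] * 6
        m = pn.fit_plsda(X, labels, 2)
        doc = pn.model_to_json(m)
        json.loads(doc)
        back = pn.model_from_json(doc)
        assert list(pn.predict_plsda(back, X)) == list(pn.predict_plsda(m, X))
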