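"""Cost function G, PCA, SPA and GA variable selection."""

import numpy as np
import pytest

import irscreen as ir
from irscreen.reduction import GAParams, regularize_covariance, spa_chain


class TestMahalanobis:
    def test_zero_at_mean(self):
        assert ir.mahalanobis_sq([1.0, 2.0], [1.0, 2.0], np.eye(2)) == 0.0

    def test_identity_covariance_is_euclidean(self):
        d = ir.mahalanobis_sq([3.0, 4.0], [0.0, 0.0], np.eye(2))
        assert d == pytest.approx(25.0)

    def test_diagonal_covariance_worked_case(self):
        d = ir.mahalanobis_sq([2.0, 3.0], [0.0, 0.0], np.diag([2.0, 1.0]))
        assert d == pytest.approx(2**2 / 2 + 3**2 / 1)  # = 11

    def test_singular_covariance_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            ir.mahalanobis_sq([1.0, 1.0], [0.0, 0.0], np.zeros((2, 2)))

    def test_regularization_restores_definiteness(self):
        C = np.array([[1.0, 1.0], [1.0, 1.0]])  # rank 1
        Creg, lam = regularize_covariance(C)
        assert lam > 0
        assert np.linalg.eigvalsh(Creg)[0] > 0


class TestCostG:
    def one_d_stats(self):
        """1-D two-class training set with pooled variance 1, means 0 and 4."""
        X = np.array([[-1.0], [1.0], [3.0], [5.0]])
        y = np.array([0, 0, 1, 1])
        stats = ir.fit_class_statistics(X, y)
        # pooled variance of {-1,1} and {3,5} around their means: 2+2 over 2 df
        assert stats.pooled_cov[0, 0] == pytest.approx(2.0)
        return stats

    def test_one_d_worked_case(self):
        X = np.array([[-1.0], [1.0], [3.0], [5.0]])
        y = np.array([0, 0, 1, 1])
        stats = ir.fit_class_statistics(X, y)
        # validation point x=1 of class 0: own d2 = 1/2, wrong d2 = 9/2
        ev = ir.cost_g(np.array([[1.0]]), np.array([0]), stats)
        assert ev.G == pytest.approx(1.0 / 9.0)
        assert ev.fitness == pytest.approx(9.0)
        assert ev.n_validation == 1

    def test_point_at_own_mean_gives_zero(self):
        stats = self.one_d_stats()
        ev = ir.cost_g(np.array([[0.0]]), np.array([0]), stats)
        assert ev.g_values[0] == 0.0

    def test_equidistant_point_gives_one(self):
        stats = self.one_d_stats()
        ev = ir.cost_g(np.array([[2.0]]), np.array([1]), stats)
        assert ev.g_values[0] == pytest.approx(1.0)

    def test_point_at_wrong_mean_flagged_inf(self):
        stats = self.one_d_stats()
        ev = ir.cost_g(np.array([[4.0]]), np.array([0]), stats)
        assert np.isinf(ev.g_values[0])
        assert ev.flagged[0]

    def test_affine_invariance(self):
        """G is unchanged by any invertible affine map applied to all data."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 3))
        y = np.array([0, 1] * 20)
        X[y == 1] += [1.0, 0.5, -0.3]
        Xv = rng.normal(size=(10, 3)) + 0.5
        yv = np.array([0, 1] * 5)
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        b = rng.normal(size=3)
        G1 = ir.cost_g(Xv, yv, ir.fit_class_statistics(X, y)).G
        G2 = ir.cost_g(Xv @ A.T + b, yv, ir.fit_class_statistics(X @ A.T + b, y)).G
        assert G2 == pytest.approx(G1, rel=1e-8)


class TestPca:
    def test_points_on_line_one_component(self):
        X = np.array([[i, i] for i in range(6)], dtype=float)
        model = ir.pca_fit(X, 2)
        ev = model.explained_variance
        assert ev[0] / ev.sum() == pytest.approx(1.0)

    def test_training_mean_maps_to_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 4))
        model = ir.pca_fit(X, 3)
        np.testing.assert_allclose(
            ir.pca_transform(model, X.mean(axis=0)), 0.0, atol=1e-12
        )

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 4))
        model = ir.pca_fit(X, 4)
        scores = ir.pca_transform(model, X)
        back = scores @ model.components + model.mean
        np.testing.assert_allclose(back, X, atol=1e-9)

    def test_sign_convention_and_sklearn_agreement(self):
        from sklearn.decomposition import PCA as SkPCA

        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 5))
        model = ir.pca_fit(X, 3)
        # largest-|.| element of each loading is positive
        for comp in model.components:
            assert comp[np.argmax(np.abs(comp))] > 0
        sk = SkPCA(n_components=3).fit(X)
        # same subspace: loadings agree up to sign
        for ours, theirs in zip(model.components, sk.components_):
            assert abs(abs(np.dot(ours, theirs)) - 1.0) < 1e-9

    def test_component_count_out_of_range(self):
        with pytest.raises(ValueError):
            ir.pca_fit(np.zeros((4, 3)), 4)


def cost_g_oracle(X_tr, y_tr, X_va, y_va, sel):
    """Independent textbook implementation of G over a variable subset."""
    sel = list(sel)
    Xt, Xv = X_tr[:, sel], X_va[:, sel]
    m0, m1 = Xt[y_tr == 0].mean(axis=0), Xt[y_tr == 1].mean(axis=0)
    X0, X1 = Xt[y_tr == 0], Xt[y_tr == 1]
    S = ((X0 - m0).T @ (X0 - m0) + (X1 - m1).T @ (X1 - m1)) / (len(Xt) - 2)
    if np.linalg.eigvalsh(S)[0] < 1e-10:
        S = S + (1e-6 * np.trace(S) / S.shape[0]) * np.eye(S.shape[0])
    Sinv = np.linalg.inv(S)
    gs = []
    for x, lab in zip(Xv, y_va):
        own = m0 if lab == 0 else m1
        wrong = m1 if lab == 0 else m0
        d_own = (x - own) @ Sinv @ (x - own)
        d_wrong = (x - wrong) @ Sinv @ (x - wrong)
        gs.append(d_own / d_wrong)
    return float(np.mean(gs))


class TestSpa:
    def test_orthogonal_columns_picked_in_norm_order(self):
        X = np.diag([3.0, 2.0, 1.0])
        chain = spa_chain(X, start=0, max_vars=3)
        assert chain == [0, 1, 2]

    def test_duplicate_column_never_selected_twice(self):
        rng = np.random.default_rng(4)
        col = rng.normal(size=10)
        X = np.column_stack([col, col, rng.normal(size=10)])
        chain = spa_chain(X, start=0, max_vars=3)
        assert 1 not in chain  # exact duplicate has zero projected norm

    def test_matches_exhaustive_prefix_oracle(self):
        """SPA equals brute-force search over all chain prefixes, scored by
        an independent G implementation."""
        rng = np.random.default_rng(6)
        n_tr, n_va, p = 24, 12, 6
        X_tr = rng.normal(size=(n_tr, p))
        y_tr = np.array([0, 1] * (n_tr // 2))
        X_tr[y_tr == 1, :2] += 1.0
        X_va = rng.normal(size=(n_va, p))
        y_va = np.array([0, 1] * (n_va // 2))
        X_va[y_va == 1, :2] += 1.0

        model = ir.spa_select(X_tr, y_tr, X_va, y_va, max_vars=3)

        best = None
        for start in range(p):
            chain = spa_chain(X_tr, start, 3)
            for L in range(1, len(chain) + 1):
                G = cost_g_oracle(X_tr, y_tr, X_va, y_va, chain[:L])
                key = (G, L, start)
                if best is None or key < best[0]:
                    best = (key, sorted(chain[:L]))
        assert sorted(model.selected.tolist()) == best[1]
        assert best[0][0] == pytest.approx(model.provenance["validation_G"])

    def test_selected_are_original_variables(self, preprocessed_cohort):
        """SPA does not modify the data space: it returns original columns."""
        dsp, _ = preprocessed_cohort
        split = ir.split_dataset(dsp)
        X, y = dsp.absorbance, dsp.labels
        model = ir.spa_select(
            X[split.train_idx], y[split.train_idx],
            X[split.val_idx], y[split.val_idx], max_vars=8,
        )
        assert model.kind == "spa"
        sel = model.selected
        assert np.array_equal(sel, np.unique(sel))  # unique, sorted
        np.testing.assert_array_equal(
            model.transform(X), X[:, sel]
        )


class TestGa:
    @staticmethod
    def planted_problem(seed=0):
        """p=10 features; vars 2 and 7 jointly separate the classes."""
        rng = np.random.default_rng(seed)
        n = 60
        X = rng.normal(size=(n, 10))
        y = np.array([0, 1] * (n // 2))
        X[y == 1, 2] += 1.2
        X[y == 1, 7] += 1.2
        Xv = rng.normal(size=(30, 10))
        yv = np.array([0, 1] * 15)
        Xv[yv == 1, 2] += 1.2
        Xv[yv == 1, 7] += 1.2
        return X, y, Xv, yv

    def test_deterministic_given_seed(self):
        X, y, Xv, yv = self.planted_problem()
        params = GAParams(generations=10, population=20, seed=99, realizations=2,
                          init_active=3)
        a = ir.ga_select(X, y, Xv, yv, params)
        b = ir.ga_select(X, y, Xv, yv, params)
        np.testing.assert_array_equal(a.selected, b.selected)

    def test_no_operators_keeps_population_except_elite(self):
        X, y, Xv, yv = self.planted_problem()
        params = GAParams(generations=5, population=10, p_crossover=0.0,
                         p_mutation=0.0, realizations=1, seed=1, init_active=3)
        model = ir.ga_select(X, y, Xv, yv, params)
        # with no operators, the best fitness can never change after gen 0
        hist = model.provenance["best_fitness_history"]
        assert all(h == pytest.approx(hist[0]) for h in hist)

    def test_best_fitness_non_decreasing(self):
        X, y, Xv, yv = self.planted_problem()
        params = GAParams(generations=15, population=30, seed=3, realizations=1,
                          init_active=3)
        model = ir.ga_select(X, y, Xv, yv, params)
        hist = model.provenance["best_fitness_history"]
        assert all(b >= a - 1e-12 for a, b in zip(hist, hist[1:]))

    def test_recovers_planted_optimum(self):
        """The planted 2-variable optimum is found in >=95% of 50 seeded runs."""
        X, y, Xv, yv = self.planted_problem(seed=42)
        hits = 0
        for seed in range(50):
            params = GAParams(generations=40, population=50, realizations=1,
                              seed=seed, init_active=3)
            model = ir.ga_select(X, y, Xv, yv, params)
            if {2, 7} <= set(model.selected.tolist()):
                hits += 1
        assert hits >= 48  # 96% of 50


class TestChoosePcaComponents:
    def test_selects_informative_dimension_count(self):
        """With class structure in 2 dims, validation G picks a small count."""
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 12))
        y = np.array([0, 1] * 30)
        X[y == 1, 0] += 2.0
        X[y == 1, 1] += 2.0
        Xv = rng.normal(size=(20, 12))
        yv = np.array([0, 1] * 10)
        Xv[yv == 1, 0] += 2.0
        Xv[yv == 1, 1] += 2.0
        model = ir.choose_pca_components(X, y, Xv, yv, max_components=8)
        assert 1 <= model.components.shape[0] <= 8
        assert "validation_G" in model.provenance
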