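import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from specfe.selection import (
    Selector,
    apply_selector,
    cars_select,
    edf_ratios,
    fit_projection,
    fit_selector,
    rank_features,
    rfe_elimination_order,
    rfe_select,
    spa_chain,
    spa_select,
    top_n_indices,
)
from specfe.selection import _pls_coef_path


class TestProjections:
    def test_pca_single_direction_explains_everything(self, rng):
        t = rng.normal(size=25)
        v = rng.normal(size=10)
        X = np.outer(t, v) + 5.0
        sel = fit_projection("pca", X, 1)
        scores = apply_selector(sel, X)
        recon = scores @ sel.state["components"] + sel.state["mean"]
        resid = np.linalg.norm(X - recon) / np.linalg.norm(X - X.mean(axis=0))
        assert resid <= 1e-8

    def test_pca_equals_svd_on_centered_data(self, rng):
        X = rng.normal(size=(20, 12))
        Xc = X - X.mean(axis=0)
        s_pca = apply_selector(fit_projection("pca", Xc, 4), Xc)
        s_svd = apply_selector(fit_projection("svd", Xc, 4), Xc)
        for k in range(4):
            col = s_svd[:, k]
            sign = np.sign(col @ s_pca[:, k])
            assert np.allclose(s_pca[:, k], sign * col, atol=1e-8)

    def test_linear_kernel_kpca_matches_pca_up_to_scale_and_sign(self, rng):
        X = rng.normal(size=(20, 10))
        s_pca = apply_selector(fit_projection("pca", X, 3), X)
        s_kpca = apply_selector(fit_projection("kpca", X, 3, kernel="linear"), X)
        for k in range(3):
            a, b = s_pca[:, k], s_kpca[:, k]
            scale = (a @ b) / (b @ b)
            assert np.allclose(a, scale * b, atol=1e-6 * np.linalg.norm(a))

    def test_n_out_of_range(self, rng):
        X = rng.normal(size=(8, 5))
        with pytest.raises(ValueError):
            fit_projection("pca", X, 9)
        with pytest.raises(ValueError):
            fit_projection("kpca", X, 8)


class TestRankers:
    def test_f_statistic_closed_form(self, rng):
        # engineer a column with empirical correlation exactly 0.5
        n = 12
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
        zc = z - z.mean()
        zc -= (zc @ xc) * xc
        zc /= np.linalg.norm(zc)
        y = 0.5 * xc + np.sqrt(0.75) * zc + 10.0
        f = rank_features("f_test", x[:, None], y)
        assert np.isclose(f[0], 10.0 / 3.0, atol=1e-9)

    def test_f_matches_corrcoef_oracle(self, rng):
        X = rng.normal(size=(30, 8))
        y = rng.normal(size=30)
        f = rank_features("f_test", X, y)
        for j in range(8):
            r2 = np.corrcoef(X[:, j], y)[0, 1] ** 2
            assert np.isclose(f[j], 28 * r2 / (1 - r2), rtol=1e-10)

    def test_ppmcc_perfect_correlation(self, rng):
        X = rng.normal(size=(15, 4))
        y = X[:, 2].copy()
        scores = rank_features("ppmcc", X, y)
        assert np.isclose(scores[2], 1.0)

    def test_constant_column_scores_zero_with_warning(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 1] = 4.2
        with pytest.warns(RuntimeWarning, match="constant column"):
            scores = rank_features("ppmcc", X, rng.normal(size=10))
        assert scores[1] == 0.0

    def test_mi_detects_nonlinear_dependence(self):
        rng = np.random.default_rng(123)
        n = 200
        x = rng.uniform(-1, 1, size=n)
        y = x**2
        noise = rng.normal(size=(n, 50))
        X = np.column_stack([x, noise])
        mi = rank_features("mi", X, y, seed=0)
        assert mi[0] > np.percentile(mi[1:], 95)
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.2

    def test_top_n_sets_nested_and_tie_broken_low_index(self):
        scores = np.array([1.0, 3.0, 1.0, 3.0, 0.5])
        assert top_n_indices(scores, 2).tolist() == [1, 3]
        assert top_n_indices(scores, 3).tolist() == [0, 1, 3]
        for n in range(1, 5):
            assert set(top_n_indices(scores, n)) <= set(top_n_indices(scores, n + 1))


class TestRfe:
    def test_exact_column_survives_to_one(self, rng):
        X = rng.normal(size=(40, 6))
        y = X[:, 1].copy()
        assert rfe_select(X, y, 1).indices.tolist() == [1]

    def test_single_step_removes_smallest_coefficient(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        sd = X.std(axis=0, ddof=1)
        beta = np.linalg.lstsq(
            np.hstack([np.ones((30, 1)), X / sd]), y, rcond=None
        )[0][1:]
        weakest = int(np.argmin(np.abs(beta)))
        sel = rfe_select(X, y, 4)
        assert weakest not in sel.indices
        with pytest.raises(ValueError):
            rfe_select(X, y, 5)  # n == p is rejected

    def test_matches_hand_rolled_elimination_oracle(self, rng):
        X = rng.normal(size=(25, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=25)

        def oracle(X, y, n):
            active = list(range(X.shape[1]))
            sd = X.std(axis=0, ddof=1)
            while len(active) > n:
                A = np.column_stack([np.ones(X.shape[0]), X[:, active] / sd[active]])
                coef = np.linalg.pinv(A) @ y
                active.pop(int(np.argmin(np.abs(coef[1:]))))
            return sorted(active)

        for n in (1, 2, 3):
            assert rfe_select(X, y, n).indices.tolist() == oracle(X, y, n)


class TestSpa:
    def test_orthogonal_columns_chain_follows_norms(self, rng):
        Q, _ = np.linalg.qr(rng.normal(size=(10, 4)))
        norms = np.array([3.0, 5.0, 2.0, 4.0])
        X = Q * norms
        chain = spa_chain(X, start=1, n_max=4)
        assert chain == [1, 3, 0, 2]  # descending residual norm = column norm

    def test_duplicate_column_selected_once(self, rng):
        X = rng.normal(size=(12, 4))
        X[:, 3] = X[:, 0]
        chain = spa_chain(X, start=0, n_max=4)
        assert 3 not in chain

    def test_matches_exhaustive_candidate_oracle(self, rng):
        n, p = 24, 6
        X = rng.normal(size=(n, p))
        y = X[:, 0] - 0.5 * X[:, 4] + 0.1 * rng.normal(size=n)
        seed, folds, n_min, n_max = 3, 5, 1, 3
        sel = spa_select(X, y, n_min=n_min, n_max=n_max, seed=seed, folds=folds)

        # oracle: projections via explicit least squares, same CV folds
        def residual_norms(chosen):
            S = X[:, chosen]
            proj = S @ np.linalg.pinv(S)
            return np.linalg.norm(X - proj @ X, axis=0)

        splits = list(KFold(folds, shuffle=True, random_state=seed).split(np.arange(n)))

        def cv_rmse(idx):
            sse = 0.0
            for tr, va in splits:
                A = np.column_stack([np.ones(tr.size), X[np.ix_(tr, idx)]])
                beta = np.linalg.pinv(A) @ y[tr]
                sse += np.sum((y[va] - beta[0] - X[np.ix_(va, idx)] @ beta[1:]) ** 2)
            return np.sqrt(sse / n)

        best = None
        for start in range(p):
            chain = [start]
            for _ in range(n_max - 1):
                rn = residual_norms(chain)
                rn[chain] = -1
                chain.append(int(np.argmax(rn)))
            for L in range(n_min, n_max + 1):
                idx = sorted(chain[:L])
                key = (cv_rmse(idx), L, start)
                if best is None or key < best:
                    best, best_idx = key, idx
        assert sel.indices.tolist() == best_idx

    def test_low_collinearity_property(self, rng):
        # on a collinear design SPA picks less mutually correlated columns
        # than random subsets of the same size (median over 20 replicates)
        def max_abs_corr(X, idx):
            C = np.corrcoef(X[:, idx].T)
            return np.abs(C[np.triu_indices(len(idx), 1)]).max()

        diffs = []
        for rep in range(20):
            r = np.random.default_rng(rep)
            base = r.normal(size=(30, 3))
            X = np.repeat(base, 3, axis=1) + 0.3 * r.normal(size=(30, 9))
            y = base @ [1.0, -1.0, 0.5] + 0.1 * r.normal(size=30)
            sel = spa_select(X, y, n_min=3, n_max=3, seed=rep)
            rand_idx = r.choice(9, size=3, replace=False)
            diffs.append(max_abs_corr(X, rand_idx) - max_abs_corr(X, sel.indices))
        assert np.median(diffs) > 0


class TestCars:
    def test_edf_schedule_endpoints_closed_form(self):
        r = edf_ratios(100, 50)
        assert np.isclose(r[0], 1.0, rtol=1e-12)
        assert np.isclose(r[-1], 2.0 / 100.0, rtol=1e-12)
        r2 = edf_ratios(221, 50)
        assert np.isclose(r2[0], 1.0) and np.isclose(r2[-1], 2.0 / 221.0)

    def test_edf_forced_counts_non_increasing(self):
        r = edf_ratios(221, 50)
        counts = np.ceil(r * 221)
        assert np.all(np.diff(counts) <= 0)

    def test_pls_coefficient_path_matches_refits(self, rng):
        X = rng.normal(size=(40, 30))
        y = X[:, 3] - X[:, 17] + 0.2 * rng.normal(size=40)
        xm, ym, B = _pls_coef_path(X, y, 6)
        for k in (1, 3, 6):
            m = PLSRegression(n_components=k, scale=False).fit(X, y)
            assert np.allclose(B[:, k - 1], m.coef_.ravel(), atol=1e-8)
            pred = (X - xm) @ B[:, k - 1] + ym
            assert np.allclose(pred, m.predict(X).ravel(), atol=1e-8)

    def test_recovers_planted_bands(self, quiet_dataset):
        from specfe import GeneratorConfig

        cfg = GeneratorConfig()
        centers = cfg.informative()
        sel = cars_select(quiet_dataset.reflectance, quiet_dataset.ssc, seed=5)
        wl = quiet_dataset.wavelengths
        hits = sum(
            any(abs(wl[i] - c) <= 10.0 for i in sel.indices) for c in centers
        )
        assert hits >= 2

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(40, 25))
        y = X[:, 5] + 0.3 * rng.normal(size=40)
        a = cars_select(X, y, runs=10, seed=9)
        b = cars_select(X, y, runs=10, seed=9)
        assert a.indices.tolist() == b.indices.tolist()

    def test_parameter_validation(self, rng):
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        with pytest.raises(ValueError):
            cars_select(X, y, runs=1)
        with pytest.raises(ValueError):
            cars_select(X, y, mc_ratio=1.0)


class TestApplySelector:
    def test_full_index_set_is_identity(self, rng):
        X = rng.normal(size=(7, 5))
        sel = Selector("f_test", 5, 5, {"indices": np.arange(5)})
        assert np.array_equal(apply_selector(sel, X), X)

    def test_apply_is_deterministic(self, rng):
        X = rng.normal(size=(20, 10))
        sel = fit_projection("kpca", X, 3)
        assert np.array_equal(apply_selector(sel, X), apply_selector(sel, X))

    def test_pca_single_row_matches_training_scores(self, rng):
        X = rng.normal(size=(15, 8))
        sel = fit_projection("pca", X, 3)
        scores = apply_selector(sel, X)
        assert np.allclose(apply_selector(sel, X[4:5]), scores[4:5], atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        sel = fit_projection("pca", rng.normal(size=(10, 8)), 2)
        with pytest.raises(ValueError):
            apply_selector(sel, rng.normal(size=(3, 7)))

    def test_output_width_equals_n_features(self, rng, quiet_dataset):
        X, y = quiet_dataset.reflectance[:40], quiet_dataset.ssc[:40]
        for method, n in [("pca", 4), ("f_test", 7), ("rfe", 3)]:
            sel = fit_selector(method, X, y, n=n)
            assert apply_selector(sel, X).shape == (40, n)


def test_deterministic_selectors_invariant_to_row_order(rng):
    X = rng.normal(size=(30, 12))
    y = X[:, 4] + 0.2 * rng.normal(size=30)
    perm = rng.permutation(30)
    for method in ("f_test", "ppmcc"):
        a = fit_selector(method, X, y, n=4)
        b = fit_selector(method, X[perm], y[perm], n=4)
        assert a.indices.tolist() == b.indices.tolist()
    assert (
        rfe_select(X, y, 3).indices.tolist()
        == rfe_select(X[perm], y[perm], 3).indices.tolist()
    )
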