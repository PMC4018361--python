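import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldapls import (
    LDAPLS,
    ExLDAPLS,
    combine_ex,
    fit_lda_pls,
    lda_direction,
    make_toy2d,
    project,
    search_lambda,
)
from ldapls.lda_pls import DegenerateBlendError, _lambda_grid


def cosine(a, b):
    return abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))


def two_class(rng, n=50, k=2, sep=2.0):
    half = n // 2
    X = rng.standard_normal((2 * half, k))
    y = np.r_[np.full(half, -1), np.full(half, 1)]
    shift = rng.standard_normal(k)
    X[y == 1] += sep * shift / np.linalg.norm(shift)
    return X, y


class TestLdaPlsStructure:
    def test_two_lv_coincides_with_lda_in_2d(self, rng):
        """With 2 LVs on full-rank 2-feature data the corrected direction
        falls back onto plain LDA."""
        X, y = two_class(rng, n=50, k=2)
        model = fit_lda_pls(X, y, n_lv=2, n_components=1)
        assert cosine(model.coefs_[:, 0], model.directions_lda_[:, 0]) > 1 - 1e-8

    def test_one_lv_is_total_scatter_times_lda(self, rng):
        """One LV gives B ∝ Xc^T Xc w_lda (the PLS weight identity)."""
        X, y = two_class(rng, n=60, k=8)
        model = fit_lda_pls(X, y, n_lv=1, n_components=1)
        Xc = X - X.mean(axis=0)
        ref = Xc.T @ Xc @ model.directions_lda_[:, 0]
        assert cosine(model.coefs_[:, 0], ref) > 1 - 1e-8

    def test_full_lv_collapse(self, rng):
        """A full set of latent variables recovers the exact regression of
        the (exactly linear) LDA projection values, hence w_lda itself."""
        X, y = two_class(rng, n=40, k=5)
        model = fit_lda_pls(X, y, n_lv=5, n_components=1)
        assert cosine(model.coefs_[:, 0], model.directions_lda_[:, 0]) > 1 - 1e-6

    def test_deflation_scores_orthogonal(self, rng):
        X, y = two_class(rng, n=60, k=10)
        model = fit_lda_pls(X, y, n_lv=2, n_components=3)
        T = model.deflation_scores_
        G = T.T @ T
        assert np.abs(G - np.diag(np.diag(G))).max() < 1e-8

    def test_unit_lda_directions_finite_coefs(self, rng):
        X, y = two_class(rng, n=40, k=6)
        model = fit_lda_pls(X, y, n_lv=2, n_components=2)
        np.testing.assert_allclose(
            np.linalg.norm(model.directions_lda_, axis=0), 1.0, atol=1e-10
        )
        assert np.isfinite(model.coefs_).all()
        assert (np.linalg.norm(model.coefs_, axis=0) > 0).all()

    def test_lda_score_deflation_switch(self, rng):
        X, y = two_class(rng, n=40, k=6)
        model = LDAPLS(n_components=2, n_lv=1, deflation="lda").fit(X, y)
        s = model.transform(X)
        assert s.shape == (40, 2)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_property_2d_2lv_coincidence(self, seed):
        rng = np.random.default_rng(seed)
        X, y = two_class(rng, n=50, k=2, sep=1.5)
        model = fit_lda_pls(X, y, n_lv=2, n_components=1)
        assert cosine(model.coefs_[:, 0], model.directions_lda_[:, 0]) > 1 - 1e-6


class TestProjection:
    def test_training_projection_reproduces_fit(self, rng):
        X, y = two_class(rng, n=50, k=8)
        model = fit_lda_pls(X, y, n_lv=2, n_components=3)
        S = project(model, X)
        expected = model.deflation_scores_ * model.score_norms_
        np.testing.assert_allclose(S, expected, atol=1e-8)

    def test_column_means_project_to_zero(self, rng):
        X, y = two_class(rng, n=40, k=5)
        model = fit_lda_pls(X, y, n_lv=1, n_components=2)
        S = project(model, X.mean(axis=0)[None, :])
        np.testing.assert_allclose(S, 0.0, atol=1e-10)

    def test_single_component_is_plain_projection(self, rng):
        X, y = two_class(rng, n=40, k=5)
        model = fit_lda_pls(X, y, n_lv=1, n_components=1)
        S = project(model, X)
        np.testing.assert_allclose(
            S[:, 0], (X - X.mean(axis=0)) @ model.coefs_[:, 0], atol=1e-10
        )

    def test_dimension_mismatch(self, rng):
        X, y = two_class(rng, n=30, k=4)
        model = fit_lda_pls(X, y, n_lv=1)
        with pytest.raises(ValueError):
            project(model, X[:, :2])


class TestCombineEx:
    def test_endpoints(self, rng):
        w = rng.standard_normal(5)
        B = rng.standard_normal(5) * 13.0
        at0 = combine_ex(w, B, 0.0).w_combined
        at1 = combine_ex(w, B, 1.0).w_combined
        np.testing.assert_allclose(at0, w / np.linalg.norm(w), atol=1e-12)
        np.testing.assert_allclose(at1, B / np.linalg.norm(B), atol=1e-12)

    def test_identical_inputs_fixed_point(self, rng):
        w = rng.standard_normal(4)
        w /= np.linalg.norm(w)
        for lam in (0.0, 0.3, 1.0):
            np.testing.assert_allclose(
                combine_ex(w, 5.0 * w, lam).w_combined, w, atol=1e-12
            )

    def test_unit_norm_and_continuity(self, rng):
        w = rng.standard_normal(6)
        B = rng.standard_normal(6)
        lams = np.linspace(0, 1, 101)
        dirs = np.array([combine_ex(w, B, l).w_combined for l in lams])
        np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-12)
        steps = np.linalg.norm(np.diff(dirs, axis=0), axis=1)
        assert steps.max() < 0.1  # no jumps along the path

    def test_antiparallel_interior_blend_degenerate(self):
        w = np.array([1.0, 0.0])
        with pytest.raises(DegenerateBlendError):
            combine_ex(w, -w, 0.5)

    def test_lambda_out_of_range(self):
        with pytest.raises(ValueError):
            combine_ex(np.ones(2), np.ones(2), 1.5)


class TestSearchLambda:
    def test_grid_has_1001_points(self):
        grid = _lambda_grid(1e-3)
        assert len(grid) == 1001
        assert grid[0] == 0.0 and grid[-1] == 1.0

    def test_best_dominates_endpoints_and_ties_break_low(self, rng):
        X, y = two_class(rng, n=80, k=4, sep=3.0)
        res = search_lambda(X, y, n_lv=1, seed=5)
        best_acc = res.val_accuracy[res.grid == res.best_lambda][0]
        assert best_acc >= res.val_accuracy[0]
        assert best_acc >= res.val_accuracy[-1]
        # smallest λ on ties
        ties = res.grid[res.val_accuracy == best_acc]
        assert res.best_lambda == ties.min()

    def test_easy_data_best_lambda_zero(self, rng):
        """When LDA alone separates both halves, λ=0 already attains the
        maximum and the tie rule keeps it."""
        X, y = two_class(rng, n=60, k=3, sep=25.0)
        res = search_lambda(X, y, n_lv=1, seed=1)
        assert res.val_accuracy[0] == 1.0
        assert res.best_lambda == 0.0

    def test_deterministic_in_seed(self, rng):
        X, y = two_class(rng, n=60, k=4)
        r1 = search_lambda(X, y, n_lv=1, seed=9)
        r2 = search_lambda(X, y, n_lv=1, seed=9)
        assert r1.best_lambda == r2.best_lambda
        np.testing.assert_array_equal(r1.val_accuracy, r2.val_accuracy)
        assert r1.split_info == r2.split_info

    def test_vectorized_curve_matches_classifier_loop(self, rng):
        """The fast grid evaluation must agree with per-λ classifier fits."""
        from ldapls import GaussianLinearClassifier
        from ldapls.lda_pls import LDAPLS as _LDAPLS

        X, y = two_class(rng, n=60, k=4)
        res = search_lambda(X, y, n_lv=1, seed=3)
        sel = np.asarray(res.split_info["selection"])
        ver = np.asarray(res.split_info["verification"])
        model = _LDAPLS(n_components=1, n_lv=1).fit(X[sel], y[sel])
        w = model.directions_lda_[:, 0]
        B = model.coefs_[:, 0]
        for i in [0, 137, 500, 804, 1000]:
            d = combine_ex(w, B, res.grid[i]).w_combined
            s_sel = model.center_.apply(X[sel]) @ d
            s_ver = model.center_.apply(X[ver]) @ d
            clf = GaussianLinearClassifier().fit(s_sel, y[sel])
            acc = (clf.predict(s_ver) == y[ver]).mean()
            assert acc == pytest.approx(res.val_accuracy[i], abs=1e-12)

    def test_tiny_dataset_split_error(self):
        X = np.arange(12, dtype=float).reshape(6, 2)
        y = np.array([-1, -1, -1, 1, 1, 1])
        with pytest.raises(ValueError, match="larger dataset"):
            search_lambda(X, y, n_lv=1, seed=0)


class TestExLDAPLSEstimator:
    def test_fixed_lambda_endpoints_match_bases(self, rng):
        X, y = two_class(rng, n=50, k=5)
        base = LDAPLS(n_components=1, n_lv=1).fit(X, y)
        at1 = ExLDAPLS(n_components=1, n_lv=1, lam=1.0).fit(X, y)
        s_base = base.transform(X)[:, 0] / np.linalg.norm(base.coefs_[:, 0])
        np.testing.assert_allclose(at1.transform(X)[:, 0], s_base, atol=1e-8)
        at0 = ExLDAPLS(n_components=1, n_lv=1, lam=0.0).fit(X, y)
        s_lda = (X - X.mean(0)) @ base.directions_lda_[:, 0]
        np.testing.assert_allclose(at0.transform(X)[:, 0], s_lda, atol=1e-8)

    def test_searched_lambda_recorded_and_deterministic(self, rng):
        X, y = two_class(rng, n=80, k=4)
        m1 = ExLDAPLS(n_lv=1, random_state=4).fit(X, y)
        m2 = ExLDAPLS(n_lv=1, random_state=4).fit(X, y)
        assert 0.0 <= m1.lambda_ <= 1.0
        assert m1.lambda_ == m2.lambda_

    def test_toy_phenomenon_blend_fixes_lda(self):
        """Frozen-toy regression: plain LDA cannot reach training accuracy 1
        but some λ on the grid can."""
        from ldapls import GaussianLinearClassifier
        from ldapls.lda_pls import _grid_accuracies

        ds = make_toy2d()
        w = lda_direction(ds.X, ds.y)
        Xc = ds.X - ds.X.mean(axis=0)
        clf = GaussianLinearClassifier().fit(Xc @ w, ds.y)
        lda_acc = (clf.predict(Xc @ w) == ds.y).mean()
        assert lda_acc < 1.0

        model = LDAPLS(n_components=1, n_lv=1).fit(ds.X, ds.y)
        b_hat = model.coefs_[:, 0] / np.linalg.norm(model.coefs_[:, 0])
        grid = _lambda_grid(1e-3)
        mix = (1 - grid)[None, :] * model.directions_lda_[:, 0][:, None] + grid[
            None, :
        ] * b_hat[:, None]
        accs = _grid_accuracies(Xc @ mix, ds.y, Xc @ mix, ds.y)
        assert accs.max() == 1.0
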