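"""Soft-thresholding, component fitting against SVD oracles, deflation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mintpls import (
    MultiStudyDataset,
    encode_dummy,
    fit_mint,
    soft_threshold,
    standardize_by_study,
    threshold_for_keepx,
)
from mintpls.core import FitError, deflate, fit_component

from conftest import make_dataset, random_dataset


# ---------------------------------------------------------------- primitives
class TestSoftThreshold:
    @pytest.mark.parametrize(
        "w, lam, expected",
        [
            ([0.5, -0.1, 0.3], 0.2, [0.3, 0.0, 0.1]),
            ([0.5, -0.1, 0.3], 0.0, [0.5, -0.1, 0.3]),
            ([0.5, -0.1, 0.3], 0.6, [0.0, 0.0, 0.0]),
        ],
    )
    def test_definition(self, w, lam, expected):
        np.testing.assert_allclose(soft_threshold(np.array(w), lam), expected, atol=1e-15)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.array([1.0]), -0.1)

    @given(
        hnp.arrays(np.float64, st.integers(1, 30),
                   elements=st.floats(-10, 10, allow_nan=False)),
        st.floats(0, 5),
    )
    @settings(derandomize=True, max_examples=100)
    def test_zeros_exactly_where_magnitude_below_lambda(self, w, lam):
        out = soft_threshold(w, lam)
        np.testing.assert_array_equal(out == 0.0, np.abs(w) <= lam)
        assert np.all(np.abs(out) <= np.abs(w))


class TestThresholdForKeepx:
    def test_order_statistic(self):
        w = np.array([0.9, -0.5, 0.1])
        lam = threshold_for_keepx(w, 2)
        assert lam == pytest.approx(0.1)
        np.testing.assert_allclose(soft_threshold(w, lam), [0.8, -0.4, 0.0])

    def test_keep_all_gives_zero(self):
        assert threshold_for_keepx(np.array([0.3, 0.2]), 2) == 0.0

    def test_boundary_tie_keeps_both_with_warning(self):
        w = np.array([0.4, 0.4, 0.2])
        with pytest.warns(UserWarning, match="tie"):
            lam = threshold_for_keepx(w, 1)
        out = soft_threshold(w, lam)
        assert np.count_nonzero(out) == 2

    @pytest.mark.parametrize("keep", [0, 4])
    def test_keep_out_of_range(self, keep):
        with pytest.raises(ValueError):
            threshold_for_keepx(np.array([1.0, 2.0, 3.0]), keep)

    @given(st.data())
    @settings(derandomize=True, max_examples=100)
    def test_exact_count_for_distinct_magnitudes(self, data):
        n = data.draw(st.integers(2, 40))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        w = rng.normal(size=n)  # continuous draws: ties have measure zero
        keep = data.draw(st.integers(1, n))
        lam = threshold_for_keepx(w, keep)
        assert np.count_nonzero(soft_threshold(w, lam)) == keep


# ---------------------------------------------------------------- deflation
class TestDeflate:
    def test_residual_orthogonal_to_component(self):
        rng = np.random.default_rng(1)
        x, y, t = rng.normal(size=(10, 6)), rng.normal(size=(10, 3)), rng.normal(size=10)
        x1, y1, p, c = deflate(x, y, t)
        np.testing.assert_allclose(x1.T @ t, 0.0, atol=1e-12)
        np.testing.assert_allclose(y1.T @ t, 0.0, atol=1e-12)

    def test_rank_one_matrix_deflates_to_zero(self):
        rng = np.random.default_rng(2)
        t, c = rng.normal(size=8), rng.normal(size=5)
        x = np.outer(t, c)
        x1, _, p, _ = deflate(x, np.outer(t, [1.0, -1.0]), t)
        np.testing.assert_allclose(x1, 0.0, atol=1e-13)
        np.testing.assert_allclose(p, c, rtol=1e-12)

    def test_idempotent_on_residual(self):
        rng = np.random.default_rng(3)
        x, y, t = rng.normal(size=(10, 4)), rng.normal(size=(10, 2)), rng.normal(size=10)
        x1, y1, _, _ = deflate(x, y, t)
        x2, y2, _, _ = deflate(x1, y1, t)
        np.testing.assert_allclose(x2, x1, atol=1e-13)
        np.testing.assert_allclose(y2, y1, atol=1e-13)

    def test_zero_component_rejected(self):
        with pytest.raises(FitError):
            deflate(np.ones((4, 2)), np.ones((4, 2)), np.zeros(4))


# ---------------------------------------------------------------- components
def svd_pls_oracle(xs, ys, n_components):
    """Independent oracle: successive top singular pairs of X'Y with
    regression deflation of both blocks (dense two-block PLS)."""
    a_list, b_list, t_list = [], [], []
    x, y = xs.copy(), ys.copy()
    for _ in range(n_components):
        u, s, vt = np.linalg.svd(x.T @ y, full_matrices=False)
        a, b = u[:, 0], vt[0]
        j = np.argmax(np.abs(a))
        if a[j] < 0:
            a, b = -a, -b
        t = x @ a
        tt = t @ t
        x = x - np.outer(t, x.T @ t / tt)
        y = y - np.outer(t, y.T @ t / tt)
        a_list.append(a)
        b_list.append(b)
        t_list.append(t)
    return np.column_stack(a_list), np.column_stack(b_list), np.column_stack(t_list)


class TestFitComponent:
    def test_unpenalized_component_is_top_singular_pair(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(10, 5))
        y = rng.normal(size=(10, 2))
        a, b, t, u, diag = fit_component(x, y, keep=5)
        uu, ss, vt = np.linalg.svd(x.T @ y, full_matrices=False)
        s = np.sign(a @ uu[:, 0])
        np.testing.assert_allclose(a, s * uu[:, 0], atol=1e-10)
        np.testing.assert_allclose(b, s * vt[0], atol=1e-10)
        assert a @ (x.T @ y) @ b == pytest.approx(ss[0], rel=1e-10)

    def test_keep_one_selects_best_single_column(self):
        # one X column equals a centered Y column; the rest is noise
        rng = np.random.default_rng(5)
        n, p = 40, 8
        y_raw = np.array([1.0, 0.0] * (n // 2))
        y = np.column_stack([y_raw, 1 - y_raw]) - 0.5
        x = rng.normal(scale=0.5, size=(n, p))
        x[:, 3] = y[:, 0]
        a, b, *_ = fit_component(x, y, keep=1)
        # brute-force oracle: column maximizing max_b |x_j' Y b| = ||Y' x_j||
        scores = np.linalg.norm(y.T @ x, axis=0)
        assert np.flatnonzero(a)[0] == np.argmax(scores) == 3

    def test_zero_cross_product_rejected(self):
        with pytest.raises(FitError, match="no covariance"):
            fit_component(np.ones((4, 2)), np.zeros((4, 2)), keep=2)

    def test_nonconvergence_warns_and_returns_iterate(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=(20, 10)), rng.normal(size=(20, 3))
        with pytest.warns(UserWarning, match="did not converge"):
            a, b, t, u, diag = fit_component(x, y, keep=3, tol=0.0, max_iter=2)
        assert not diag["converged"]
        assert np.linalg.norm(a) == pytest.approx(1.0)


class TestFitMint:
    def test_default_components_is_classes_minus_one(self, small_dataset):
        model = fit_mint(small_dataset)
        assert len(small_dataset.classes) == 3
        assert model.n_components == 2

    def test_single_study_dense_fit_matches_pls_oracle(self):
        ds, _ = make_dataset(n_studies=1, n_classes=3, samples_per_class=4,
                             n_variables=6, study_sd=0.0, study_scale_sd=0.0, seed=9)
        dummy = encode_dummy(ds.class_labels)
        xs, ys, _ = standardize_by_study(ds, dummy)
        a_o, b_o, t_o = svd_pls_oracle(xs, ys, 2)
        model = fit_mint(ds, keep_x="all")
        np.testing.assert_allclose(model.a.to_numpy(), a_o, atol=1e-8)
        np.testing.assert_allclose(model.b.to_numpy(), b_o, atol=1e-8)
        np.testing.assert_allclose(model.t_global.to_numpy(), t_o, atol=1e-8)

    def test_multi_study_dense_fit_matches_oracle_on_standardized_concatenation(self):
        # per-study centering makes the summed per-study cross-product equal
        # the concatenated one, so the dense fit must match the same oracle
        for m in (2, 5):
            ds, _ = make_dataset(n_studies=m, n_classes=2, samples_per_class=5,
                                 n_variables=7, seed=20 + m)
            dummy = encode_dummy(ds.class_labels)
            xs, ys, _ = standardize_by_study(ds, dummy)
            a_o, b_o, t_o = svd_pls_oracle(xs, ys, 1)
            model = fit_mint(ds, keep_x="all", n_components=1)
            np.testing.assert_allclose(model.a.to_numpy(), a_o, atol=1e-8)
            np.testing.assert_allclose(model.t_global.to_numpy(), t_o, atol=1e-8)

    def test_global_components_mutually_orthogonal(self, small_dataset):
        model = fit_mint(small_dataset, keep_x=[10, 10])
        t = model.t_global.to_numpy()
        dot = abs(t[:, 0] @ t[:, 1])
        assert dot < 1e-8 * np.linalg.norm(t[:, 0]) * np.linalg.norm(t[:, 1])

    def test_sparsity_matches_keepx(self, small_dataset):
        model = fit_mint(small_dataset, keep_x=[4, 9])
        nnz = (model.a.to_numpy() != 0.0).sum(axis=0)
        assert nnz.tolist() == [4, 9]

    def test_loadings_unit_norm(self, small_dataset):
        model = fit_mint(small_dataset, keep_x=[4, 9])
        np.testing.assert_allclose(np.linalg.norm(model.a.to_numpy(), axis=0), 1.0,
                                   rtol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(model.b.to_numpy(), axis=0), 1.0,
                                   rtol=1e-12)

    def test_deterministic_and_bitwise_identical(self, small_dataset):
        m1 = fit_mint(small_dataset, keep_x=[5, 5])
        m2 = fit_mint(small_dataset, keep_x=[5, 5])
        assert np.array_equal(m1.a.to_numpy(), m2.a.to_numpy())
        assert np.array_equal(m1.t_global.to_numpy(), m2.t_global.to_numpy())

    def test_monotone_nesting_of_components(self, small_dataset):
        full = fit_mint(small_dataset, keep_x=[5, 8], n_components=2)
        first = fit_mint(small_dataset, keep_x=[5], n_components=1)
        np.testing.assert_array_equal(full.a.iloc[:, 0].to_numpy(),
                                      first.a.iloc[:, 0].to_numpy())
        np.testing.assert_array_equal(full.t_global.iloc[:, 0].to_numpy(),
                                      first.t_global.iloc[:, 0].to_numpy())

    def test_invariant_to_study_block_order(self, small_dataset):
        order = np.argsort(small_dataset.study_labels.to_numpy(), kind="stable")[::-1]
        permuted = MultiStudyDataset(
            small_dataset.expression.iloc[order],
            small_dataset.study_labels.iloc[order],
            small_dataset.class_labels.iloc[order],
        )
        m1 = fit_mint(small_dataset, keep_x=[5, 5])
        m2 = fit_mint(permuted, keep_x=[5, 5])
        np.testing.assert_allclose(m1.a.to_numpy(), m2.a.to_numpy(), atol=1e-10)
        np.testing.assert_allclose(
            m1.t_global.loc[m2.t_global.index].to_numpy(),
            m2.t_global.to_numpy(), atol=1e-10,
        )

    def test_partial_scores_are_row_blocks_of_global(self, small_dataset):
        model = fit_mint(small_dataset, keep_x=[5, 5])
        for study in small_dataset.studies:
            block = model.partial_scores(study)
            mask = small_dataset.study_mask(study)
            np.testing.assert_array_equal(block.to_numpy(),
                                          model.t_global.to_numpy()[mask])

    def test_invalid_inputs_rejected(self, small_dataset):
        with pytest.raises(ValueError, match=">= 1"):
            fit_mint(small_dataset, n_components=0)
        with pytest.raises(ValueError, match="keep_x"):
            fit_mint(small_dataset, keep_x=[5], n_components=2)
        with pytest.raises(ValueError, match="keep_x"):
            fit_mint(small_dataset, keep_x=[0, 5])

    def test_shuffled_labels_fit_still_valid(self):
        rng = np.random.default_rng(12)
        ds = random_dataset(rng, n_studies=2, n_classes=2, n_per=6, p=10)
        model = fit_mint(ds, keep_x=[3])
        assert (model.a.to_numpy() != 0).sum() == 3
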