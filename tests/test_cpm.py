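"""CPM machinery: residualization, edge selection, CV prediction, permutation, FDR."""
import numpy as np
import pytest
from scipy import stats

import mcqcpm as mc
from mcqcpm.cpm import LoocvEngine
from mcqcpm.errors import DegenerateDataError, EmptyMaskError, InvalidConfigError

from conftest import covmat


def partial_r_oracle(edge, behavior, covariates=None):
    """Partial correlation via the inverse of the joint correlation matrix."""
    cols = [edge, behavior]
    if covariates is not None and np.size(covariates):
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] == len(edge):
            C = C.T
        cols.extend(C)
    R = np.corrcoef(np.vstack(cols))
    omega = np.linalg.inv(R)
    return -omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1])


class TestResidualize:
    def test_no_covariates_is_mean_centering(self, rng):
        v = rng.normal(size=30)
        np.testing.assert_allclose(mc.residualize(v), v - v.mean(), atol=1e-12)

    def test_perfect_fit_gives_zero(self, rng):
        c = rng.normal(size=40)
        np.testing.assert_allclose(mc.residualize(2 * c, c), 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        v = rng.normal(size=50)
        C = rng.normal(size=(50, 3))
        D = np.column_stack([np.ones(50), C])
        expected = v - D @ np.linalg.solve(D.T @ D, D.T @ v)
        np.testing.assert_allclose(mc.residualize(v, C), expected, atol=1e-10)

    def test_residual_orthogonal_to_covariates(self, rng):
        v = rng.normal(size=60)
        C = rng.normal(size=(60, 2))
        res = mc.residualize(v, C)
        assert abs(res.sum()) < 1e-8 * 60
        assert np.abs(C.T @ res).max() < 1e-8 * 60

    def test_collinear_covariate_named(self, rng):
        c = rng.normal(size=30)
        with pytest.raises(DegenerateDataError, match="column 1"):
            mc.residualize(rng.normal(size=30), np.column_stack([c, 2 * c]))


class TestSelectEdges:
    def test_reduces_to_plain_pearson_without_covariates(self, rng):
        X = rng.normal(size=(40, 25))
        y = rng.normal(size=40)
        sel = mc.select_edges(X, y, None, 0.05)
        for k in range(25):
            r, p = stats.pearsonr(X[:, k], y)
            assert sel.r[k] == pytest.approx(r, abs=1e-10)
            assert sel.p[k] == pytest.approx(p, abs=1e-10)

    def test_partial_r_matches_precision_matrix_oracle(self, rng):
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        C = rng.normal(size=(30, 2))
        sel = mc.select_edges(X, y, C, 0.05)
        for k in range(10):
            assert sel.r[k] == pytest.approx(
                partial_r_oracle(X[:, k], y, C), abs=1e-8
            )

    def test_planted_edges_land_in_positive_mask(self, planted_cohort):
        """Power at r=0.5, n=180, alpha=0.01 is ~1: planted edges selected."""
        d = planted_cohort
        sel = mc.select_edges(
            d.edges, d.behavior["CSC"].to_numpy(), covmat(d.behavior), 0.01
        )
        truth = d.ground_truth.mask("CSC", d.edges.n_edges, "pos")
        assert (sel.pos_mask & truth).sum() / truth.sum() >= 0.90

    def test_masks_disjoint_and_within_threshold(self, small_cohort):
        d = small_cohort
        sel = mc.select_edges(
            d.edges, d.behavior["NEG"].to_numpy(), covmat(d.behavior), 0.05
        )
        assert not (sel.pos_mask & sel.neg_mask).any()
        assert (sel.p[sel.pos_mask] < 0.05).all()
        assert (sel.p[sel.neg_mask] < 0.05).all()

    def test_zero_variance_behavior_rejected(self, rng):
        with pytest.raises(DegenerateDataError, match="zero variance"):
            mc.select_edges(rng.normal(size=(30, 5)), np.ones(30))


class TestSummedStrength:
    def test_single_edge_and_arithmetic(self):
        row = np.array([0.5, -0.2, 0.9])
        assert mc.summed_strength(row, [True, False, False]) == 0.5
        assert mc.summed_strength(row, [True, True, False]) == pytest.approx(0.3)

    def test_partition_identity(self, rng):
        row = rng.normal(size=50)
        mask = rng.random(50) < 0.4
        total = mc.summed_strength(row, np.ones(50, bool))
        assert mc.summed_strength(row, mask) + mc.summed_strength(row, ~mask) == pytest.approx(total)

    def test_empty_mask_is_model_not_built(self):
        with pytest.raises(EmptyMaskError):
            mc.summed_strength(np.array([1.0, 2.0]), [False, False])


class TestCpmLoocv:
    def test_perfect_signal_limit(self, rng):
        """Behavior equal to a noiseless linear map of one edge predicts r ~ 1."""
        X = rng.normal(size=(30, 15))
        y = 3.0 * X[:, 4] + 1.0
        res = mc.cpm_loocv(X, y, None, 0.01, "positive")
        assert res.r > 0.99

    def test_planted_cohort_prediction(self, planted_cohort):
        d = planted_cohort
        res = mc.cpm_loocv(
            d.edges, d.behavior["CSC"].to_numpy(), covmat(d.behavior), 0.01, "positive"
        )
        assert res.r >= 0.3
        assert res.n_missing == 0

    def test_permuted_behavior_kills_prediction(self, planted_cohort):
        d = planted_cohort
        rng = np.random.default_rng(77)
        y = rng.permutation(d.behavior["CSC"].to_numpy())
        res = mc.cpm_loocv(d.edges, y, covmat(d.behavior), 0.01, "positive")
        assert np.isnan(res.r) or res.r < 0.3

    def test_affine_shift_of_behavior(self, small_cohort):
        """Adding a constant to the behavior leaves masks unchanged and
        shifts predictions by the same constant."""
        d = small_cohort
        y = d.behavior["CSC"].to_numpy()
        C = covmat(d.behavior)
        r1 = mc.cpm_loocv(d.edges, y, C, 0.01, "positive", keep_fold_details=True)
        r2 = mc.cpm_loocv(d.edges, y + 100.0, C, 0.01, "positive", keep_fold_details=True)
        np.testing.assert_array_equal(r1.fold_masks, r2.fold_masks)
        np.testing.assert_allclose(r2.predicted, r1.predicted + 100.0, atol=1e-6)

    def test_no_leakage_within_fold(self, small_cohort):
        """Perturbing a held-out subject's edges leaves its fold's selection
        and fitted coefficients untouched."""
        d = small_cohort
        y = d.behavior["CSC"].to_numpy()
        C = covmat(d.behavior)
        i = 7
        base = mc.cpm_loocv(d.edges, y, C, 0.01, "positive", keep_fold_details=True)
        X2 = d.edges.values.copy()
        X2[i] += np.random.default_rng(0).normal(0, 1, X2.shape[1])
        pert = mc.cpm_loocv(X2, y, C, 0.01, "positive", keep_fold_details=True)
        np.testing.assert_array_equal(base.fold_masks[i], pert.fold_masks[i])
        np.testing.assert_allclose(base.fold_coefs[i], pert.fold_coefs[i], atol=1e-12)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(InvalidConfigError):
            mc.cpm_loocv(rng.normal(size=(10, 5)), rng.normal(size=10))


class TestCpmKfold:
    def test_k_equals_n_reduces_to_loocv_exactly(self, small_cohort):
        d = small_cohort
        y = d.behavior["CSC"].to_numpy()
        C = covmat(d.behavior)
        lo = mc.cpm_loocv(d.edges, y, C, 0.01, "positive")
        kn = mc.cpm_kfold(d.edges, y, C, 0.01, "positive", k=len(y), repeats=1, seed=3)
        np.testing.assert_array_equal(kn.predicted, lo.predicted)
        np.testing.assert_array_equal(kn.consensus_mask, lo.consensus_mask)

    def test_seeded_determinism(self, small_cohort):
        d = small_cohort
        y = d.behavior["CSC"].to_numpy()
        a = mc.cpm_kfold(d.edges, y, covmat(d.behavior), k=5, repeats=3, seed=11)
        b = mc.cpm_kfold(d.edges, y, covmat(d.behavior), k=5, repeats=3, seed=11)
        np.testing.assert_array_equal(a.predicted, b.predicted)

    def test_k_larger_than_n_rejected(self, small_cohort):
        d = small_cohort
        with pytest.raises(InvalidConfigError):
            mc.cpm_kfold(d.edges, d.behavior["CSC"].to_numpy(), k=999)


class TestLoocvEngine:
    def test_engine_matches_fold_loop_implementation(self, small_cohort):
        """The vectorized LOOCV evaluator reproduces the plain per-fold
        implementation on both tails, predictions and r."""
        d = small_cohort
        C = covmat(d.behavior)
        engine = LoocvEngine(d.edges, C, 0.01)
        for dim in ("CSC", "NEG", "CC"):
            y = d.behavior[dim].to_numpy()
            for tail in ("positive", "negative"):
                ref = mc.cpm_loocv(d.edges, y, C, 0.01, tail)
                r_e, pred_e = engine.evaluate(y, tail)
                assert np.array_equal(
                    np.isfinite(ref.predicted), np.isfinite(pred_e)
                )
                ok = np.isfinite(ref.predicted)
                np.testing.assert_allclose(pred_e[ok], ref.predicted[ok], atol=1e-9)
                if np.isnan(ref.r):
                    assert np.isnan(r_e)
                else:
                    assert r_e == pytest.approx(ref.r, abs=1e-9)

    def test_engine_matches_without_covariates(self, small_cohort):
        d = small_cohort
        y = d.behavior["CSC"].to_numpy()
        ref = mc.cpm_loocv(d.edges, y, None, 0.01, "positive")
        r_e, pred_e = LoocvEngine(d.edges, None, 0.01).evaluate(y, "positive")
        ok = np.isfinite(ref.predicted)
        np.testing.assert_allclose(pred_e[ok], ref.predicted[ok], atol=1e-9)


class TestPermutationTest:
    def test_strong_signal_hits_plus_one_boundary(self, rng):
        """r_obs above every null gives the smallest attainable p, 1/(n+1)."""
        X = rng.normal(size=(40, 30))
        y = 2.0 * X[:, 3] + 0.1 * rng.normal(size=40)
        p = mc.permutation_test(X, y, None, 0.01, "positive", n_perm=100, seed=5)
        assert p == pytest.approx(1.0 / 101.0)

    def test_p_never_zero_and_bounded(self, small_cohort):
        d = small_cohort
        p = mc.permutation_test(
            d.edges, d.behavior["CC"].to_numpy(), covmat(d.behavior),
            n_perm=100, seed=2,
        )
        assert 0.0 < p <= 1.0

    def test_generic_callable_path_agrees_with_engine(self, small_cohort):
        """Supplying the fold-loop pipeline as a callable gives the same p
        as the fast built-in engine (same seed, same statistic)."""
        d = small_cohort
        y = d.behavior["CSC"].to_numpy()
        C = covmat(d.behavior)
        p_fast = mc.permutation_test(d.edges, y, C, 0.01, "positive",
                                     n_perm=100, seed=9)
        p_slow = mc.permutation_test(
            d.edges, y, C, 0.01, "positive", n_perm=100, seed=9,
            cpm_callable=lambda yy: mc.cpm_loocv(d.edges, yy, C, 0.01, "positive").r,
        )
        assert p_fast == p_slow

    def test_n_perm_floor(self, small_cohort):
        d = small_cohort
        with pytest.raises(InvalidConfigError):
            mc.permutation_test(d.edges, d.behavior["CSC"].to_numpy(), n_perm=10)


class TestFdrBh:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(mc.fdr_bh([0.02]), [0.02])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(mc.fdr_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_equal_identity(self):
        np.testing.assert_allclose(mc.fdr_bh([0.2, 0.2, 0.2, 0.2]), [0.2] * 4)

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=37)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(mc.fdr_bh(p), expected, atol=1e-12)

    def test_q_at_least_p_and_order_preserved(self, rng):
        p = rng.uniform(size=20)
        q = mc.fdr_bh(p)
        assert (q >= p - 1e-15).all()
        assert (q[np.argsort(p)] == np.sort(q)).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidConfigError):
            mc.fdr_bh([0.5, 1.2])
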