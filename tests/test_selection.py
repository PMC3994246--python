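import numpy as np
import pytest
from scipy import stats

from cvprotocols import (
    CVProtocol,
    Dataset,
    KNNBuilder,
    PearsonSelector,
    RidgeBuilder,
    SyntheticSpec,
    double_cross_validation,
    generate_regression,
    grid_from_values,
    make_selection_grid,
    optimal_param_distribution,
    pearson_rank_select,
    repeated_grid_search_cv,
    repeated_grid_search_cv_with_selection,
    ridge_lambda_grid,
    single_cv_losses,
    squared_error_cv_loss,
)
from cvprotocols.learners import ParamPoint
from cvprotocols.selection import ProtocolError

from _oracles import (
    double_cv_knn,
    grid_search_with_selection_knn,
    repeated_grid_search_knn,
    single_cv_knn,
)


def _knn_protocol(ks, V, Nexp, seed, selector=None, n_values=None):
    grid = grid_from_values("k", ks, complexity="decreasing")
    if selector is not None:
        grid = make_selection_grid(n_values, grid)
    return CVProtocol(grid=grid, V=V, Nexp=Nexp, loss=squared_error_cv_loss,
                      builder=KNNBuilder("regression"), selector=selector,
                      base_seed=seed)


@pytest.fixture
def medium_regression():
    ds, truth = generate_regression(
        SyntheticSpec(n_samples=40, n_variables=6, n_informative=2,
                      coefficient_scale=1.5, noise_sd=0.5, seed=17)
    )
    return ds, truth


class TestSingleCV:
    def test_matches_brute_force_oracle(self):
        ds, _ = generate_regression(SyntheticSpec(12, 4, 2, seed=1, noise_sd=0.3))
        proto = _knn_protocol([1, 3], V=3, Nexp=1, seed=0)
        mine = single_cv_losses(ds, proto, seed=99)
        oracle = single_cv_knn(ds.X, ds.y, [1, 3], V=3, seed=99)
        np.testing.assert_allclose(mine, oracle, rtol=0, atol=0)

    def test_loo_invariant_across_seeds(self, medium_regression):
        ds, _ = medium_regression
        proto = _knn_protocol([1, 3, 5], V=ds.n_samples, Nexp=1, seed=0)
        a = single_cv_losses(ds, proto, seed=1)
        b = single_cv_losses(ds, proto, seed=2)
        np.testing.assert_array_equal(a, b)

    def test_unfittable_point_names_point_and_fold(self, medium_regression):
        ds, _ = medium_regression
        proto = _knn_protocol([1, 1000], V=4, Nexp=1, seed=0)
        with pytest.raises(ProtocolError, match=r"k=1000.*fold"):
            single_cv_losses(ds, proto, seed=0)


class TestRepeatedGridSearch:
    def test_nexp_one_reduces_to_single_cv(self, medium_regression):
        ds, _ = medium_regression
        proto = _knn_protocol([1, 3, 5], V=5, Nexp=1, seed=44)
        res = repeated_grid_search_cv(ds, proto)
        from cvprotocols._seeds import derive_seed
        single = single_cv_losses(ds, proto, derive_seed(44, "repeat", 0))
        np.testing.assert_array_equal(res.loss_table[0], single)
        np.testing.assert_array_equal(res.mean_loss, single)

    def test_tie_break_prefers_lower_complexity(self):
        # synthetic mean losses via a degenerate two-point grid where both
        # points give identical predictions: k=N-ish on tiny data
        grid = (ParamPoint.make(1, k=2), ParamPoint.make(0, k=3))
        from cvprotocols.selection import choose_best
        assert choose_best(np.array([0.3, 0.3]), grid) == 1
        assert choose_best(np.array([0.3, 0.2, 0.2]),
                           (ParamPoint.make(1, a=1), ParamPoint.make(2, a=2),
                            ParamPoint.make(3, a=3))) == 1

    def test_matches_repeated_oracle(self, medium_regression):
        ds, _ = medium_regression
        proto = _knn_protocol([1, 3, 5], V=4, Nexp=3, seed=7)
        res = repeated_grid_search_cv(ds, proto)
        table, means, k_best = repeated_grid_search_knn(
            ds.X, ds.y, [1, 3, 5], V=4, Nexp=3, base_seed=7
        )
        np.testing.assert_allclose(res.loss_table, table, atol=0)
        assert res.chosen["k"] == k_best

    def test_monotone_grid_refinement(self, medium_regression):
        """Adding a grid point can only lower (or keep) the best mean loss."""
        ds, _ = medium_regression
        small = repeated_grid_search_cv(ds, _knn_protocol([3, 5], 4, 2, seed=9))
        large = repeated_grid_search_cv(ds, _knn_protocol([1, 3, 5], 4, 2, seed=9))
        assert large.best_mean_loss <= small.best_mean_loss + 1e-15

    def test_parallel_execution_identical(self, medium_regression):
        ds, _ = medium_regression
        proto = _knn_protocol([1, 3], V=4, Nexp=4, seed=3)
        a = repeated_grid_search_cv(ds, proto, n_jobs=1)
        b = repeated_grid_search_cv(ds, proto, n_jobs=2)
        np.testing.assert_array_equal(a.loss_table, b.loss_table)
        assert a.chosen == b.chosen


class TestParamDistribution:
    def test_counts_sum_to_nexp(self, medium_regression):
        ds, _ = medium_regression
        res = repeated_grid_search_cv(ds, _knn_protocol([1, 3, 5], 4, 6, seed=2))
        dist = optimal_param_distribution(res)
        assert dist.sum() == 6

    def test_loo_puts_all_mass_on_one_point(self, medium_regression):
        ds, _ = medium_regression
        res = repeated_grid_search_cv(
            ds, _knn_protocol([1, 3], ds.n_samples, 3, seed=2)
        )
        dist = optimal_param_distribution(res)
        assert list(dist.values) == [3]


class TestPearsonSelection:
    def test_column_identical_to_y_ranked_first(self, medium_regression):
        ds, _ = medium_regression
        X = np.column_stack([ds.X, ds.y])
        ds2 = Dataset(X, ds.y, ds.variable_names + ["copy_of_y"], "regression")
        sel = pearson_rank_select(ds2, 1)
        assert sel[0] == ds.n_variables

    def test_p_equals_P_returns_all_sorted(self, medium_regression):
        ds, _ = medium_regression
        sel = pearson_rank_select(ds, ds.n_variables)
        assert sorted(sel) == list(range(ds.n_variables))

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 3))
        y = rng.normal(size=6)
        ds = Dataset(X, y, ["a", "b", "c"], "regression")
        r = [abs(stats.pearsonr(X[:, j], y)[0]) for j in range(3)]
        expected = sorted(range(3), key=lambda j: (-r[j], j))
        np.testing.assert_array_equal(pearson_rank_select(ds, 3), expected)

    def test_zero_variance_column_warns_not_errors(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        ds = Dataset(X, np.arange(10.0), ["const", "lin"], "regression")
        with pytest.warns(UserWarning, match="zero-variance"):
            sel = pearson_rank_select(ds, 2)
        assert sel[0] == 1  # informative column outranks the constant


class TestSelectionInsideCV:
    def test_n_fixed_at_P_reduces_to_plain_grid_search(self, medium_regression):
        ds, _ = medium_regression
        plain = repeated_grid_search_cv(ds, _knn_protocol([1, 3], 4, 2, seed=5))
        with_sel = repeated_grid_search_cv_with_selection(
            ds, _knn_protocol([1, 3], 4, 2, seed=5, selector=PearsonSelector(),
                              n_values=[ds.n_variables])
        )
        # the 2-D grid orders alpha by ascending complexity (k descending);
        # align columns by k before comparing
        order = np.argsort([-pt["k"] for pt in plain.grid])
        np.testing.assert_allclose(with_sel.loss_table, plain.loss_table[:, order],
                                   atol=0)
        assert with_sel.chosen["k"] == plain.chosen["k"]

    def test_matches_2d_oracle(self):
        ds, _ = generate_regression(SyntheticSpec(18, 5, 2, seed=6, noise_sd=0.4))
        proto = _knn_protocol([1, 3], V=3, Nexp=2, seed=13,
                              selector=PearsonSelector(), n_values=[1, 3])
        res = repeated_grid_search_cv_with_selection(ds, proto)
        table, means, (n_best, k_best) = grid_search_with_selection_knn(
            ds.X, ds.y, [1, 3], [1, 3], V=3, Nexp=2, base_seed=13
        )
        # package grid order: n ascending, then k by ascending complexity
        # (i.e. k descending); oracle order: n ascending, k in given order
        remap = [1, 0, 3, 2]
        np.testing.assert_allclose(res.loss_table, table[:, remap], atol=0)
        assert (res.chosen["n_variables"], res.chosen["k"]) == (n_best, k_best)

    def test_selector_sees_training_rows_only(self):
        """Permuting held-out-fold outputs leaves that fold's selection
        unchanged (the leakage guard)."""
        ds, _ = generate_regression(SyntheticSpec(24, 6, 2, seed=8, noise_sd=0.4))
        proto = _knn_protocol([1, 3], V=3, Nexp=1, seed=21,
                              selector=PearsonSelector(), n_values=[2, 4])
        res = repeated_grid_search_cv_with_selection(ds, proto)

        from cvprotocols._seeds import derive_seed
        from cvprotocols.partitioning import make_folds
        folds = make_folds(ds.n_samples, 3, derive_seed(21, "repeat", 0))
        target_fold = 2
        te = folds.test_indices(target_fold)
        y2 = ds.y.copy()
        y2[te] = y2[te][::-1] + 5.0  # scramble held-out outputs only
        ds2 = Dataset(ds.X, y2, ds.variable_names, "regression")
        res2 = repeated_grid_search_cv_with_selection(ds2, proto)
        for n in (2, 4):
            np.testing.assert_array_equal(
                res.selection_audit[(0, target_fold, n)],
                res2.selection_audit[(0, target_fold, n)],
            )

    def test_noiseless_recovery_near_zero_loss(self):
        """On noiseless sparse linear data, selection + tiny-λ ridge finds an
        essentially interpolating model."""
        ds, _ = generate_regression(
            SyntheticSpec(60, 10, 3, coefficient_scale=1.0, noise_sd=0.0, seed=30)
        )
        lam = grid_from_values("lambda", [1e-8], "increasing")
        grid = make_selection_grid([3, 5, 10], lam)
        proto = CVProtocol(grid=grid, V=5, Nexp=2, loss=squared_error_cv_loss,
                           builder=RidgeBuilder(), selector=PearsonSelector(),
                           base_seed=2)
        res = repeated_grid_search_cv_with_selection(ds, proto)
        assert res.best_mean_loss < 1e-6


class TestDoubleCV:
    def test_forced_choice_degenerates_to_plain_cv(self, medium_regression):
        ds, _ = medium_regression
        res = double_cross_validation(
            ds, PearsonSelector(), KNNBuilder("regression"),
            grid_from_values("k", [3], "decreasing"),
            n_values=[ds.n_variables], V1=4, V2=3,
            loss=squared_error_cv_loss, base_seed=0,
        )
        assert res.p_chosen == ds.n_variables
        assert res.alpha_chosen["k"] == 3

    def test_matches_literal_transcription_oracle(self):
        ds, _ = generate_regression(SyntheticSpec(18, 5, 2, seed=14, noise_sd=0.4))
        res = double_cross_validation(
            ds, PearsonSelector(), KNNBuilder("regression"),
            grid_from_values("k", [1, 3], "decreasing"),
            n_values=[1, 2], V1=3, V2=3,
            loss=squared_error_cv_loss, base_seed=5,
        )
        p_o, k_o, step1_o, step2_o = double_cv_knn(
            ds.X, ds.y, [1, 2], [1, 3], V1=3, V2=3, base_seed=5
        )
        assert res.p_chosen == p_o
        assert res.alpha_chosen["k"] == k_o
        assert res.step1_losses == pytest.approx(step1_o, abs=0)
        np.testing.assert_allclose(res.step2_losses, step2_o, atol=0)

    def test_side_by_side_with_grid_search(self):
        """Double CV and the 2-D grid search may legitimately disagree on the
        chosen variable count (complexity mixing); both should still land in
        the informative range on strong-signal data."""
        ds, truth = generate_regression(
            SyntheticSpec(80, 12, 4, coefficient_scale=2.0, noise_sd=0.5, seed=44)
        )
        lam_grid = ridge_lambda_grid(ds, n_lambda=5)
        dcv = double_cross_validation(
            ds, PearsonSelector(), RidgeBuilder(), lam_grid,
            n_values=[2, 4, 8, 12], V1=5, V2=4,
            loss=squared_error_cv_loss, base_seed=9,
        )
        proto = CVProtocol(grid=make_selection_grid([2, 4, 8, 12], lam_grid),
                           V=5, Nexp=2, loss=squared_error_cv_loss,
                           builder=RidgeBuilder(), selector=PearsonSelector(),
                           base_seed=9)
        gs = repeated_grid_search_cv_with_selection(ds, proto)
        assert dcv.p_chosen >= 4
        assert gs.chosen["n_variables"] >= 4
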